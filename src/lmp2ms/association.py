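"""Stratified case-control association analysis for the LMP2 R60H genotype.

The unit of analysis is a stratified genotype contingency table (case/control
status by RR/RH/HH), from which the module computes odds ratios with Woolf
(log-scale) 95% confidence intervals, Pearson chi-square tests with both
asymptotic and Monte Carlo (fixed-margins) p-values, Hardy-Weinberg
equilibrium tests, cohort-homogeneity checks that license pooling two case
series, and permutation ANOVA comparisons of disease onset age.

The statsmodels-flavoured entry point is :class:`CaseControlAssociation`,
built from subject records or a DataFrame; ``fit()`` returns an
:class:`AssociationResults` with all panels and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, ParameterError
from ._rand import substream
from .permutation import PermutationTestResult, permutation_f_test

GENOTYPE_ORDER = ("HH", "RH", "RR")
Z_95 = 1.959964  # two-sided 95% normal quantile


@dataclass(frozen=True)
class SubjectRecord:
    """One genotyped individual of the case-control study."""

    subject_id: str
    status: str  # "case" | "control"
    sex: str  # "male" | "female"
    lmp2: str  # "RR" | "RH" | "HH"
    a02_carrier: str = "unknown"  # "yes" | "no" | "unknown"
    drb115_carrier: str = "unknown"
    onset_age: Optional[float] = None
    cohort: str = "1"  # case series "1"/"2", or "control"

    def __post_init__(self):
        if self.status not in ("case", "control"):
            raise ParameterError(f"bad status {self.status!r}")
        if self.sex not in ("male", "female"):
            raise ParameterError(f"bad sex {self.sex!r}")
        if self.lmp2 not in GENOTYPE_ORDER:
            raise ParameterError(f"bad LMP2 genotype {self.lmp2!r}")
        for val in (self.a02_carrier, self.drb115_carrier):
            if val not in ("yes", "no", "unknown"):
                raise ParameterError(f"bad carrier flag {val!r}")
        if self.status == "control" and self.onset_age is not None:
            raise ParameterError("controls cannot carry an onset age")


@dataclass
class GenotypeTable:
    """Status x genotype counts for one stratum."""

    counts: pd.DataFrame  # index ["case","control"], columns HH/RH/RR
    stratum: Dict[str, Optional[str]] = field(default_factory=dict)

    def __post_init__(self):
        arr = self.counts.to_numpy()
        if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
            raise ParameterError("genotype counts must be non-negative integers")

    def percentages(self) -> pd.DataFrame:
        """Row percentages rounded to 1 decimal (display convention)."""
        pct = self.counts.div(self.counts.sum(axis=1), axis=0) * 100.0
        return pct.round(1)

    def to_array(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float)


@dataclass(frozen=True)
class OddsRatioResult:
    """2x2 odds ratio with Woolf 95% CI."""

    comparison: str
    odds_ratio: float
    ci95: Tuple[float, float]
    log_or_se: float
    haldane_corrected: bool = False


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    df: int
    p_asymptotic: float


@dataclass(frozen=True)
class MonteCarloChi2Result:
    chi2: float
    df: int
    p_monte_carlo: float
    mc_stderr: float
    n_reps: int
    seed: int


@dataclass(frozen=True)
class HWEResult:
    """Pearson chi-square test of Hardy-Weinberg proportions (df=1)."""

    observed: Tuple[int, int, int]  # (n_HH, n_RH, n_RR)
    allele_freq: float  # frequency of the H allele
    chi2: float
    df: int
    p: float


def tabulate(
    subjects: Sequence[SubjectRecord],
    sex: Optional[str] = None,
    a02: Optional[str] = None,
    case_cohorts: Optional[Sequence[str]] = None,
) -> GenotypeTable:
    """Cross-tabulate status x LMP2 genotype for one stratum.

    ``sex`` and ``a02`` filter the stratum (None = no filter); subjects with
    unknown A*02 carriage are excluded whenever an A*02 filter is applied.
    ``case_cohorts`` optionally restricts cases to the given series.
    """
    rows = []
    for s in subjects:
        if sex is not None and s.sex != sex:
            continue
        if a02 is not None:
            if s.a02_carrier == "unknown" or s.a02_carrier != a02:
                continue
        if case_cohorts is not None and s.status == "case" and s.cohort not in case_cohorts:
            continue
        rows.append((s.status, s.lmp2))
    if not rows:
        raise InsufficientDataError("empty stratum after filtering")
    df = pd.DataFrame(rows, columns=["status", "lmp2"])
    counts = pd.crosstab(df["status"], df["lmp2"])
    counts = counts.reindex(index=["case", "control"], columns=list(GENOTYPE_ORDER),
                            fill_value=0)
    if counts.sum(axis=1).eq(0).any():
        raise InsufficientDataError("a status group is empty in this stratum")
    return GenotypeTable(counts=counts, stratum={"sex": sex, "a02": a02})


def odds_ratio(a: float, b: float, c: float, d: float,
               comparison: str = "") -> OddsRatioResult:
    """Odds ratio of genotype-1 vs genotype-2 for cases vs controls.

    Arguments are (case_g1, case_g2, control_g1, control_g2); the odds ratio
    is (case_g1 * control_g2) / (case_g2 * control_g1), with a Woolf
    log-scale 95% CI.  If any cell is zero, Haldane's +0.5 is added to all
    four cells and the result is flagged.
    """
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise ParameterError("cell counts must be non-negative")
    haldane = any(x == 0 for x in cells)
    if haldane:
        a, b, c, d = (x + 0.5 for x in cells)
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(orr) - Z_95 * se)
    hi = math.exp(math.log(orr) + Z_95 * se)
    return OddsRatioResult(comparison, orr, (lo, hi), se, haldane)


def _validate_table(table: np.ndarray) -> np.ndarray:
    table = np.asarray(table, dtype=float)
    if table.ndim != 2:
        raise ParameterError("contingency table must be 2-D")
    if (table < 0).any():
        raise ParameterError("negative counts in contingency table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ParameterError("zero margin in contingency table")
    return table


def pearson_chi2(table) -> Chi2Result:
    """Classical Pearson chi-square, no continuity correction."""
    table = _validate_table(table)
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    if df == 0:
        return Chi2Result(0.0, 0, 1.0)
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return Chi2Result(float(chi2), int(dof), float(p))


def monte_carlo_chi2(table, n_reps: int = 10_000, seed: int = 0) -> MonteCarloChi2Result:
    """Monte Carlo Pearson chi-square with fixed margins.

    Tables are sampled from the conditional null with exactly the observed
    row and column margins (Patefield's algorithm); the p-value uses the
    add-one estimator (1 + #{chi2* >= chi2}) / (n_reps + 1) so it can never
    be zero.  The Monte Carlo standard error sqrt(p(1-p)/n_reps) is reported.
    """
    table = _validate_table(table)
    if n_reps < 1000:
        raise ParameterError("n_reps must be at least 1000")
    obs = pearson_chi2(table)
    if obs.df == 0:
        return MonteCarloChi2Result(0.0, 0, 1.0, 0.0, n_reps, seed)
    row, col = table.sum(axis=1), table.sum(axis=0)
    expected = np.outer(row, col) / table.sum()
    rng = substream(seed, "monte_carlo_tables")
    dist = stats.random_table(row, col)
    hits = 0
    chunk = 20_000
    done = 0
    thresh = obs.chi2 - 1e-9
    while done < n_reps:
        b = min(chunk, n_reps - done)
        sims = dist.rvs(b, random_state=rng)
        chi2_sim = ((sims - expected) ** 2 / expected).sum(axis=(1, 2))
        hits += int(np.count_nonzero(chi2_sim >= thresh))
        done += b
    p = (1 + hits) / (n_reps + 1)
    return MonteCarloChi2Result(obs.chi2, obs.df, p,
                                math.sqrt(p * (1 - p) / n_reps), n_reps, seed)


def hwe_test(n_hh: int, n_rh: int, n_rr: int) -> HWEResult:
    """Pearson chi-square test of Hardy-Weinberg proportions for a biallelic locus.

    Expected counts come from the observed H-allele frequency
    p = (2 n_HH + n_RH) / 2n; the statistic has one degree of freedom
    (three genotype classes, one estimated allele frequency).
    """
    counts = (n_hh, n_rh, n_rr)
    if any(c < 0 for c in counts):
        raise ParameterError("negative genotype counts")
    n = sum(counts)
    if n == 0:
        raise ParameterError("no subjects")
    p = (2 * n_hh + n_rh) / (2 * n)
    if p in (0.0, 1.0):
        # monomorphic sample is trivially in equilibrium
        return HWEResult(counts, p, 0.0, 1, 1.0)
    expected = np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2]) * n
    chi2 = float((((np.array(counts) - expected) ** 2) / expected).sum())
    return HWEResult(counts, p, chi2, 1, float(stats.chi2.sf(chi2, 1)))


def cohort_homogeneity(
    table_cohort1: GenotypeTable,
    table_cohort2: GenotypeTable,
    status: str = "case",
    n_reps: Optional[int] = None,
    seed: int = 0,
):
    """Chi-square comparison of genotype distributions between two case series.

    A non-significant result licenses pooling the series into one sample.
    Returns the asymptotic result, or the Monte Carlo result when ``n_reps``
    is given.
    """
    if list(table_cohort1.counts.columns) != list(table_cohort2.counts.columns):
        raise ParameterError("cohort tables have different genotype columns")
    stacked = np.vstack([
        table_cohort1.counts.loc[status].to_numpy(),
        table_cohort2.counts.loc[status].to_numpy(),
    ])
    if n_reps is None:
        return pearson_chi2(stacked)
    return monte_carlo_chi2(stacked, n_reps=n_reps, seed=seed)


def onset_age_compare(
    groups: Mapping[str, Sequence[float]],
    n_permutations: int = 10_000,
    seed: Optional[int] = None,
) -> Tuple[PermutationTestResult, pd.DataFrame]:
    """Permutation one-way ANOVA of onset ages across genotype/carrier groups.

    Returns the test result and a per-group table of n, mean and SD
    (rounded to 2 decimals, the display convention for ages).
    """
    if len(groups) < 2:
        raise InsufficientDataError("need at least two onset-age groups")
    for name, ages in groups.items():
        if len(ages) < 2:
            raise InsufficientDataError(f"group {name!r} has fewer than 2 ages")
    res = permutation_f_test([np.asarray(v, float) for v in groups.values()],
                             n_permutations=n_permutations, seed=seed)
    table = pd.DataFrame(
        {
            "n": [len(v) for v in groups.values()],
            "mean": [round(float(np.mean(v)), 2) for v in groups.values()],
            "sd": [round(float(np.std(v, ddof=1)), 2) for v in groups.values()],
        },
        index=list(groups.keys()),
    )
    return res, table


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

DEFAULT_CONTRASTS = (("HH", "RR"), ("HH", "RH"), ("RH", "RR"))


@dataclass
class AssociationResults:
    """Fitted association panels for one stratum; returned by fit()."""

    table: GenotypeTable
    overall: Chi2Result
    overall_mc: Optional[MonteCarloChi2Result]
    contrasts: List[Tuple[str, OddsRatioResult, Chi2Result]]
    hwe_cases: HWEResult
    hwe_controls: HWEResult
    n_reps: Optional[int]
    seed: Optional[int]

    def summary(self) -> str:
        lines = []
        stratum = ", ".join(f"{k}={v}" for k, v in self.table.stratum.items() if v)
        lines.append(f"Case-control association ({stratum or 'all subjects'})")
        lines.append("")
        pct = self.table.percentages()
        for g in self.table.counts.columns:
            case_n = self.table.counts.loc["case", g]
            ctl_n = self.table.counts.loc["control", g]
            lines.append(
                f"  {g}: cases {case_n} ({pct.loc['case', g]}%)  "
                f"controls {ctl_n} ({pct.loc['control', g]}%)"
            )
        lines.append(
            f"  overall chi2 = {self.overall.chi2:.3f} (df {self.overall.df}), "
            f"p = {self.overall.p_asymptotic:.3f}"
            + (
                f", MC p = {self.overall_mc.p_monte_carlo:.4f} "
                f"(n_reps {self.overall_mc.n_reps}, seed {self.overall_mc.seed})"
                if self.overall_mc else ""
            )
        )
        for name, orr, chi in self.contrasts:
            lo, hi = orr.ci95
            lines.append(
                f"  {name}: OR = {orr.odds_ratio:.3f} ({lo:.3f}-{hi:.3f}), "
                f"p = {chi.p_asymptotic:.3f}"
                + ("  [Haldane +0.5]" if orr.haldane_corrected else "")
            )
        lines.append(
            f"  HWE: cases chi2 = {self.hwe_cases.chi2:.3f} (p = {self.hwe_cases.p:.3f}); "
            f"controls chi2 = {self.hwe_controls.chi2:.3f} (p = {self.hwe_controls.p:.3f})"
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "stratum": self.table.stratum,
            "counts": {
                status: {g: int(self.table.counts.loc[status, g])
                         for g in self.table.counts.columns}
                for status in self.table.counts.index
            },
            "percentages": {
                status: {g: float(self.table.percentages().loc[status, g])
                         for g in self.table.counts.columns}
                for status in self.table.counts.index
            },
            "overall": {
                "chi2": self.overall.chi2, "df": self.overall.df,
                "p": self.overall.p_asymptotic,
            },
            "contrasts": {
                name: {
                    "odds_ratio": orr.odds_ratio,
                    "ci95": list(orr.ci95),
                    "p": chi.p_asymptotic,
                    "haldane": orr.haldane_corrected,
                }
                for name, orr, chi in self.contrasts
            },
            "hwe": {
                "cases": {"chi2": self.hwe_cases.chi2, "p": self.hwe_cases.p},
                "controls": {"chi2": self.hwe_controls.chi2, "p": self.hwe_controls.p},
            },
        }
        if self.overall_mc is not None:
            out["overall"]["monte_carlo"] = {
                "p": self.overall_mc.p_monte_carlo,
                "stderr": self.overall_mc.mc_stderr,
                "n_reps": self.overall_mc.n_reps,
                "seed": self.overall_mc.seed,
            }
        return out


class CaseControlAssociation:
    """Genotype association model for one case-control stratum.

    Build from :class:`SubjectRecord` lists (``CaseControlAssociation(subjects)``),
    a DataFrame (`from_dataframe`), or directly from a counts table
    (`from_counts`); ``fit()`` computes the genotype table, overall and
    pairwise chi-square tests, odds ratios and Hardy-Weinberg panels.
    """

    def __init__(self, subjects: Sequence[SubjectRecord],
                 sex: Optional[str] = None, a02: Optional[str] = None):
        self.table = tabulate(subjects, sex=sex, a02=a02)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "CaseControlAssociation":
        from .io import subjects_from_dataframe

        return cls(subjects_from_dataframe(df), **kwargs)

    @classmethod
    def from_counts(cls, counts: pd.DataFrame,
                    stratum: Optional[dict] = None) -> "CaseControlAssociation":
        obj = cls.__new__(cls)
        obj.table = GenotypeTable(counts=counts, stratum=stratum or {})
        return obj

    def fit(
        self,
        contrasts: Sequence[Tuple[str, str]] = DEFAULT_CONTRASTS,
        n_reps: Optional[int] = None,
        seed: int = 0,
    ) -> AssociationResults:
        counts = self.table.counts
        overall = pearson_chi2(counts.to_numpy())
        overall_mc = (
            monte_carlo_chi2(counts.to_numpy(), n_reps=n_reps, seed=seed)
            if n_reps else None
        )
        results = []
        for g1, g2 in contrasts:
            a = counts.loc["case", g1]
            b = counts.loc["case", g2]
            c = counts.loc["control", g1]
            d = counts.loc["control", g2]
            orr = odds_ratio(a, b, c, d, comparison=f"{g1} vs {g2}")
            chi = pearson_chi2(np.array([[a, b], [c, d]]))
            results.append((f"{g1} vs {g2}", orr, chi))
        hwe_cases = hwe_test(*(int(counts.loc["case", g]) for g in GENOTYPE_ORDER))
        hwe_controls = hwe_test(*(int(counts.loc["control", g]) for g in GENOTYPE_ORDER))
        return AssociationResults(self.table, overall, overall_mc, results,
                                  hwe_cases, hwe_controls, n_reps, seed)
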