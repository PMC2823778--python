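"""Specific production (SP) of proteasomal fragments and its group comparisons.

SP is the mass-spectrometry signal of a fragment divided by the signal of
substrate consumed at the same time, times 1000:

    SP = 1000 * fragment_signal / (S(0) - S(t))

It estimates the number of fragment molecules produced per digested substrate
molecule (up to a fragment-specific detector factor).  Because both signals
come from the same run, the per-set detector scale cancels, and samples are
comparable within a degradation set; comparisons across sets go through
within-set z-score standardization.

Samples are binned by the fraction of substrate consumed (<25%, 25-35%,
35-50%); samples at >=50% consumption are excluded, which keeps re-entry of
products into the proteasome core negligible.  Group comparisons: Student t
(H-carrier vs non-carrier), permutation ANOVA (three genotypes), exact
Mann-Whitney (PA28 effect), with Levene's check of variance homogeneity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, ParameterError, UndefinedSPError
from .kinetics import DigestionExperiment, fraction_consumed
from .permutation import exact_mann_whitney, permutation_f_test

logger = logging.getLogger(__name__)

#: Consumption bins, half-open [low, high); >=0.5 is excluded from analysis.
BINS: Dict[str, Tuple[float, float]] = {
    "lt25": (0.0, 0.25),
    "b25_35": (0.25, 0.35),
    "b35_50": (0.35, 0.50),
}
EXCLUDED = "excluded"
EPITOPE_FRAGMENT = "10-18"


@dataclass(frozen=True)
class SPEstimate:
    """SP of one fragment in one sample, with its consumption bin."""

    set_id: str
    preparation_id: str
    lmp2_genotype: str
    pa28: bool
    fragment_name: str
    time: float
    sp: float
    consumption: float
    bin: str
    sp_standardized: Optional[float] = None

    @property
    def is_h_carrier(self) -> bool:
        return self.lmp2_genotype in ("RH", "HH")


@dataclass(frozen=True)
class GroupComparisonResult:
    """A two- or k-group comparison of SP (or any sample statistic)."""

    statistic_name: str  # "t", "F", "U" or "W_levene"
    statistic_value: float
    p: float
    groups: tuple
    n_per_group: tuple
    percent_decrease: Optional[float] = None
    levene_p: Optional[float] = None
    method: Optional[str] = None


def compute_sp(fragment_signal: float, substrate_consumed_signal: float) -> float:
    """SP = 1000 * fragment / consumed-substrate signal."""
    if fragment_signal < 0:
        raise ParameterError("fragment signal must be non-negative")
    if substrate_consumed_signal <= 0:
        raise UndefinedSPError("no substrate consumed; SP undefined")
    return 1000.0 * fragment_signal / substrate_consumed_signal


def assign_bin(consumption: float) -> str:
    """Map a consumption fraction to its analysis bin (>=0.5 -> excluded)."""
    if not 0.0 <= consumption <= 1.0:
        raise ParameterError(f"consumption {consumption} outside [0, 1]")
    for name, (lo, hi) in BINS.items():
        if lo <= consumption < hi:
            return name
    return EXCLUDED


def sp_estimates(experiments: Sequence[DigestionExperiment]) -> List[SPEstimate]:
    """Compute SP for every fragment at every t>0 sample of each experiment.

    Timepoints where no substrate was consumed (observed consumption 0 after
    clamping) carry no SP and are skipped with a log message.
    """
    out: List[SPEstimate] = []
    for exp in experiments:
        s0 = exp.substrate_at(0.0)
        for i, t in enumerate(exp.times):
            if t == 0.0:
                continue
            consumed = s0 - exp.substrate_signal[i]
            if consumed <= 0:
                logger.info(
                    "no measurable consumption at t=%g in %s; SP skipped",
                    t, exp.preparation_id,
                )
                continue
            frac = fraction_consumed(exp, t)
            for name, sig in exp.fragment_signals.items():
                out.append(
                    SPEstimate(
                        set_id=exp.set_id,
                        preparation_id=exp.preparation_id,
                        lmp2_genotype=exp.lmp2_genotype,
                        pa28=exp.pa28,
                        fragment_name=name,
                        time=float(t),
                        sp=compute_sp(float(sig[i]), float(consumed)),
                        consumption=frac,
                        bin=assign_bin(frac),
                    )
                )
    return out


def standardize_within_set(estimates: Sequence[SPEstimate]) -> List[SPEstimate]:
    """Z-score SP within each degradation set x fragment (sample SD, ddof=1).

    Sets with fewer than two estimates for a fragment, or with zero within-set
    variance, are passed through unstandardized with a warning.
    """
    df = pd.DataFrame(
        {
            "set_id": [e.set_id for e in estimates],
            "fragment": [e.fragment_name for e in estimates],
            "sp": [e.sp for e in estimates],
        }
    )
    out: List[SPEstimate] = []
    grouped = df.groupby(["set_id", "fragment"])["sp"]
    means = grouped.transform("mean")
    sds = grouped.transform("std")  # ddof=1; NaN for singleton groups
    for i, est in enumerate(estimates):
        sd = sds.iloc[i]
        if not np.isfinite(sd) or sd == 0:
            logger.warning(
                "set %s fragment %s: zero or undefined within-set variance; "
                "estimate passed through unstandardized",
                est.set_id, est.fragment_name,
            )
            out.append(est)
        else:
            out.append(replace(est, sp_standardized=(est.sp - means.iloc[i]) / sd))
    return out


def _select(
    estimates: Sequence[SPEstimate],
    bin: str,
    pa28: bool,
    fragment: str = EPITOPE_FRAGMENT,
) -> List[SPEstimate]:
    if bin not in BINS:
        raise ParameterError(f"unknown analysis bin {bin!r}")
    return [
        e for e in estimates
        if e.bin == bin and e.pa28 == pa28 and e.fragment_name == fragment
    ]


def _values(ests: Sequence[SPEstimate], standardized: bool) -> np.ndarray:
    if standardized:
        vals = [e.sp_standardized for e in ests]
        if any(v is None for v in vals):
            raise ParameterError("standardized comparison requested before standardization")
        return np.asarray(vals, dtype=float)
    return np.asarray([e.sp for e in ests], dtype=float)


def levene_test(groups: Sequence[Sequence[float]]) -> GroupComparisonResult:
    """Levene's test (deviations from group means) for variance homogeneity."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise InsufficientDataError("Levene's test needs >=2 groups with n>=2")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if all(np.ptp(a) == 0 for a in arrays):
        # all groups constant: no dispersion anywhere, trivially homogeneous
        return GroupComparisonResult(
            "W_levene", 0.0, 1.0,
            tuple(range(len(groups))), tuple(len(g) for g in groups),
        )
    w, p = stats.levene(*arrays, center="mean")
    return GroupComparisonResult(
        "W_levene", float(w), float(p),
        tuple(range(len(groups))), tuple(len(g) for g in groups),
    )


def compare_sp_by_genotype(
    estimates: Sequence[SPEstimate],
    bin: str,
    mode: str = "h_carrier_t",
    pa28: bool = True,
    fragment: str = EPITOPE_FRAGMENT,
    use_standardized: bool = False,
    welch: bool = False,
    n_permutations: int = 10_000,
    seed: Optional[int] = None,
) -> GroupComparisonResult:
    """Genotype effect on SP within one consumption bin and PA28 condition.

    ``h_carrier_t`` pools RH+HH against RR and runs a two-sided Student t test
    (pooled variance; Welch behind the ``welch`` flag), preceded by Levene's
    homogeneity check whose p is recorded.  ``three_group_mc_anova`` runs the
    permutation F test across RR/RH/HH.  ``percent_decrease`` is always
    computed from unstandardized SP means so it reads as a yield ratio.
    """
    sel = _select(estimates, bin, pa28, fragment)
    if mode == "h_carrier_t":
        carriers = [e for e in sel if e.is_h_carrier]
        noncarriers = [e for e in sel if not e.is_h_carrier]
        if len(carriers) < 2 or len(noncarriers) < 2:
            raise InsufficientDataError(
                f"bin {bin!r}: need >=2 estimates per carrier group "
                f"(have {len(noncarriers)} RR, {len(carriers)} H-carrier)"
            )
        xc = _values(carriers, use_standardized)
        xn = _values(noncarriers, use_standardized)
        lev = levene_test([xc, xn])
        scale = max(np.abs(xc).max(), np.abs(xn).max(), 1e-300)
        if np.std(xc) <= 1e-9 * scale and np.std(xn) <= 1e-9 * scale:
            # both groups (numerically) constant: t is 0 or +/-inf by sign
            diff = xc.mean() - xn.mean()
            if abs(diff) <= 1e-9 * scale:
                t, p = 0.0, 1.0
            else:
                t, p = math.copysign(math.inf, diff), 0.0
        else:
            t, p = stats.ttest_ind(xc, xn, equal_var=not welch)
        pdec = percent_decrease(sel)
        return GroupComparisonResult(
            "t", float(t), float(p), ("H-carrier", "RR"), (len(xc), len(xn)),
            percent_decrease=pdec, levene_p=lev.p,
            method="welch_t" if welch else "pooled_t",
        )
    if mode == "three_group_mc_anova":
        groups = []
        labels = []
        for g in ("RR", "RH", "HH"):
            vals = _values([e for e in sel if e.lmp2_genotype == g], use_standardized)
            if len(vals) < 2:
                raise InsufficientDataError(f"genotype {g} has <2 estimates in bin {bin!r}")
            groups.append(vals)
            labels.append(g)
        res = permutation_f_test(groups, n_permutations=n_permutations, seed=seed)
        return GroupComparisonResult(
            "F", res.statistic, res.p_value, tuple(labels),
            tuple(len(g) for g in groups),
            percent_decrease=percent_decrease(sel), method=res.method,
        )
    raise ParameterError(f"unknown comparison mode {mode!r}")


def percent_decrease(estimates: Sequence[SPEstimate]) -> float:
    """100 * (1 - mean SP of H-carriers / mean SP of non-carriers), raw SP."""
    carrier = [e.sp for e in estimates if e.is_h_carrier]
    noncarrier = [e.sp for e in estimates if not e.is_h_carrier]
    if not carrier or not noncarrier:
        raise InsufficientDataError("both carrier groups needed for percent decrease")
    return 100.0 * (1.0 - np.mean(carrier) / np.mean(noncarrier))


def compare_sp_pa28(
    estimates_with: Sequence[float],
    estimates_without: Sequence[float],
) -> GroupComparisonResult:
    """Effect of PA28 on SP: exact two-sided Mann-Whitney U."""
    res = exact_mann_whitney(estimates_with, estimates_without)
    return GroupComparisonResult(
        "U", res.statistic, res.p_value, ("PA28+", "PA28-"), res.n_per_group,
        method=res.method,
    )


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------


@dataclass
class DigestionStudyResults:
    """Fitted kinetics and SP panels for a digestion experiment set."""

    kinetics: pd.DataFrame  # per set: k1, s0, r2
    estimates: List[SPEstimate]
    k1_anova: object  # PermutationTestResult across genotypes, PA28 present
    genotype_panels: Dict[str, Dict[str, GroupComparisonResult]]  # pa28 -> bin -> t
    pa28_panels: Dict[str, GroupComparisonResult]  # fragment -> Mann-Whitney
    seed: Optional[int]

    def summary(self) -> str:
        lines = ["Digestion study", ""]
        lines.append("K1 by genotype (PA28 present): "
                     f"F = {self.k1_anova.statistic:.3f}, p = {self.k1_anova.p_value:.3f}")
        for frag, res in self.pa28_panels.items():
            lines.append(
                f"PA28 effect on SP({frag}): U = {res.statistic_value:g}, "
                f"p = {res.p:.4g} [{res.method}]"
            )
        for cond, panels in self.genotype_panels.items():
            for bin_name, res in panels.items():
                lines.append(
                    f"H-carrier effect, {cond}, bin {bin_name}: "
                    f"t = {res.statistic_value:.2f}, p = {res.p:.4g}, "
                    f"decrease = {res.percent_decrease:.1f}%"
                )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        def _cmp(res: GroupComparisonResult) -> dict:
            d = {
                "statistic": res.statistic_name,
                "value": res.statistic_value,
                "p": res.p,
                "n_per_group": list(res.n_per_group),
            }
            if res.percent_decrease is not None:
                d["percent_decrease"] = res.percent_decrease
            if res.levene_p is not None:
                d["levene_p"] = res.levene_p
            return d

        return {
            "k1": self.kinetics.to_dict(orient="records"),
            "k1_anova": {"F": self.k1_anova.statistic, "p": self.k1_anova.p_value,
                         "method": self.k1_anova.method},
            "pa28_effect": {f: _cmp(r) for f, r in self.pa28_panels.items()},
            "genotype_effect": {
                cond: {b: _cmp(r) for b, r in panels.items()}
                for cond, panels in self.genotype_panels.items()
            },
            "seed": self.seed,
        }


class DigestionStudy:
    """The full digestion analysis: kinetics fits, SP, bins, group tests.

    Parameters
    ----------
    experiments : sequence of DigestionExperiment
        Typically read with :func:`lmp2ms.io.read_digestion` or generated by
        :func:`lmp2ms.simulate.simulate_digestion`.
    """

    def __init__(self, experiments: Sequence[DigestionExperiment]):
        if not experiments:
            raise InsufficientDataError("no digestion experiments")
        self.experiments = list(experiments)

    @classmethod
    def from_csv(cls, path) -> "DigestionStudy":
        from .io import read_digestion

        return cls(read_digestion(path))

    def fit(
        self,
        n_permutations: int = 10_000,
        seed: Optional[int] = None,
        use_standardized: bool = False,
    ) -> DigestionStudyResults:
        from .kinetics import fit_first_order, compare_k1

        fits = {}
        rows = []
        for exp in self.experiments:
            fit = fit_first_order(exp)
            fits[exp.set_id] = fit
            rows.append(
                {
                    "set_id": exp.set_id,
                    "preparation_id": exp.preparation_id,
                    "genotype": exp.lmp2_genotype,
                    "pa28": exp.pa28,
                    "k1": fit.k1,
                    "s0": fit.s0,
                    "r_squared": fit.r_squared,
                }
            )
        kin = pd.DataFrame(rows)

        by_genotype = {
            g: [fits[e.set_id] for e in self.experiments
                if e.lmp2_genotype == g and e.pa28]
            for g in ("RR", "RH", "HH")
        }
        by_genotype = {g: f for g, f in by_genotype.items() if len(f) >= 2}
        k1_anova = compare_k1(by_genotype, n_permutations=n_permutations, seed=seed)

        ests = standardize_within_set(sp_estimates(self.experiments))

        genotype_panels: Dict[str, Dict[str, GroupComparisonResult]] = {}
        for pa28, cond in ((True, "pa28_present"), (False, "pa28_absent")):
            panels = {}
            for bin_name in BINS:
                try:
                    panels[bin_name] = compare_sp_by_genotype(
                        ests, bin_name, mode="h_carrier_t", pa28=pa28,
                        use_standardized=use_standardized,
                    )
                except InsufficientDataError:
                    continue
            genotype_panels[cond] = panels

        pa28_panels = {}
        for frag in sorted({e.fragment_name for e in ests}):
            with_ = [e.sp for e in ests if e.fragment_name == frag and e.pa28
                     and e.bin != EXCLUDED]
            without = [e.sp for e in ests if e.fragment_name == frag and not e.pa28
                       and e.bin != EXCLUDED]
            if with_ and without:
                # one value per preparation: average SP over its retained samples
                pa28_panels[frag] = compare_sp_pa28(
                    _per_preparation_means(ests, frag, True),
                    _per_preparation_means(ests, frag, False),
                )
        return DigestionStudyResults(kin, ests, k1_anova, genotype_panels,
                                     pa28_panels, seed)


def _per_preparation_means(
    estimates: Sequence[SPEstimate], fragment: str, pa28: bool
) -> List[float]:
    """Mean retained-bin SP per preparation (the paper's per-sample unit)."""
    by_prep: Dict[str, List[float]] = {}
    for e in estimates:
        if e.fragment_name == fragment and e.pa28 == pa28 and e.bin != EXCLUDED:
            by_prep.setdefault(e.preparation_id, []).append(e.sp)
    return [float(np.mean(v)) for v in by_prep.values()]
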