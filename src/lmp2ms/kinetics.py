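"""First-order degradation kinetics of proteasomal substrate digestion.

A digestion time-course follows S(t) = S0 * exp(-K1 * t) under first-order
kinetics.  With multiplicative (lognormal) measurement noise the log-linear
least-squares fit of ln S(t) on t is the maximum-likelihood estimator of K1,
so that is what :class:`FirstOrderDecay` does — no iterative nonlinear
refinement, no convergence failures.

The module also computes the fraction of substrate consumed at each sampled
time (the quantity the specific-production analysis bins on) and compares
fitted K1 values across genotype groups with a permutation ANOVA.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np

from .exceptions import DegenerateDecayError, InsufficientDataError, ParameterError
from .permutation import PermutationTestResult, permutation_f_test

logger = logging.getLogger(__name__)

#: 28-mer myelin basic protein substrate (MBP 102-129); positions 10-18 are
#: the HLA-A*0201-restricted epitope MBP 111-119 (SLSRFSWGA).
MBP_102_129 = "PSQGKGRGLSLSRFSWGAEGQRPGFGYG"

#: Default fragment tiling of the 28-mer: N-flank, epitope, C-flank.
DEFAULT_FRAGMENTS: Dict[str, Tuple[int, int]] = {
    "1-9": (1, 9),
    "10-18": (10, 18),
    "19-28": (19, 28),
}

GENOTYPES = ("RR", "RH", "HH")


@dataclass
class DigestionExperiment:
    """One proteasome preparation x PA28 condition digestion time-course.

    Parameters
    ----------
    set_id : str
        Degradation-set (batch) identifier; signals within a set share one
        detector scale factor.
    preparation_id : str
        Identifier of the purified 20S proteasome preparation.
    lmp2_genotype : {"RR", "RH", "HH"}
        LMP2 codon-60 genotype of the source cell line.
    pa28 : bool
        Whether the PA28-alpha/beta activator was present.
    times : array of float
        Sampling times in minutes; must include 0.
    substrate_signal : array of float
        Quantified substrate MS signal at each time; positive at t=0.
    fragment_signals : mapping of fragment name -> array of float
        Quantified fragment MS signals, same length as ``times``.
    """

    set_id: str
    preparation_id: str
    lmp2_genotype: str
    pa28: bool
    times: np.ndarray
    substrate_signal: np.ndarray
    fragment_signals: Dict[str, np.ndarray]
    substrate_sequence: str = MBP_102_129
    fragment_coords: Dict[str, Tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_FRAGMENTS)
    )

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.substrate_signal = np.asarray(self.substrate_signal, dtype=float)
        self.fragment_signals = {
            k: np.asarray(v, dtype=float) for k, v in self.fragment_signals.items()
        }
        if self.lmp2_genotype not in GENOTYPES:
            raise ParameterError(f"unknown LMP2 genotype {self.lmp2_genotype!r}")
        if self.times.shape != self.substrate_signal.shape:
            raise ParameterError("times and substrate_signal length mismatch")
        for name, sig in self.fragment_signals.items():
            if sig.shape != self.times.shape:
                raise ParameterError(f"fragment {name!r} signal length mismatch")
        if not np.any(self.times == 0.0):
            raise ParameterError("time-course must include t=0")
        if self.substrate_signal[self.times == 0.0][0] <= 0:
            raise ParameterError("substrate signal at t=0 must be positive")
        L = len(self.substrate_sequence)
        for name, (lo, hi) in self.fragment_coords.items():
            if not (1 <= lo <= hi <= L):
                raise ParameterError(
                    f"fragment {name!r} coordinates ({lo},{hi}) outside 1..{L}"
                )

    @property
    def is_h_carrier(self) -> bool:
        """True when the preparation carries at least one 60H allele."""
        return self.lmp2_genotype in ("RH", "HH")

    def substrate_at(self, time: float) -> float:
        mask = self.times == time
        if not np.any(mask):
            raise ParameterError(f"time {time} not sampled in {self.preparation_id}")
        return float(self.substrate_signal[mask][0])


@dataclass(frozen=True)
class KineticsFit:
    """Log-linear least-squares estimate of the first-order rate constant."""

    k1: float
    s0: float
    r_squared: float
    k1_stderr: float
    n_points: int

    def summary(self) -> str:
        return (
            f"K1 = {self.k1:.5g} /min (SE {self.k1_stderr:.3g}), "
            f"S0 = {self.s0:.5g}, R^2 = {self.r_squared:.4f}, n = {self.n_points}"
        )


class FirstOrderDecay:
    """Model S(t) = S0 exp(-K1 t), fitted by least squares on ln S.

    Timepoints with non-positive signal are dropped from the fit (the log is
    undefined there).  K1 is constrained to be non-negative: an upward drift
    in the signal fits best as no decay, and the slope is clamped at zero.
    """

    def __init__(self, times: Sequence[float], signal: Sequence[float]):
        self.times = np.asarray(times, dtype=float)
        self.signal = np.asarray(signal, dtype=float)
        if self.times.shape != self.signal.shape:
            raise ParameterError("times and signal must have the same length")

    def fit(self) -> KineticsFit:
        keep = self.signal > 0
        t = self.times[keep]
        y = np.log(self.signal[keep])
        if np.count_nonzero(self.signal[self.times > 0] > 0) == 0:
            raise DegenerateDecayError("no positive substrate signal after t=0")
        if len(t) < 3:
            raise InsufficientDataError(
                f"need >=3 positive-signal timepoints, have {len(t)}"
            )
        n = len(t)
        tbar, ybar = t.mean(), y.mean()
        sxx = float(np.sum((t - tbar) ** 2))
        sxy = float(np.sum((t - tbar) * (y - ybar)))
        slope = sxy / sxx
        intercept = ybar - slope * tbar
        resid = y - (intercept + slope * t)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((y - ybar) ** 2))
        r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
        se = math.sqrt(ss_res / (n - 2) / sxx) if n > 2 else math.nan
        k1 = max(0.0, -slope)
        if slope > 0:
            logger.warning("signal drifts upward; K1 clamped to 0")
        return KineticsFit(k1=k1, s0=math.exp(intercept), r_squared=r2,
                           k1_stderr=se, n_points=n)


def fit_first_order(experiment: DigestionExperiment) -> KineticsFit:
    """Fit the first-order rate constant K1 to an experiment's substrate decay."""
    return FirstOrderDecay(experiment.times, experiment.substrate_signal).fit()


def fraction_consumed(experiment: DigestionExperiment, time: float) -> float:
    """Fraction of substrate consumed at ``time``: 1 - S(t)/S(0), clamped to [0,1].

    Uses the observed signals (not fitted values), so the per-set detector
    factor cancels exactly.
    """
    s0 = experiment.substrate_at(0.0)
    st = experiment.substrate_at(time)
    frac = 1.0 - st / s0
    if frac < 0.0:
        logger.warning(
            "substrate signal at t=%g exceeds t=0 signal (%s); consumption clamped to 0",
            time, experiment.preparation_id,
        )
        return 0.0
    return min(frac, 1.0)


def compare_k1(
    fits_by_group: Mapping[str, Sequence[KineticsFit]],
    n_permutations: int = 10_000,
    seed: Optional[int] = None,
) -> PermutationTestResult:
    """Permutation one-way ANOVA of fitted K1 values across genotype groups."""
    if len(fits_by_group) < 2:
        raise InsufficientDataError("need at least two genotype groups")
    for name, fits in fits_by_group.items():
        if len(fits) < 2:
            raise InsufficientDataError(f"group {name!r} has fewer than 2 fits")
    groups = [np.array([f.k1 for f in fits]) for fits in fits_by_group.values()]
    return permutation_f_test(groups, n_permutations=n_permutations, seed=seed)
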