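"""Permutation and enumeration tests used throughout the pipeline.

Two primitives live here:

* a one-way permutation ANOVA (the "Monte Carlo ANOVA" used for genotype
  effects on kinetic constants, specific production and onset age), which
  switches automatically to exhaustive enumeration of label arrangements
  when that is feasible, and
* an exact two-sided Mann-Whitney U test by complete enumeration of group
  assignments, with a normal approximation (tie-corrected) fallback for
  larger samples.

Both return :class:`PermutationTestResult` so downstream reporting is uniform.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .exceptions import InsufficientDataError
from ._rand import substream

__all__ = [
    "PermutationTestResult",
    "f_oneway_statistic",
    "permutation_f_test",
    "mann_whitney_u",
    "exact_mann_whitney",
]

_FLOAT_TIE_TOL = 1e-12


@dataclass(frozen=True)
class PermutationTestResult:
    """Outcome of a permutation or enumeration test."""

    statistic_name: str
    statistic: float
    p_value: float
    n_groups: int
    n_per_group: tuple
    method: str  # "exhaustive", "monte_carlo", or "asymptotic"
    n_permutations: Optional[int] = None
    seed: Optional[int] = None


def f_oneway_statistic(groups: Sequence[np.ndarray]) -> float:
    """Classical one-way ANOVA F statistic.

    Zero within-group variance with a between-group difference yields
    ``inf``; no between-group difference yields 0.
    """
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    n = ns.sum()
    means = np.array([np.mean(g) for g in groups])
    grand = np.concatenate(groups).mean()
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(np.sum((g - m) ** 2) for g, m in zip(groups, means)))
    if ssw == 0.0:
        return 0.0 if ssb == 0.0 else math.inf
    return (ssb / (k - 1)) / (ssw / (n - k))


def _f_from_positions(values: np.ndarray, sizes: Sequence[int], sq_total: float) -> float:
    """F statistic when `values` is already ordered so groups are contiguous."""
    k = len(sizes)
    n = len(values)
    grand = values.mean()
    ssb = 0.0
    ssw_total = sq_total - n * grand**2  # total SS
    start = 0
    for size in sizes:
        m = values[start : start + size].mean()
        ssb += size * (m - grand) ** 2
        start += size
    ssw = ssw_total - ssb
    if ssw <= _FLOAT_TIE_TOL * max(1.0, sq_total):
        return 0.0 if ssb <= _FLOAT_TIE_TOL * max(1.0, sq_total) else math.inf
    return (ssb / (k - 1)) / (ssw / (n - k))


def _n_arrangements(sizes: Sequence[int]) -> int:
    total = sum(sizes)
    count = math.factorial(total)
    for s in sizes:
        count //= math.factorial(s)
    return count


def _iter_partitions(indices: tuple, sizes: Sequence[int]):
    """Yield all distinct assignments of `indices` into groups of given sizes."""
    if len(sizes) == 1:
        yield (indices,)
        return
    for first in itertools.combinations(indices, sizes[0]):
        chosen = set(first)
        rest = tuple(i for i in indices if i not in chosen)
        for tail in _iter_partitions(rest, sizes[1:]):
            yield (first,) + tail


def permutation_f_test(
    groups: Sequence[Sequence[float]],
    n_permutations: int = 10_000,
    seed: Optional[int] = None,
    exhaustive_limit: int = 1_000_000,
) -> PermutationTestResult:
    """One-way permutation ANOVA on group labels.

    The p-value is the fraction of label arrangements whose F statistic is at
    least the observed one.  All arrangements are enumerated when their number
    does not exceed ``exhaustive_limit``; otherwise ``n_permutations`` random
    relabellings are drawn and the add-one estimator
    ``(1 + #{F* >= F}) / (n + 1)`` is used.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise InsufficientDataError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise InsufficientDataError("empty group in permutation ANOVA")
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    sq_total = float(np.sum(pooled**2))
    f_obs = _f_from_positions(pooled, sizes, sq_total)
    thresh = f_obs - _FLOAT_TIE_TOL * max(1.0, abs(f_obs))

    n_arr = _n_arrangements(sizes)
    if n_arr <= exhaustive_limit:
        hits = 0
        idx = tuple(range(len(pooled)))
        for parts in _iter_partitions(idx, sizes):
            order = [i for part in parts for i in part]
            f = _f_from_positions(pooled[order], sizes, sq_total)
            if f >= thresh:
                hits += 1
        return PermutationTestResult(
            "F", f_obs, hits / n_arr, len(groups), tuple(sizes), "exhaustive", n_arr, None
        )

    rng = substream(seed, "permutation") if seed is not None else np.random.default_rng()
    hits = 0
    # vectorised batches of permutations
    batch = 2_000
    done = 0
    n = len(pooled)
    while done < n_permutations:
        b = min(batch, n_permutations - done)
        order = np.argsort(rng.random((b, n)), axis=1)
        perm = pooled[order]
        grand = perm.mean(axis=1)
        ssb = np.zeros(b)
        start = 0
        for size in sizes:
            m = perm[:, start : start + size].mean(axis=1)
            ssb += size * (m - grand) ** 2
            start += size
        sst = (perm**2).sum(axis=1) - n * grand**2
        ssw = sst - ssb
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ssb / (len(sizes) - 1)) / (ssw / (n - len(sizes)))
        f = np.where(ssw <= _FLOAT_TIE_TOL * max(1.0, sq_total),
                     np.where(ssb <= _FLOAT_TIE_TOL * max(1.0, sq_total), 0.0, np.inf),
                     f)
        hits += int(np.count_nonzero(f >= thresh))
        done += b
    p = (1 + hits) / (n_permutations + 1)
    return PermutationTestResult(
        "F", f_obs, p, len(groups), tuple(sizes), "monte_carlo", n_permutations, seed
    )


def _average_ranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple:
    """Return (U1, U_min): U of the first sample and the conventional min(U1, U2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    ranks = _average_ranks(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2
    return u1, min(u1, n1 * n2 - u1)


def exact_mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    enumeration_limit: int = 24,
) -> PermutationTestResult:
    """Two-sided Mann-Whitney U test, exact by enumeration for small samples.

    For total n up to ``enumeration_limit`` all C(n, n1) assignments of the
    pooled observed values to the two groups are enumerated (ties handled
    naturally because observed values, with their tied ranks, are permuted);
    the two-sided p-value counts assignments whose U deviates from its null
    mean n1*n2/2 at least as much as the observed U.  Larger samples fall back
    to the tie-corrected normal approximation.

    The reported statistic is min(U1, U2), the conventional "U".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise InsufficientDataError("empty group in Mann-Whitney test")
    u1_obs, u_min = mann_whitney_u(x, y)
    mu = n1 * n2 / 2
    dev_obs = abs(u1_obs - mu)

    if n1 + n2 <= enumeration_limit:
        ranks = _average_ranks(np.concatenate([x, y]))
        offset = n1 * (n1 + 1) / 2
        total = math.comb(n1 + n2, n1)
        hits = 0
        for combo in itertools.combinations(range(n1 + n2), n1):
            u1 = ranks[list(combo)].sum() - offset
            if abs(u1 - mu) >= dev_obs - _FLOAT_TIE_TOL * max(1.0, dev_obs):
                hits += 1
        return PermutationTestResult(
            "U", u_min, hits / total, 2, (n1, n2), "exhaustive", total, None
        )

    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return PermutationTestResult("U", u_min, float(res.pvalue), 2, (n1, n2), "asymptotic")
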