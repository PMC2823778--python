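"""Pairwise linkage disequilibrium between unphased biallelic loci.

Haplotype frequencies are estimated by EM over the single ambiguous class
(the double heterozygote, whose two gametes are either AB|ab or Ab|aB);
from the fitted frequencies the module computes the raw disequilibrium
coefficient D = p_AB - p_A p_B, Lewontin's normalized D', and the squared
allele correlation r^2.  Significance is available as the standard
chi-square approximation chi2 = 2n * r^2 on 2n chromosomes.

Genotypes are encoded as copies of the reference allele (0, 1 or 2).
Dominant carrier-status markers (e.g. HLA-A*02 carried yes/no) do not reveal
allele counts; :func:`genotypes_from_carrier` codes carriers as single-copy
heterozygotes, an approximation appropriate at moderate allele frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .exceptions import MonomorphicLocusError, ParameterError

_GENO_STR = {0: ("aa", "bb"), 1: ("Aa", "Bb"), 2: ("AA", "BB")}


@dataclass(frozen=True)
class LDEstimate:
    """EM haplotype frequencies and derived LD statistics for a locus pair."""

    hap_freqs: Tuple[float, float, float, float]  # (p_AB, p_Ab, p_aB, p_ab)
    d: float
    d_prime: float
    r2: float
    log_likelihood: float
    n_iterations: int
    converged: bool
    n_subjects: int

    @property
    def allele_freqs(self) -> Tuple[float, float]:
        p_ab_, p_abar, p_abarb, _ = self.hap_freqs
        return (p_ab_ + p_abar, p_ab_ + p_abarb)  # (p_A, p_B)

    def chi2_test(self) -> Tuple[float, float]:
        """LD significance: chi2 = 2n r^2 on 1 df over 2n chromosomes."""
        chi2 = 2 * self.n_subjects * self.r2
        return chi2, float(stats.chi2.sf(chi2, 1))

    def summary(self) -> str:
        p_ab, p_abar, p_abarb, p_abarbbar = self.hap_freqs
        chi2, p = self.chi2_test()
        return (
            f"haplotypes: AB {p_ab:.4f}  Ab {p_abar:.4f}  "
            f"aB {p_abarb:.4f}  ab {p_abarbbar:.4f}\n"
            f"D = {self.d:.4f}  D' = {self.d_prime:.4f}  r2 = {self.r2:.4f}\n"
            f"chi2(1) = {chi2:.3f}, p = {p:.4f}  "
            f"[EM: {self.n_iterations} iter, logL = {self.log_likelihood:.4f}]"
        )


def _genotype_counts(geno1: np.ndarray, geno2: np.ndarray) -> np.ndarray:
    """3x3 table n[i, j] = #subjects with i copies of A and j copies of B."""
    table = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            table[i, j] = np.count_nonzero((geno1 == i) & (geno2 == j))
    return table


def class_probs(p_ab: float, p_abar: float, p_abarb: float, p_abarbbar: float) -> np.ndarray:
    """Multinomial probabilities of the nine two-locus genotype classes.

    Entry [i, j]: probability of carrying i copies of A and j of B, under
    random union of gametes.
    """
    h = np.array([p_ab, p_abar, p_abarb, p_abarbbar])
    # haplotype k contributes (a_k, b_k) allele copies
    a = np.array([1, 1, 0, 0])
    b = np.array([1, 0, 1, 0])
    probs = np.zeros((3, 3))
    for k in range(4):
        for m in range(4):
            probs[a[k] + a[m], b[k] + b[m]] += h[k] * h[m]
    return probs


def log_likelihood(hap_freqs: Sequence[float], table: np.ndarray) -> float:
    """Multinomial log-likelihood of a 3x3 genotype-pair table."""
    probs = class_probs(*hap_freqs)
    mask = table > 0
    if np.any(probs[mask] <= 0):
        return -math.inf
    return float((table[mask] * np.log(probs[mask])).sum())


def em_haplotype_freqs(
    genotype_pairs,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> LDEstimate:
    """EM estimate of two-locus haplotype frequencies from unphased genotypes.

    ``genotype_pairs`` is a sequence of (g1, g2) with each genotype the count
    of the reference allele (0/1/2), or the strings AA/Aa/aa x BB/Bb/bb.

    Phase is known for every subject except the double heterozygote; the
    E-step splits those between AB|ab and Ab|aB in proportion to the current
    products p_AB p_ab and p_Ab p_aB, the M-step recounts haplotypes, and
    iteration starts from linkage equilibrium and stops when the
    log-likelihood improves by less than ``tol``.  The log-likelihood is
    checked to be non-decreasing at every step.
    """
    g1, g2 = _coerce_genotypes(genotype_pairs)
    if len(g1) < 2:
        raise ParameterError("need at least two subjects")
    table = _genotype_counts(g1, g2)
    n = table.sum()
    p_a = (2 * table[2, :].sum() + table[1, :].sum()) / (2 * n)
    p_b = (2 * table[:, 2].sum() + table[:, 1].sum()) / (2 * n)
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise MonomorphicLocusError("LD undefined: a locus is monomorphic")

    # unambiguous haplotype counts (double het excluded)
    #   AB: 2*n[2,2] + n[2,1] + n[1,2]
    base = np.array([
        2 * table[2, 2] + table[2, 1] + table[1, 2],  # AB
        2 * table[2, 0] + table[2, 1] + table[1, 0],  # Ab
        2 * table[0, 2] + table[0, 1] + table[1, 2],  # aB
        2 * table[0, 0] + table[0, 1] + table[1, 0],  # ab
    ], dtype=float)
    n_dh = table[1, 1]  # double heterozygotes: AB|ab or Ab|aB

    h = np.array([p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b,
                  (1 - p_a) * (1 - p_b)])
    ll = log_likelihood(h, table)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        cis = h[0] * h[3]          # coupling AB|ab
        trans = h[1] * h[2]        # repulsion Ab|aB
        w = cis / (cis + trans) if cis + trans > 0 else 0.5
        counts = base + n_dh * np.array([w, 1 - w, 1 - w, w])
        h_new = counts / (2 * n)
        ll_new = log_likelihood(h_new, table)
        if ll_new < ll - 1e-9 * max(1.0, abs(ll)):
            raise RuntimeError("EM log-likelihood decreased")  # pragma: no cover
        h = h_new
        if ll_new - ll < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new
    d, d_prime, r2 = ld_stats(h)
    return LDEstimate(tuple(float(x) for x in h), d, d_prime, r2,
                      ll, it, converged, int(n))


def ld_stats(hap_freqs: Sequence[float]) -> Tuple[float, float, float]:
    """(D, D', r^2) from haplotype frequencies (p_AB, p_Ab, p_aB, p_ab).

    D = p_AB - p_A p_B; D' = D / D_max with
    D_max = min(p_A p_b, p_a p_B) for D > 0 and min(p_A p_B, p_a p_b) for
    D < 0; D = 0 gives D' = 0 by convention.  r^2 = D^2/(p_A p_a p_B p_b).
    """
    h = np.asarray(hap_freqs, dtype=float)
    if h.min() < -1e-12 or abs(h.sum() - 1.0) > 1e-9:
        raise ParameterError("haplotype frequencies must be a simplex point")
    p_ab, p_abar, p_abarb, p_abarbbar = h
    p_a = p_ab + p_abar
    p_b = p_ab + p_abarb
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise MonomorphicLocusError("LD undefined at boundary allele frequency")
    d = p_ab - p_a * p_b
    if d > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    elif d < 0:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    else:
        return 0.0, 0.0, 0.0
    d_prime = d / d_max
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return float(d), float(d_prime), float(r2)


def genotypes_from_carrier(flags: Sequence[str]) -> np.ndarray:
    """Code dominant carrier flags as allele counts: yes -> 1 copy, no -> 0."""
    out = []
    for f in flags:
        if f == "yes":
            out.append(1)
        elif f == "no":
            out.append(0)
        else:
            raise ParameterError(f"carrier flag {f!r} is not yes/no")
    return np.asarray(out)


def _coerce_genotypes(genotype_pairs) -> Tuple[np.ndarray, np.ndarray]:
    str_map = {"AA": 2, "Aa": 1, "aA": 1, "aa": 0, "BB": 2, "Bb": 1, "bB": 1, "bb": 0}
    g1, g2 = [], []
    for a, b in genotype_pairs:
        g1.append(str_map[a] if isinstance(a, str) else int(a))
        g2.append(str_map[b] if isinstance(b, str) else int(b))
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    if ((g1 < 0) | (g1 > 2) | (g2 < 0) | (g2 > 2)).any():
        raise ParameterError("genotypes must be 0, 1 or 2 allele copies")
    return g1, g2


class HaplotypeEM:
    """Model wrapper: HaplotypeEM(g1, g2).fit() -> LDEstimate.

    ``g1`` and ``g2`` are per-subject allele counts (0/1/2) at the two loci.
    LMP2 genotypes map via RR/RH/HH -> 0/1/2 copies of H; carrier flags via
    :func:`genotypes_from_carrier`.
    """

    LMP2_CODES = {"RR": 0, "RH": 1, "HH": 2}

    def __init__(self, g1: Sequence[int], g2: Sequence[int]):
        self._pairs = list(zip(g1, g2))

    @classmethod
    def from_lmp2_and_carrier(cls, lmp2: Sequence[str], carrier: Sequence[str]) -> "HaplotypeEM":
        g1 = [cls.LMP2_CODES[g] for g in lmp2]
        return cls(g1, genotypes_from_carrier(carrier))

    def fit(self, tol: float = 1e-10, max_iter: int = 1000) -> LDEstimate:
        return em_haplotype_freqs(self._pairs, tol=tol, max_iter=max_iter)
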