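"""Synthetic genotype populations and digestion time-courses.

Two generators with recorded ground truth:

* :func:`simulate_population` draws case-control subjects — sex, HLA-A*02 and
  HLA-DRB1*15 carriage, and an LMP2 codon-60 genotype in Hardy-Weinberg
  proportions — and assigns disease status from a logistic model whose
  log-odds combine a baseline with the logs of the configured odds ratios.
  The protective HH effect applies only inside the female x A*02-carrier
  stratum, mirroring the stratified design the association module analyses.

* :func:`simulate_digestion` builds first-order digestion time-courses:
  substrate S(t) = B * S0 * exp(-K1 t) with K1 raised by a multiplier when
  PA28 is present, and fragment signals
  F(t) = B * yield * S0 * (1 - exp(-K1 t)) * eps, where B is a per-set
  lognormal detector factor and eps multiplicative lognormal noise on the
  fragment channel.  The H-carrier yield ratio attenuates the epitope
  fragment (10-18) of RH/HH preparations only when PA28 is present; PA28
  multiplies the epitope yield for all genotypes.

All randomness flows from the single config seed through named substreams
(:mod:`lmp2ms._rand`), so each stage is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .exceptions import ParameterError
from ._rand import substream
from .association import SubjectRecord
from .kinetics import DigestionExperiment, DEFAULT_FRAGMENTS

GENOTYPES = ("RR", "RH", "HH")


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ParameterError(f"{name} must be in [0, 1], got {value}")


def _check_pos(name: str, value: float) -> None:
    if not value > 0:
        raise ParameterError(f"{name} must be > 0, got {value}")


@dataclass(frozen=True)
class GenotypeSimConfig:
    """Parameters of the synthetic case-control population.

    Defaults emulate the study conditions: control H-allele frequency ~0.36,
    roughly half the population female and half A*02 carriers, and the three
    reported effects — A*02 protective (OR 0.671), DRB1*15 risk (OR 2.525),
    and the HH genotype protective only in A*02-carrier females (OR 0.443).
    """

    n_subjects: int = 20_000
    h_allele_freq: float = 0.36
    a02_carrier_freq: float = 0.50
    drb115_carrier_freq: float = 0.25
    female_freq: float = 0.48
    baseline_case_logodds: float = -1.0
    or_drb115: float = 2.525
    or_a02: float = 0.671
    or_hh_in_a02_females: float = 0.443
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects <= 0:
            raise ParameterError("n_subjects must be positive")
        for name in ("h_allele_freq", "a02_carrier_freq", "drb115_carrier_freq",
                     "female_freq"):
            _check_prob(name, getattr(self, name))
        for name in ("or_drb115", "or_a02", "or_hh_in_a02_females"):
            _check_pos(name, getattr(self, name))

    def hwe_proportions(self) -> Tuple[float, float, float]:
        """(P_RR, P_RH, P_HH) under Hardy-Weinberg at the H allele frequency."""
        q = self.h_allele_freq
        return ((1 - q) ** 2, 2 * q * (1 - q), q**2)


@dataclass
class SimulatedPopulation:
    """Subjects plus the ground truth that generated them."""

    subjects: List[SubjectRecord]
    ground_truth: dict

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self):
        return len(self.subjects)


def simulate_population(config: GenotypeSimConfig) -> SimulatedPopulation:
    """Draw a case-control population under the configured logistic model."""
    n = config.n_subjects
    q = config.h_allele_freq
    sex_rng = substream(config.seed, "population.sex")
    geno_rng = substream(config.seed, "population.genotype")
    a02_rng = substream(config.seed, "population.a02")
    drb_rng = substream(config.seed, "population.drb115")
    status_rng = substream(config.seed, "population.status")
    age_rng = substream(config.seed, "population.onset_age")
    cohort_rng = substream(config.seed, "population.cohort")

    female = sex_rng.random(n) < config.female_freq
    h_copies = geno_rng.binomial(2, q, size=n)  # HWE via two allele draws
    a02 = a02_rng.random(n) < config.a02_carrier_freq
    drb = drb_rng.random(n) < config.drb115_carrier_freq

    logit = np.full(n, config.baseline_case_logodds)
    logit += np.log(config.or_a02) * a02
    logit += np.log(config.or_drb115) * drb
    hh_stratum = (h_copies == 2) & female & a02
    logit += np.log(config.or_hh_in_a02_females) * hh_stratum
    p_case = 1.0 / (1.0 + np.exp(-logit))
    is_case = status_rng.random(n) < p_case

    # onset ages for cases: normal around the reported cohort means, >=18
    ages = np.clip(age_rng.normal(30.5, 10.0, size=n), 18.0, None)
    cohorts = cohort_rng.integers(1, 3, size=n)

    geno_names = np.array(["RR", "RH", "HH"])
    subjects = [
        SubjectRecord(
            subject_id=f"S{i:06d}",
            status="case" if is_case[i] else "control",
            sex="female" if female[i] else "male",
            lmp2=str(geno_names[h_copies[i]]),
            a02_carrier="yes" if a02[i] else "no",
            drb115_carrier="yes" if drb[i] else "no",
            onset_age=round(float(ages[i]), 2) if is_case[i] else None,
            cohort=str(cohorts[i]) if is_case[i] else "control",
        )
        for i in range(n)
    ]
    truth = {
        "config": asdict(config),
        "hwe_proportions": list(config.hwe_proportions()),
        "n_cases": int(is_case.sum()),
        "n_controls": int(n - is_case.sum()),
    }
    return SimulatedPopulation(subjects, truth)


def simulate_case_control(
    config: GenotypeSimConfig, n_cases: int, n_controls: int, max_batches: int = 200
) -> SimulatedPopulation:
    """Sample by status until the target case and control counts are reached.

    Case-control studies sample on outcome; this repeatedly draws populations
    from ``config`` (advancing the seed each batch) and keeps subjects until
    both targets are filled.
    """
    cases: List[SubjectRecord] = []
    controls: List[SubjectRecord] = []
    truth = None
    for batch in range(max_batches):
        pop = simulate_population(
            GenotypeSimConfig(**{**asdict(config), "seed": config.seed + 7919 * batch})
        )
        if truth is None:
            truth = pop.ground_truth
        for s in pop.subjects:
            if s.status == "case" and len(cases) < n_cases:
                cases.append(s)
            elif s.status == "control" and len(controls) < n_controls:
                controls.append(s)
        if len(cases) >= n_cases and len(controls) >= n_controls:
            break
    else:  # pragma: no cover
        raise RuntimeError("failed to fill case/control targets")
    truth = dict(truth or {}, n_cases=n_cases, n_controls=n_controls)
    return SimulatedPopulation(cases + controls, truth)


@dataclass(frozen=True)
class DigestionSimConfig:
    """Parameters of the synthetic digestion experiment.

    Defaults are calibrated to the in-vitro study design: nine preparations
    (3 per genotype; the source breakdown is a declared default), each
    digested with and without PA28; sampling times spanning all three
    consumption bins under both rate regimes; epitope yield attenuated by
    the H-carrier ratio 0.712 (a 28.8% decrease) when PA28 is present.
    """

    n_preparations_per_genotype: Tuple[int, int, int] = (3, 3, 3)  # RR, RH, HH
    k1_base: float = 0.005  # per-minute rate without PA28
    k1_pa28_multiplier: float = 3.0
    epitope_yield_base: float = 0.25  # epitope per consumed substrate
    h_carrier_yield_ratio: float = 0.712  # applied to epitope yield, PA28 present
    pa28_epitope_yield_multiplier: float = 2.0
    flanking_yield_1_9: float = 0.30
    flanking_yield_19_28: float = 0.20
    timepoints_min: Tuple[float, ...] = (0.0, 10.0, 20.0, 30.0, 40.0, 60.0, 120.0)
    batch_scale_sd: float = 0.3  # lognormal sigma of the per-set detector factor
    noise_sd: float = 0.15  # lognormal sigma of per-fragment-signal noise
    s0: float = 1000.0  # initial substrate signal, arbitrary units
    seed: int = 0

    def __post_init__(self):
        if len(self.n_preparations_per_genotype) != 3 or any(
            n < 0 for n in self.n_preparations_per_genotype
        ):
            raise ParameterError("n_preparations_per_genotype must be 3 non-negative counts")
        _check_pos("k1_base", self.k1_base)
        if self.k1_pa28_multiplier <= 1:
            raise ParameterError("k1_pa28_multiplier must exceed 1")
        for name in ("epitope_yield_base", "flanking_yield_1_9", "flanking_yield_19_28"):
            _check_prob(name, getattr(self, name))
        if not 0 < self.h_carrier_yield_ratio <= 1:
            raise ParameterError("h_carrier_yield_ratio must be in (0, 1]")
        _check_pos("pa28_epitope_yield_multiplier", self.pa28_epitope_yield_multiplier)
        tp = np.asarray(self.timepoints_min, dtype=float)
        if len(tp) < 3 or np.any(np.diff(tp) <= 0):
            raise ParameterError("timepoints_min must be >=3 strictly increasing times")
        if tp[0] != 0.0:
            raise ParameterError("timepoints_min must start at 0")
        if self.batch_scale_sd < 0 or self.noise_sd < 0:
            raise ParameterError("noise scales must be non-negative")
        _check_pos("s0", self.s0)


@dataclass
class SimulatedDigestion:
    """Digestion experiments plus the generating parameters."""

    experiments: List[DigestionExperiment]
    ground_truth: dict

    def __iter__(self):
        return iter(self.experiments)

    def __len__(self):
        return len(self.experiments)


def simulate_digestion(config: DigestionSimConfig) -> SimulatedDigestion:
    """Generate digestion time-courses for every preparation x PA28 condition."""
    batch_rng = substream(config.seed, "digestion.batch")
    noise_rng = substream(config.seed, "digestion.noise")
    t = np.asarray(config.timepoints_min, dtype=float)
    experiments: List[DigestionExperiment] = []
    truth_rows = []
    for genotype, n_preps in zip(GENOTYPES, config.n_preparations_per_genotype):
        for p in range(n_preps):
            prep_id = f"{genotype}{p + 1}"
            for pa28 in (False, True):
                k1 = config.k1_base * (config.k1_pa28_multiplier if pa28 else 1.0)
                ey = config.epitope_yield_base
                if pa28:
                    ey *= config.pa28_epitope_yield_multiplier
                    if genotype in ("RH", "HH"):
                        ey *= config.h_carrier_yield_ratio
                yields = {
                    "1-9": config.flanking_yield_1_9,
                    "10-18": ey,
                    "19-28": config.flanking_yield_19_28,
                }
                b = math.exp(batch_rng.normal(0.0, config.batch_scale_sd)) \
                    if config.batch_scale_sd > 0 else 1.0
                substrate = b * config.s0 * np.exp(-k1 * t)
                consumed = b * config.s0 * (1.0 - np.exp(-k1 * t))
                frag_signals: Dict[str, np.ndarray] = {}
                for name, y in yields.items():
                    eps = (
                        np.exp(noise_rng.normal(0.0, config.noise_sd, size=len(t)))
                        if config.noise_sd > 0 else np.ones(len(t))
                    )
                    frag_signals[name] = y * consumed * eps
                set_id = f"set_{prep_id}_{'pa28' if pa28 else 'core'}"
                experiments.append(
                    DigestionExperiment(
                        set_id=set_id,
                        preparation_id=prep_id,
                        lmp2_genotype=genotype,
                        pa28=pa28,
                        times=t.copy(),
                        substrate_signal=substrate,
                        fragment_signals=frag_signals,
                        fragment_coords=dict(DEFAULT_FRAGMENTS),
                    )
                )
                truth_rows.append(
                    {
                        "set_id": set_id,
                        "preparation_id": prep_id,
                        "genotype": genotype,
                        "pa28": pa28,
                        "true_k1": k1,
                        "true_yields": yields,
                        "batch_factor": b,
                    }
                )
    truth = {"config": _config_dict(config), "per_set": truth_rows}
    return SimulatedDigestion(experiments, truth)


def _config_dict(config: DigestionSimConfig) -> dict:
    d = asdict(config)
    d["n_preparations_per_genotype"] = list(d["n_preparations_per_genotype"])
    d["timepoints_min"] = list(d["timepoints_min"])
    return d
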