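"""Pipeline configuration and report generation.

`run_association` and `run_digestion` tie the analysis modules together:
they read a subject or digestion table, run every panel of the corresponding
analysis and write TSV/JSON report files.  Two runs with the same
configuration and seed produce byte-identical JSON; every stochastic block
records its replicate count and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from .exceptions import ParameterError
from . import association as assoc
from .association import CaseControlAssociation, onset_age_compare
from .ld import HaplotypeEM
from .exceptions import MonomorphicLocusError, InsufficientDataError
from .sp import DigestionStudy

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"


@dataclass
class PipelineConfig:
    """Configuration of a report run; see the CLI for flag equivalents."""

    input_path: Optional[str] = None
    output_dir: str = "results"
    seed: int = 0
    n_reps: int = 10_000
    alpha: float = 0.05
    stratum_sex: Optional[str] = "female"
    stratum_a02: Optional[str] = "yes"
    use_standardized_sp: bool = False

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError("alpha must be in (0, 1)")
        if self.seed is None:
            raise ParameterError("a seed is mandatory for stochastic runs")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _config_block(config: "PipelineConfig") -> dict:
    # the output location is not an analysis input; keep result JSON
    # byte-identical across runs that differ only in where they write
    block = asdict(config)
    block.pop("output_dir", None)
    return block


def _write_json(payload: dict, path: Path) -> None:
    payload = {"schema_version": SCHEMA_VERSION, **payload}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def run_association(config: PipelineConfig) -> Dict[str, Path]:
    """Full association report for one stratum of a subject table.

    Emits the genotype table, OR/CI/p contrasts, Monte Carlo chi-square,
    Hardy-Weinberg panels, cohort homogeneity, LD of LMP2 against both HLA
    carrier loci, and the onset-age comparison.
    """
    from .io import read_subjects

    subjects = read_subjects(config.input_path)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    model = CaseControlAssociation(subjects, sex=config.stratum_sex,
                                   a02=config.stratum_a02)
    results = model.fit(n_reps=config.n_reps, seed=config.seed)
    payload = {"association": results.to_dict(), "config": _config_block(config)}

    # cohort homogeneity: genotype distribution of case series 1 vs 2
    try:
        t1 = assoc.tabulate(subjects, sex=config.stratum_sex, a02=config.stratum_a02,
                            case_cohorts=["1"])
        t2 = assoc.tabulate(subjects, sex=config.stratum_sex, a02=config.stratum_a02,
                            case_cohorts=["2"])
        hom = assoc.cohort_homogeneity(t1, t2)
        payload["cohort_homogeneity"] = {
            "chi2": hom.chi2, "df": hom.df, "p": hom.p_asymptotic,
            "pooling_licensed": bool(hom.p_asymptotic > config.alpha),
        }
    except (InsufficientDataError, ParameterError) as exc:
        logger.info("cohort homogeneity skipped: %s", exc)

    # LD of LMP2 against carrier loci, in the stratum's controls
    in_stratum = [
        s for s in subjects
        if (config.stratum_sex is None or s.sex == config.stratum_sex)
        and s.status == "control"
    ]
    ld_block = {}
    for locus, flag_of in (("a02", lambda s: s.a02_carrier),
                           ("drb115", lambda s: s.drb115_carrier)):
        known = [s for s in in_stratum if flag_of(s) != "unknown"]
        if len(known) < 2:
            continue
        try:
            est = HaplotypeEM.from_lmp2_and_carrier(
                [s.lmp2 for s in known], [flag_of(s) for s in known]
            ).fit()
            chi2, p = est.chi2_test()
            ld_block[f"lmp2_vs_{locus}"] = {
                "d_prime": est.d_prime, "r2": est.r2, "d": est.d,
                "chi2": chi2, "p": p, "n": est.n_subjects,
            }
        except MonomorphicLocusError as exc:
            logger.info("LD for %s skipped: %s", locus, exc)
    if ld_block:
        payload["linkage_disequilibrium"] = ld_block

    # onset age by genotype within the stratum's cases
    age_groups = {}
    for g in ("HH", "RH", "RR"):
        ages = [
            s.onset_age for s in subjects
            if s.status == "case" and s.lmp2 == g and s.onset_age is not None
            and (config.stratum_sex is None or s.sex == config.stratum_sex)
            and (config.stratum_a02 is None or s.a02_carrier == config.stratum_a02)
        ]
        if len(ages) >= 2:
            age_groups[g] = ages
    if len(age_groups) >= 2:
        res, table = onset_age_compare(age_groups, seed=config.seed)
        payload["onset_age"] = {
            "F": res.statistic, "p": res.p_value, "method": res.method,
            "n_permutations": res.n_permutations, "seed": config.seed,
            "groups": table.to_dict(orient="index"),
        }

    json_path = outdir / "association.json"
    _write_json(payload, json_path)
    tsv_path = outdir / "genotype_table.tsv"
    results.table.counts.to_csv(tsv_path, sep="\t")
    return {"json": json_path, "genotype_table": tsv_path}


def run_digestion(config: PipelineConfig) -> Dict[str, Path]:
    """Full digestion report: K1 table, SP-by-bin tables, group comparisons."""
    study = DigestionStudy.from_csv(config.input_path)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    results = study.fit(seed=config.seed, n_permutations=config.n_reps,
                        use_standardized=config.use_standardized_sp)
    payload = {"digestion": results.to_dict(), "config": _config_block(config)}
    json_path = outdir / "digestion.json"
    _write_json(payload, json_path)
    k1_path = outdir / "k1_table.tsv"
    results.kinetics.to_csv(k1_path, sep="\t", index=False)
    sp_path = outdir / "sp_estimates.tsv"
    pd.DataFrame(
        [
            {
                "set_id": e.set_id, "preparation_id": e.preparation_id,
                "genotype": e.lmp2_genotype,
                "pa28": "present" if e.pa28 else "absent",
                "fragment": e.fragment_name, "time_min": e.time,
                "sp": e.sp, "consumption": e.consumption, "bin": e.bin,
                "sp_standardized": e.sp_standardized,
            }
            for e in results.estimates
        ]
    ).to_csv(sp_path, sep="\t", index=False)
    return {"json": json_path, "k1_table": k1_path, "sp_estimates": sp_path}
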