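"""Reading and writing the subject and digestion tables.

Both inputs are plain CSV/TSV with declared headers; the delimiter is chosen
from the file extension (``.tsv`` -> tab, anything else -> comma).  Schema
violations are reported with the offending row number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import ParameterError, SchemaError
from .association import SubjectRecord
from .kinetics import DigestionExperiment

SUBJECT_COLUMNS = [
    "subject_id", "status", "sex", "lmp2",
    "a02_carrier", "drb115_carrier", "onset_age", "cohort",
]
DIGESTION_COLUMNS = [
    "set_id", "preparation_id", "genotype", "pa28", "time_min",
    "substrate_signal", "frag_1_9", "frag_10_18", "frag_19_28",
]
_FRAG_COLUMNS = {"frag_1_9": "1-9", "frag_10_18": "10-18", "frag_19_28": "19-28"}

PathLike = Union[str, Path]


def _delimiter(path: PathLike) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: PathLike) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")


def read_subjects(path: PathLike) -> List[SubjectRecord]:
    """Load subject records from a CSV/TSV file."""
    df = pd.read_csv(path, sep=_delimiter(path), dtype={"cohort": str})
    required = [c for c in SUBJECT_COLUMNS if c != "onset_age"]
    _require_columns(df, required, path)
    return subjects_from_dataframe(df, source=str(path))


def subjects_from_dataframe(df: pd.DataFrame, source: str = "<dataframe>") -> List[SubjectRecord]:
    subjects = []
    has_age = "onset_age" in df.columns
    for i, row in enumerate(df.itertuples(index=False), start=2):  # row 1 = header
        try:
            age = getattr(row, "onset_age", None) if has_age else None
            if age is not None and (isinstance(age, float) and np.isnan(age)):
                age = None
            subjects.append(
                SubjectRecord(
                    subject_id=str(row.subject_id),
                    status=str(row.status),
                    sex=str(row.sex),
                    lmp2=str(row.lmp2),
                    a02_carrier=str(row.a02_carrier),
                    drb115_carrier=str(row.drb115_carrier),
                    onset_age=float(age) if age is not None else None,
                    cohort=str(row.cohort),
                )
            )
        except (ParameterError, ValueError) as exc:
            raise SchemaError(f"{source}: row {i}: {exc}") from exc
    return subjects


def write_subjects(subjects: Sequence[SubjectRecord], path: PathLike) -> None:
    df = pd.DataFrame(
        [
            {
                "subject_id": s.subject_id, "status": s.status, "sex": s.sex,
                "lmp2": s.lmp2, "a02_carrier": s.a02_carrier,
                "drb115_carrier": s.drb115_carrier,
                "onset_age": s.onset_age, "cohort": s.cohort,
            }
            for s in subjects
        ],
        columns=SUBJECT_COLUMNS,
    )
    df.to_csv(path, sep=_delimiter(path), index=False)


def read_digestion(path: PathLike) -> List[DigestionExperiment]:
    """Load digestion time-courses from a long-format CSV/TSV file.

    One row per (set, preparation, PA28 condition, timepoint); rows sharing
    (set_id, preparation_id, pa28) form one experiment, sorted by time.
    """
    df = pd.read_csv(path, sep=_delimiter(path))
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    _require_columns(df, DIGESTION_COLUMNS, path)
    experiments = []
    for (set_id, prep_id, pa28), grp in df.groupby(
        ["set_id", "preparation_id", "pa28"], sort=False
    ):
        grp = grp.sort_values("time_min")
        pa28_flag = _parse_pa28(pa28, path)
        genotypes = grp["genotype"].unique()
        if len(genotypes) != 1:
            raise SchemaError(
                f"{path}: set {set_id!r} has conflicting genotypes {list(genotypes)}"
            )
        try:
            experiments.append(
                DigestionExperiment(
                    set_id=str(set_id),
                    preparation_id=str(prep_id),
                    lmp2_genotype=str(genotypes[0]),
                    pa28=pa28_flag,
                    times=grp["time_min"].to_numpy(float),
                    substrate_signal=grp["substrate_signal"].to_numpy(float),
                    fragment_signals={
                        frag: grp[col].to_numpy(float)
                        for col, frag in _FRAG_COLUMNS.items()
                    },
                )
            )
        except ParameterError as exc:
            first_row = int(grp.index.min()) + 2
            raise SchemaError(f"{path}: near row {first_row}: {exc}") from exc
    return experiments


def _parse_pa28(value, path: PathLike) -> bool:
    text = str(value).strip().lower()
    if text in ("present", "true", "1", "yes"):
        return True
    if text in ("absent", "false", "0", "no"):
        return False
    raise SchemaError(f"{path}: pa28 value {value!r} is not present/absent")


def write_digestion(experiments: Sequence[DigestionExperiment], path: PathLike) -> None:
    rows = []
    for exp in experiments:
        for i, t in enumerate(exp.times):
            rows.append(
                {
                    "set_id": exp.set_id,
                    "preparation_id": exp.preparation_id,
                    "genotype": exp.lmp2_genotype,
                    "pa28": "present" if exp.pa28 else "absent",
                    "time_min": t,
                    "substrate_signal": exp.substrate_signal[i],
                    **{
                        col: exp.fragment_signals[frag][i]
                        for col, frag in _FRAG_COLUMNS.items()
                    },
                }
            )
    pd.DataFrame(rows, columns=DIGESTION_COLUMNS).to_csv(
        path, sep=_delimiter(path), index=False
    )


def write_ground_truth(truth: Dict, path: PathLike) -> None:
    """Write a simulation's ground-truth sidecar JSON."""
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True))
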