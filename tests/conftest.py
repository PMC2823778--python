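"""Shared fixtures: printed-table fixtures expanded to subject records, and
noiseless digestion experiments with known parameters."""

import numpy as np
import pandas as pd
import pytest

from lmp2ms import DigestionExperiment, SubjectRecord

# Published stratified genotype counts (status x HH/RH/RR), used as fixtures.
TABLE2_FEMALE_A02 = {"case": (26, 146, 165), "control": (32, 80, 90)}
TABLE3_MALE_A02 = {"case": (18, 85, 75), "control": (21, 88, 85)}
TABLE1_SEX = {"case": {"male": 413, "female": 849},
              "control": {"male": 437, "female": 408}}


def subjects_from_genotype_counts(counts, sex, a02="yes", cohort_split=True):
    """Expand a status -> (n_HH, n_RH, n_RR) mapping into subject records."""
    subjects = []
    i = 0
    for status, row in counts.items():
        for geno, n in zip(("HH", "RH", "RR"), row):
            for k in range(n):
                cohort = "control" if status == "control" else (
                    "1" if (not cohort_split or k % 2 == 0) else "2")
                subjects.append(SubjectRecord(
                    subject_id=f"X{i:05d}", status=status, sex=sex,
                    lmp2=geno, a02_carrier=a02, cohort=cohort,
                ))
                i += 1
    return subjects


@pytest.fixture(scope="session")
def table2_counts():
    return pd.DataFrame(
        [TABLE2_FEMALE_A02["case"], TABLE2_FEMALE_A02["control"]],
        index=["case", "control"], columns=["HH", "RH", "RR"],
    )


@pytest.fixture(scope="session")
def table2_subjects():
    return subjects_from_genotype_counts(TABLE2_FEMALE_A02, sex="female")


@pytest.fixture(scope="session")
def table3_subjects():
    return subjects_from_genotype_counts(TABLE3_MALE_A02, sex="male")


@pytest.fixture(scope="session")
def table1_subjects():
    """Sex-distribution fixture: genotypes are irrelevant, set to RR."""
    subjects = []
    i = 0
    for status, by_sex in TABLE1_SEX.items():
        for sex, n in by_sex.items():
            for _ in range(n):
                subjects.append(SubjectRecord(
                    subject_id=f"T{i:05d}", status=status, sex=sex, lmp2="RR",
                    cohort="control" if status == "control" else "1",
                ))
                i += 1
    return subjects


def make_experiment(k1=0.01, s0=100.0, times=(0.0, 30.0, 60.0, 120.0),
                    yields=None, batch=1.0, genotype="RR", pa28=True,
                    set_id="set1", prep_id="prep1"):
    """Noiseless first-order digestion experiment with known parameters."""
    t = np.asarray(times, dtype=float)
    yields = yields or {"1-9": 0.3, "10-18": 0.25, "19-28": 0.2}
    substrate = batch * s0 * np.exp(-k1 * t)
    consumed = batch * s0 * (1 - np.exp(-k1 * t))
    return DigestionExperiment(
        set_id=set_id, preparation_id=prep_id, lmp2_genotype=genotype,
        pa28=pa28, times=t, substrate_signal=substrate,
        fragment_signals={name: y * consumed for name, y in yields.items()},
    )
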