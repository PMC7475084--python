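from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import settings

from rxdur import SimulationConfig, load_country_config, simulate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sweden_config():
    return load_country_config("sweden")


@pytest.fixture(scope="session")
def sim_small():
    """A 300-patient default cohort shared across unit tests."""
    return simulate_cohort(SimulationConfig(n_patients=300, seed=5))


@pytest.fixture(scope="session")
def sim_5000():
    """The 5000-patient cohort the stochastic checks are specified at."""
    return simulate_cohort(SimulationConfig(n_patients=5000, seed=11))


def make_patients(rows):
    """rows: (patient_id, birth_year, sex, start, end, source_id)."""
    df = pd.DataFrame(
        rows,
        columns=["patient_id", "birth_year", "sex", "enrolment_start", "enrolment_end", "source_id"],
    )
    df["birth_year"] = df["birth_year"].astype("Int64")
    for c in ("enrolment_start", "enrolment_end"):
        df[c] = pd.to_datetime(df[c])
    return df


def make_rx(rows):
    """rows: (patient_id, drug, issue_date, strength, quantity, instruction, supply)."""
    df = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "drug",
            "issue_date",
            "strength_mg",
            "quantity",
            "daily_dose_instruction_mg",
            "supply_days",
        ],
    )
    df["issue_date"] = pd.to_datetime(df["issue_date"])
    df["supply_days"] = df["supply_days"].astype("Int64")
    return df


def make_dx(rows):
    """rows: (patient_id, code_class, diagnosis_date)."""
    df = pd.DataFrame(rows, columns=["patient_id", "code_class", "diagnosis_date"])
    df["diagnosis_date"] = pd.to_datetime(df["diagnosis_date"])
    return df
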