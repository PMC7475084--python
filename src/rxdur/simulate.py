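"""Synthetic multi-country cohort generator.

Real drug-utilization sources (national prescription registries, EMR
panels, pharmacy panels) are access-restricted, so this module generates
event tables with the statistical structure the analysis assumes: per-
country launch dates and observation windows, configurable age/sex mixes,
diagnosis-recording completeness, refill behaviour with on-time and late
gaps, and per-refill discontinuation/switching hazards.  Source-specific
missingness is emulated from the country's source profiles (a panel that
records no diagnoses yields an empty diagnosis table; one that records no
ages yields missing birth years).

Events are *constructed to respect* the 30-day grace-period definitions:
the generator knows, for every patient, whether it produced a
discontinuation, a switch to or from the index drug, or censoring, and
returns those labels in a ground-truth table.  The downstream classifiers
are expected to recover them exactly, which is the pipeline's strongest
end-to-end check.

The generator is a test harness, not a calibration: defaults are chosen as
plausible for a European ADHD cohort (male fraction 0.70, ~85% recorded
diagnoses, 80% prior MPH, mean ~7 prescriptions/patient, doses mostly
30-70 mg/day with a small mass above the 70 mg/day cap), not fitted to any
particular country's results.
"""

from __future__ import annotations

import datetime as dt
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .types import (
    AGE_BANDS,
    CountryLabelConfig,
    Drug,
    Sex,
    load_country_config,
)

_SWITCH_DRUGS = (Drug.MPH.value, Drug.ATX.value, Drug.OTHER_ADHD.value)


class SimulationConfig(BaseModel):
    """Parameters of the synthetic cohort.

    Hazards are per refill decision; gaps are in days between the end of
    one prescription period and the next issue.  ``dose_mix`` is a daily
    dose (mg/day) distribution and may carry mass above 70 mg/day.
    """

    n_patients: int = Field(default=1000, gt=0)
    country: str = "sweden"
    seed: int = 0
    age_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "0-5": 0.005,
            "6-12": 0.20,
            "13-18": 0.25,
            "19-25": 0.14,
            ">25": 0.405,
        }
    )
    male_fraction: float = Field(default=0.70, ge=0, le=1)
    p_adhd_recorded: float = Field(default=0.85, ge=0, le=1)
    p_prior_mph: float = Field(default=0.80, ge=0, le=1)
    p_switch_to_given_prior_mph: float = Field(default=0.5, ge=0, le=1)
    max_prior_mph: int = Field(default=3, ge=1)
    p_late_refill: float = Field(default=0.08, ge=0, le=1)
    late_gap_mean_days: float = Field(default=60.0, gt=0)
    late_gap_max_days: int = Field(default=365, gt=31)
    discontinuation_hazard: float = Field(default=0.10, ge=0, le=1)
    switch_hazard: float = Field(default=0.03, ge=0, le=1)
    dose_mix: dict[float, float] = Field(
        default_factory=lambda: {30.0: 0.40, 50.0: 0.35, 70.0: 0.20, 90.0: 0.05}
    )
    supply_days_nominal: int = Field(default=30, gt=0)
    p_continuation_from_adolescence: float = Field(default=0.05, ge=0, le=1)
    p_non_adhd_rx: float = Field(default=0.2, ge=0, le=1)
    gap_days: int = Field(default=30, ge=0)

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        for name in ("age_mix", "dose_mix"):
            probs = list(getattr(self, name).values())
            if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-6:
                raise ValueError(f"{name} must be a normalized distribution")
        if self.discontinuation_hazard + self.switch_hazard > 1.0:
            raise ValueError("discontinuation_hazard + switch_hazard must be <= 1")
        bands = {label for label, _, _ in AGE_BANDS}
        if set(self.age_mix) != bands:
            raise ValueError(f"age_mix must cover exactly the bands {sorted(bands)}")
        return self


class SimulatedCohort(NamedTuple):
    """Event tables plus the generator's ground-truth labels."""

    patients: pd.DataFrame
    prescriptions: pd.DataFrame
    diagnoses: pd.DataFrame
    truth: pd.DataFrame


_TRUTH_COLUMNS = [
    "patient_id",
    "source_id",
    "sex",
    "age_first_ldx",
    "birth_year",
    "first_ldx_date",
    "dose_mg",
    "n_ldx_rx",
    "has_prior_mph",
    "has_prior_dx",
    "continuation_from_adolescence",
    "switched_to_ldx",
    "switched_from_ldx",
    "discontinued",
    "censored",
]


def _draw_age(rng: np.random.Generator, config: SimulationConfig) -> int:
    labels = [label for label, _, _ in AGE_BANDS]
    probs = np.array([config.age_mix[label] for label in labels])
    band = labels[rng.choice(len(labels), p=probs / probs.sum())]
    lo, hi = next((lo, hi) for label, lo, hi in AGE_BANDS if label == band)
    hi = min(hi, 60)  # keep >25 ages realistic
    return int(rng.integers(lo, hi + 1))


def _late_gap(rng: np.random.Generator, config: SimulationConfig) -> int:
    extra = int(min(rng.exponential(config.late_gap_mean_days), config.late_gap_max_days - 31))
    return config.gap_days + 1 + extra


def simulate_cohort(
    config: SimulationConfig,
    country_config: Optional[CountryLabelConfig] = None,
) -> SimulatedCohort:
    """Generate a cohort for one country.

    Deterministic: the same (config, country_config) yields byte-identical
    tables.  Raises ``ValueError`` when the observation window is shorter
    than one supply period.
    """
    cc = country_config or load_country_config(config.country)
    obs_start = pd.Timestamp(cc.observation_start)
    obs_end = pd.Timestamp(cc.observation_end)
    window_days = (obs_end - obs_start).days
    supply = config.supply_days_nominal
    if window_days < supply:
        raise ValueError(
            f"observation window ({window_days} d) shorter than one supply period ({supply} d)"
        )
    gap_max = config.gap_days  # largest gap still inside an episode

    rng = np.random.default_rng(config.seed)
    sources = cc.sources or []
    source_ids = [s.source_id for s in sources] or ["default"]
    source_by_id = {s.source_id: s for s in sources}
    doses = sorted(config.dose_mix)
    dose_probs = np.array([config.dose_mix[d] for d in doses])
    dose_probs = dose_probs / dose_probs.sum()
    day = pd.Timedelta(1, "D")

    pat_rows, rx_rows, dx_rows, truth_rows = [], [], [], []

    def emit_rx(pid: str, drug: str, issue: pd.Timestamp, dose: float, records_durations: bool):
        rx_rows.append(
            {
                "patient_id": pid,
                "drug": drug,
                "issue_date": issue,
                "strength_mg": dose,
                "quantity": float(supply),
                "daily_dose_instruction_mg": dose,
                "supply_days": supply if records_durations else pd.NA,
            }
        )

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        source_id = source_ids[int(rng.integers(0, len(source_ids)))]
        profile = source_by_id.get(source_id)
        records_dx = profile.records_diagnoses if profile else True
        records_ages = profile.records_ages if profile else True
        records_durations = profile.records_durations if profile else True

        sex = Sex.male.value if rng.random() < config.male_fraction else Sex.female.value
        cont = rng.random() < config.p_continuation_from_adolescence
        age_first = int(rng.integers(17, 19)) if cont else _draw_age(rng, config)

        first_ldx = obs_start + int(rng.integers(0, window_days)) * day
        birth_year = first_ldx.year - age_first
        dose = float(doses[rng.choice(len(doses), p=dose_probs)])

        # --- diagnosis history ------------------------------------------
        has_dx = records_dx and rng.random() < config.p_adhd_recorded
        if has_dx:
            dx_rows.append(
                {
                    "patient_id": pid,
                    "code_class": "ADHD",
                    "diagnosis_date": first_ldx - int(rng.integers(1, 1096)) * day,
                }
            )

        # --- prior MPH history ------------------------------------------
        room = (first_ldx - obs_start).days
        has_mph = False
        switched_to = False
        if rng.random() < config.p_prior_mph:
            if rng.random() < config.p_switch_to_given_prior_mph:
                gap_to_ldx = int(rng.integers(0, gap_max + 1))
            else:
                gap_to_ldx = _late_gap(rng, config)
            if room >= gap_to_ldx + supply:
                has_mph = True
                switched_to = gap_to_ldx <= gap_max
                issue = first_ldx - gap_to_ldx * day - supply * day
                emit_rx(pid, Drug.MPH.value, issue, dose, records_durations)
                for _ in range(int(rng.integers(0, config.max_prior_mph))):
                    issue = issue - int(rng.integers(0, gap_max + 1)) * day - supply * day
                    if issue < obs_start:
                        break
                    emit_rx(pid, Drug.MPH.value, issue, dose, records_durations)

        # --- index-drug sequence ----------------------------------------
        issue = first_ldx
        n_ldx = 0
        discontinued = False
        switched_from = False
        final_end = None
        switched_at_final = False
        while True:
            emit_rx(pid, Drug.LDX.value, issue, dose, records_durations)
            n_ldx += 1
            end = issue + supply * day
            cont_active = cont and (issue.year - birth_year) < cc.adult_age_threshold
            u = rng.random()
            if not cont_active and u < config.discontinuation_hazard:
                final_end = end
                break
            if not cont_active and u < config.discontinuation_hazard + config.switch_hazard:
                o_issue = end + int(rng.integers(0, gap_max + 1)) * day
                if o_issue <= obs_end:
                    other = _SWITCH_DRUGS[int(rng.integers(0, len(_SWITCH_DRUGS)))]
                    emit_rx(pid, other, o_issue, dose, records_durations)
                    for _ in range(int(rng.integers(0, 3))):
                        o_issue = o_issue + supply * day + int(rng.integers(0, gap_max + 1)) * day
                        if o_issue > obs_end:
                            break
                        emit_rx(pid, other, o_issue, dose, records_durations)
                    switched_from = True
                    switched_at_final = True
                final_end = end
                break
            late = (not cont_active) and rng.random() < config.p_late_refill
            gap = _late_gap(rng, config) if late else int(rng.integers(0, gap_max + 1))
            nxt = end + gap * day
            if nxt > obs_end:
                final_end = end
                break
            if late:
                # an in-window episode break with no switch evidence: a
                # discontinuation event, later followed by re-initiation
                discontinued = True
            issue = nxt

        adjudicable = final_end + gap_max * day <= obs_end
        if not switched_at_final and adjudicable:
            discontinued = True
        censored = (not switched_at_final) and not adjudicable

        # --- unrelated co-medication (must be ignored downstream) -------
        if rng.random() < config.p_non_adhd_rx:
            for _ in range(int(rng.integers(1, 3))):
                off = int(rng.integers(0, window_days - supply + 1))
                emit_rx(pid, Drug.NON_ADHD.value, obs_start + off * day, 500.0, records_durations)

        pat_rows.append(
            {
                "patient_id": pid,
                "birth_year": birth_year if records_ages else pd.NA,
                "sex": sex,
                "enrolment_start": obs_start,
                "enrolment_end": obs_end,
                "source_id": source_id,
            }
        )
        truth_rows.append(
            {
                "patient_id": pid,
                "source_id": source_id,
                "sex": sex,
                "age_first_ldx": age_first,
                "birth_year": birth_year,
                "first_ldx_date": first_ldx,
                "dose_mg": dose,
                "n_ldx_rx": n_ldx,
                "has_prior_mph": has_mph,
                "has_prior_dx": has_dx,
                "continuation_from_adolescence": cont,
                "switched_to_ldx": switched_to,
                "switched_from_ldx": switched_from,
                "discontinued": discontinued,
                "censored": censored,
            }
        )

    patients = pd.DataFrame(pat_rows)
    patients["birth_year"] = patients["birth_year"].astype("Int64")
    prescriptions = pd.DataFrame(rx_rows).sort_values(
        ["patient_id", "issue_date", "drug"], kind="mergesort"
    ).reset_index(drop=True)
    prescriptions["supply_days"] = prescriptions["supply_days"].astype("Int64")
    if dx_rows:
        diagnoses = pd.DataFrame(dx_rows)
    else:
        diagnoses = pd.DataFrame(columns=["patient_id", "code_class", "diagnosis_date"])
        diagnoses["diagnosis_date"] = diagnoses["diagnosis_date"].astype("datetime64[ns]")
    truth = pd.DataFrame(truth_rows, columns=_TRUTH_COLUMNS)
    return SimulatedCohort(patients, prescriptions, diagnoses, truth)
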