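"""Label-compliance auditing (off-label use detection).

Each patient is checked against the jurisdiction's label rules for the
index drug, as declared in a :class:`~rxdur.types.CountryLabelConfig`:

1. no recorded ADHD diagnosis before the first index prescription;
2. no recorded prior MPH prescription (evaluable only with at least
   ``mph_lookback_min_enrolment_days`` of enrolment history, 365 by
   default — shorter histories cannot establish absence of prior use);
3. younger than the minimum label age (6 years) at any prescription;
4. dosage exceeding the maximum daily dose (70 mg/day) — headline variant
   is the patient's average daily dose; a per-prescription variant is
   computed alongside;
5. adult use (age >= 19) without an adult approval in force at the
   prescription date (with an optional age cap, e.g. 55 in Switzerland),
   unless treatment continued from adolescence — i.e. the prescription
   belongs to a treatment episode (30-day-gap rule) that began before the
   patient's adult threshold birthday.

Flags are tri-state: True / False / not-evaluable (pandas NA), and a
not-evaluable criterion never contributes to the combined ``any_off_label``
flag.  Missingness propagates from the source profile: panels that record
no diagnoses cannot be audited for criterion 1, panels without ages cannot
be audited for 3 or 5.  Ages are year-granular (event year - birth year).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .episodes import average_daily_dose, stack_coverage
from .types import CountryLabelConfig, Drug

FLAG_COLUMNS = [
    "patient_id",
    "first_ldx_date",
    "no_prior_diagnosis",
    "no_prior_mph",
    "under_min_age",
    "dose_exceeds_cap",
    "any_rx_dose_exceeds_cap",
    "adult_off_label",
    "any_off_label",
]


def _source_flag(
    patients: pd.DataFrame, config: CountryLabelConfig, attr: str
) -> pd.Series:
    """patient_id -> boolean source capability (True when source unknown)."""
    source_map = {sid: getattr(p, attr) for sid, p in config.source_map.items()}
    per_patient = patients.set_index("patient_id")["source_id"].map(source_map)
    return per_patient.fillna(True).astype(bool)


def first_ldx_dates(prescriptions: pd.DataFrame) -> pd.Series:
    """Date of each patient's first index-drug prescription."""
    ldx = prescriptions[prescriptions["drug"] == Drug.LDX.value]
    return ldx.groupby("patient_id")["issue_date"].min()


def flag_no_prior_diagnosis(
    diagnoses: pd.DataFrame,
    first_ldx: pd.Series,
    patients: pd.DataFrame,
    config: CountryLabelConfig,
) -> pd.Series:
    """True when no ADHD diagnosis is recorded strictly before the first
    index prescription; NA for sources that record no diagnoses."""
    adhd = diagnoses[diagnoses["code_class"] == "ADHD"]
    first_dx = adhd.groupby("patient_id")["diagnosis_date"].min()
    out = pd.Series(True, index=first_ldx.index, dtype="boolean")
    dx = first_ldx.index.map(first_dx)
    has_prior = pd.Series(dx, index=first_ldx.index) < first_ldx
    out[has_prior.fillna(False)] = False

    source_records = _source_flag(patients, config, "records_diagnoses")
    out[~first_ldx.index.map(source_records).fillna(True).astype(bool)] = pd.NA
    out.name = "no_prior_diagnosis"
    return out


def flag_no_prior_mph(
    prescriptions: pd.DataFrame,
    first_ldx: pd.Series,
    patients: pd.DataFrame,
    min_enrolment_days: int = 365,
) -> pd.Series:
    """True when no MPH prescription precedes the first index prescription;
    NA when enrolment history before it is shorter than the lookback floor."""
    mph = prescriptions[prescriptions["drug"] == Drug.MPH.value]
    first_mph = mph.groupby("patient_id")["issue_date"].min()
    out = pd.Series(True, index=first_ldx.index, dtype="boolean")
    m = pd.Series(first_ldx.index.map(first_mph), index=first_ldx.index)
    out[(m < first_ldx).fillna(False)] = False

    enrol = patients.set_index("patient_id")["enrolment_start"]
    history = (first_ldx - first_ldx.index.map(enrol)).dt.days
    out[(history < min_enrolment_days) | history.isna()] = pd.NA
    out.name = "no_prior_mph"
    return out


def flag_age_and_dose(
    patients: pd.DataFrame,
    coverage: pd.DataFrame,
    config: CountryLabelConfig,
) -> pd.DataFrame:
    """Minimum-age and maximum-dose criteria.

    ``under_min_age`` — younger than the label minimum at any index
    prescription (year-granular age), NA when the birth year is unknown.
    ``dose_exceeds_cap`` — patient-level average daily dose above the cap.
    ``any_rx_dose_exceeds_cap`` — any single prescription's daily dose above
    the cap (the stricter per-event reading).
    """
    ldx = coverage[coverage["drug"] == Drug.LDX.value]
    birth = patients.set_index("patient_id")["birth_year"]
    pids = sorted(ldx["patient_id"].unique())

    ages = ldx["start"].dt.year - ldx["patient_id"].map(birth).astype("Float64")
    under = (
        pd.DataFrame({"patient_id": ldx["patient_id"], "under": ages < config.min_label_age})
        .groupby("patient_id")["under"]
        .any()
    )
    out = pd.DataFrame({"patient_id": pids})
    out["under_min_age"] = out["patient_id"].map(under).astype("boolean")
    out.loc[out["patient_id"].map(birth).isna().to_numpy(), "under_min_age"] = pd.NA

    add = average_daily_dose(ldx, cap_mg=config.max_daily_dose_mg).set_index("patient_id")
    out["dose_exceeds_cap"] = (
        out["patient_id"].map(add["exceeds_cap"]).astype("boolean")
    )
    out.loc[out["patient_id"].map(add["add_mg_per_day"]).isna().to_numpy(), "dose_exceeds_cap"] = pd.NA

    per_rx = (
        pd.DataFrame(
            {
                "patient_id": ldx["patient_id"],
                "over": ldx["dose_mg_per_day"] > config.max_daily_dose_mg,
            }
        )
        .groupby("patient_id")["over"]
        .any()
    )
    out["any_rx_dose_exceeds_cap"] = out["patient_id"].map(per_rx).fillna(False).astype(bool)
    return out


def flag_adult_off_label(
    patients: pd.DataFrame,
    coverage: pd.DataFrame,
    config: CountryLabelConfig,
    gap_days: int = 30,
    boundary: str = "inclusive",
    overlap: str = "shift",
) -> pd.Series:
    """Adult (>= ``adult_age_threshold``) use outside the adult label.

    An adult prescription is on-label when (a) its treatment episode began
    before the patient reached the adult threshold (continuation from
    adolescence — the episode chain uses the same grace period as the rest
    of the analysis), or (b) an adult approval was in force at the issue
    date and the patient is within the approval's age cap, if any.
    NA when the birth year is unknown.
    """
    ldx = coverage[coverage["drug"] == Drug.LDX.value]
    birth = patients.set_index("patient_id")["birth_year"]
    pids = sorted(ldx["patient_id"].unique())
    out = pd.Series(False, index=pids, dtype="boolean", name="adult_off_label")
    if ldx.empty:
        return out

    stacked = stack_coverage(ldx, gap_days, overlap, boundary)
    ep_start = stacked.groupby(["patient_id", "episode_id"])["eff_start"].transform("min")
    byear = stacked["patient_id"].map(birth).astype("Float64")
    age_at_rx = stacked["start"].dt.year - byear
    age_at_ep_start = ep_start.dt.year - byear

    adult = age_at_rx >= config.adult_age_threshold
    exempt_continuation = age_at_ep_start < config.adult_age_threshold
    if config.adult_approval_date is not None:
        approved = stacked["start"] >= pd.Timestamp(config.adult_approval_date)
        if config.adult_age_cap is not None:
            approved &= age_at_rx <= config.adult_age_cap
    else:
        approved = pd.Series(False, index=stacked.index)
    off = (adult & ~exempt_continuation & ~approved).fillna(False)

    per_patient = (
        pd.DataFrame({"patient_id": stacked["patient_id"], "off": off.astype(bool)})
        .groupby("patient_id")["off"]
        .any()
    )
    out[:] = out.index.map(per_patient).to_numpy(dtype=object)
    out = out.astype("boolean")
    out[out.index.map(birth.isna()).to_numpy(dtype=bool)] = pd.NA
    return out


def evaluate_offlabel(
    patients: pd.DataFrame,
    prescriptions: pd.DataFrame,
    diagnoses: pd.DataFrame,
    coverage: pd.DataFrame,
    config: CountryLabelConfig,
    gap_days: int = 30,
    boundary: str = "inclusive",
    overlap: str = "shift",
) -> pd.DataFrame:
    """Evaluate every index-drug user against the full label rule set.

    Returns one row per patient with tri-state criterion flags and the
    combined ``any_off_label`` (disjunction over evaluable criteria; the
    criteria a config does not impose — e.g. ``requires_prior_mph=False``
    — are still reported but excluded from the disjunction).
    """
    first_ldx = first_ldx_dates(prescriptions)
    out = pd.DataFrame({"patient_id": first_ldx.index})
    out["first_ldx_date"] = first_ldx.to_numpy()

    no_dx = flag_no_prior_diagnosis(diagnoses, first_ldx, patients, config)
    no_mph = flag_no_prior_mph(
        prescriptions, first_ldx, patients, config.mph_lookback_min_enrolment_days
    )
    out["no_prior_diagnosis"] = out["patient_id"].map(no_dx).astype("boolean")
    out["no_prior_mph"] = out["patient_id"].map(no_mph).astype("boolean")

    ad = flag_age_and_dose(patients, coverage, config).set_index("patient_id")
    out["under_min_age"] = out["patient_id"].map(ad["under_min_age"]).astype("boolean")
    out["dose_exceeds_cap"] = out["patient_id"].map(ad["dose_exceeds_cap"]).astype("boolean")
    out["any_rx_dose_exceeds_cap"] = (
        out["patient_id"].map(ad["any_rx_dose_exceeds_cap"]).fillna(False).astype(bool)
    )

    adult = flag_adult_off_label(patients, coverage, config, gap_days, boundary, overlap)
    out["adult_off_label"] = out["patient_id"].map(adult).astype("boolean")

    contributing = ["under_min_age", "dose_exceeds_cap", "adult_off_label"]
    if config.requires_recorded_diagnosis:
        contributing.append("no_prior_diagnosis")
    if config.requires_prior_mph:
        contributing.append("no_prior_mph")
    any_off = pd.Series(False, index=out.index)
    for col in contributing:
        any_off |= out[col].fillna(False).astype(bool)
    out["any_off_label"] = any_off
    return out[FLAG_COLUMNS]
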