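"""Cohort-level aggregation and the end-to-end pipeline.

``build_patient_table`` joins every per-patient derived measure (episodes,
exposure, average daily dose, pattern flags, off-label flags) into one
table of index-drug users; ``summarize`` reduces it to a
:class:`CohortSummary` shaped like the demographic and treatment-pattern
tables of drug-utilization reports: counts with their denominators,
percentages at full precision, and mean/SD/median/min/max for the count,
exposure and dose distributions.

Every percentage is stored alongside its denominator so any figure can be
audited; formatting (1-decimal rounding, optional small-cell suppression
below 6 as practised by some EMR data providers) happens only at display
time.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as rio
from .episodes import average_daily_dose, build_coverage, build_episodes, patient_exposure
from .offlabel import evaluate_offlabel
from .patterns import classify_patterns
from .types import AGE_BAND_LABELS, CountryLabelConfig, Drug, Sex, age_band

_STAT_SUFFIXES = ("mean", "sd", "median", "min", "max")

SUMMARY_FIELDS: list[str] = [
    "n_patients",
    "n_prescriptions",
    "male_n",
    "male_pct",
    "documented_adhd_n",
    "documented_adhd_denom",
    "documented_adhd_pct",
    *[f"age_{label.replace('-', '_').replace('>', 'gt')}_n" for label in AGE_BAND_LABELS],
    "age_evaluable_n",
    "repeat_users_n",
    "repeat_users_pct",
    *[f"rx_{s}" for s in _STAT_SUFFIXES],
    *[f"exposure_days_{s}" for s in _STAT_SUFFIXES],
    *[f"add_mg_{s}" for s in _STAT_SUFFIXES],
    "add_le_cap_n",
    "dose_over_cap_n",
    "dose_over_cap_denom",
    "dose_over_cap_pct",
    "discontinued_n",
    "discontinued_pct",
    "discontinued_naive_n",
    "censored_n",
    "switched_to_n",
    "switched_to_pct",
    "switched_from_n",
    "switched_from_pct",
    "adult_off_label_n",
    "adult_off_label_denom",
    "adult_off_label_pct",
    "no_prior_diagnosis_n",
    "no_prior_diagnosis_denom",
    "no_prior_diagnosis_pct",
    "no_prior_mph_n",
    "no_prior_mph_denom",
    "no_prior_mph_pct",
    "under_min_age_n",
    "under_min_age_denom",
    "under_min_age_pct",
    "any_off_label_n",
    "any_off_label_pct",
]


class CohortSummary:
    """Ordered field -> value mapping over :data:`SUMMARY_FIELDS`.

    Values are floats (counts are whole-valued floats; percentages in
    [0, 100]; NaN marks an undefined statistic, e.g. a percentage with a
    zero denominator).
    """

    def __init__(self, values: dict[str, float]):
        unknown = set(values) - set(SUMMARY_FIELDS)
        if unknown:
            raise ValueError(f"unknown summary fields: {sorted(unknown)}")
        self.values = {f: float(values.get(f, math.nan)) for f in SUMMARY_FIELDS}

    def __getattr__(self, name: str) -> float:
        values = self.__dict__.get("values", {})
        if name in values:
            return values[name]
        raise AttributeError(name)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __eq__(self, other) -> bool:
        if not isinstance(other, CohortSummary):
            return NotImplemented
        for f in SUMMARY_FIELDS:
            a, b = self.values[f], other.values[f]
            if math.isnan(a) and math.isnan(b):
                continue
            if not math.isclose(a, b, rel_tol=1e-12, abs_tol=1e-12):
                return False
        return True

    def __repr__(self) -> str:
        return f"CohortSummary(n_patients={self.values['n_patients']:.0f})"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"field": SUMMARY_FIELDS, "value": [self.values[f] for f in SUMMARY_FIELDS]}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CohortSummary":
        return cls(dict(zip(df["field"], df["value"].astype(float))))


def _stats(series: pd.Series) -> dict[str, float]:
    s = pd.to_numeric(series, errors="coerce").dropna()
    if s.empty:
        return dict.fromkeys(_STAT_SUFFIXES, math.nan)
    return {
        "mean": float(s.mean()),
        # sample (n-1) convention; a single observation has no spread
        "sd": 0.0 if len(s) == 1 else float(s.std(ddof=1)),
        "median": float(s.median()),
        "min": float(s.min()),
        "max": float(s.max()),
    }


def _pct(n: float, denom: float) -> float:
    return 100.0 * n / denom if denom else math.nan


def _flag_counts(col: pd.Series) -> tuple[int, int]:
    """(true count, evaluable denominator) for a tri-state flag column."""
    evaluable = col.notna()
    return int(col[evaluable].astype(bool).sum()), int(evaluable.sum())


def build_patient_table(
    patients: pd.DataFrame,
    prescriptions: pd.DataFrame,
    diagnoses: pd.DataFrame,
    config: CountryLabelConfig,
    gap_days: int = 30,
    default_supply_days: Optional[int] = 30,
    boundary: str = "inclusive",
    overlap: str = "shift",
) -> pd.DataFrame:
    """One row per index-drug user with every derived measure joined in."""
    coverage = build_coverage(prescriptions, default_supply_days)
    episodes = build_episodes(coverage, gap_days, overlap, boundary)
    exposure = patient_exposure(episodes).set_index("patient_id")
    if exposure.empty:
        return pd.DataFrame()
    add = average_daily_dose(coverage, cap_mg=config.max_daily_dose_mg).set_index("patient_id")
    flags = classify_patterns(
        coverage, prescriptions, pd.Timestamp(config.observation_end), gap_days, boundary, overlap
    ).set_index("patient_id")
    off = evaluate_offlabel(
        patients, prescriptions, diagnoses, coverage, config, gap_days, boundary, overlap
    ).set_index("patient_id")

    out = exposure.copy()
    demo = patients.set_index("patient_id")[["birth_year", "sex", "source_id"]]
    out = out.join(demo, how="left")
    out = out.join(add[["add_mg_per_day", "exceeds_cap"]].rename(columns={"exceeds_cap": "add_exceeds_cap"}))
    out = out.join(
        flags[
            [
                "discontinued",
                "discontinued_naive",
                "censored",
                "switched_to_ldx",
                "switched_from_ldx",
                "overlap_initiation",
            ]
        ]
    )
    out = out.join(off.drop(columns=["first_ldx_date"]))
    out["first_ldx_date"] = off["first_ldx_date"]

    out["age_first_ldx"] = (
        out["first_ldx_date"].dt.year - out["birth_year"].astype("Float64")
    ).astype("Float64")
    out["age_band"] = [
        age_band(int(a)) if pd.notna(a) else pd.NA for a in out["age_first_ldx"]
    ]

    # documented diagnosis: any ADHD diagnosis at or before the first index
    # prescription; not evaluable for sources that record no diagnoses
    adhd_dx = diagnoses[diagnoses["code_class"] == "ADHD"]
    first_dx = adhd_dx.groupby("patient_id")["diagnosis_date"].min()
    documented = (
        pd.Series(out.index.map(first_dx), index=out.index) <= out["first_ldx_date"]
    ).astype("boolean")
    documented[pd.Series(out.index.map(first_dx), index=out.index).isna()] = False
    records_dx = {sid: p.records_diagnoses for sid, p in config.source_map.items()}
    documented[~out["source_id"].map(records_dx).fillna(True).astype(bool)] = pd.NA
    out["documented_adhd"] = documented

    return out.reset_index()


def summarize(patient_table: pd.DataFrame, report_adult_off_label: bool = True) -> CohortSummary:
    """Aggregate a per-patient table into a :class:`CohortSummary`.

    Patients with a not-evaluable value for a criterion are excluded from
    that criterion's denominator.  With ``report_adult_off_label=False``
    the adult figure is emitted as undefined (it is still present in the
    patient table for auditing).
    """
    v: dict[str, float] = {}
    n = len(patient_table)
    v["n_patients"] = n
    if n == 0:
        for f in SUMMARY_FIELDS:
            v.setdefault(f, 0.0 if f.endswith("_n") or f.endswith("_denom") or f == "n_prescriptions" else math.nan)
        return CohortSummary(v)

    df = patient_table
    v["n_prescriptions"] = float(df["n_prescriptions"].sum())
    v["male_n"] = float((df["sex"] == Sex.male.value).sum())
    v["male_pct"] = _pct(v["male_n"], n)

    doc_n, doc_d = _flag_counts(df["documented_adhd"])
    v["documented_adhd_n"], v["documented_adhd_denom"] = doc_n, doc_d
    v["documented_adhd_pct"] = _pct(doc_n, doc_d)

    evaluable_age = df["age_band"].notna()
    v["age_evaluable_n"] = float(evaluable_age.sum())
    for label in AGE_BAND_LABELS:
        key = f"age_{label.replace('-', '_').replace('>', 'gt')}_n"
        v[key] = float((df.loc[evaluable_age, "age_band"] == label).sum())

    v["repeat_users_n"] = float(df["repeat_user"].sum())
    v["repeat_users_pct"] = _pct(v["repeat_users_n"], n)

    for key, col in (("rx", "n_prescriptions"), ("exposure_days", "duration_days")):
        for s, val in _stats(df[col]).items():
            v[f"{key}_{s}"] = val

    # dose statistics pool only patients at or below the cap (the flag for
    # exceeding it is reported separately, with its evaluable denominator)
    add = pd.to_numeric(df["add_mg_per_day"], errors="coerce")
    within = add.notna() & ~df["add_exceeds_cap"].fillna(True).astype(bool)
    for s, val in _stats(add[within]).items():
        v[f"add_mg_{s}"] = val
    v["add_le_cap_n"] = float(within.sum())
    over_n, over_d = _flag_counts(df["dose_exceeds_cap"])
    v["dose_over_cap_n"], v["dose_over_cap_denom"] = over_n, over_d
    v["dose_over_cap_pct"] = _pct(over_n, over_d)

    for key, col in (
        ("discontinued", "discontinued"),
        ("switched_to", "switched_to_ldx"),
        ("switched_from", "switched_from_ldx"),
    ):
        cnt = float(df[col].astype(bool).sum())
        v[f"{key}_n"] = cnt
        v[f"{key}_pct"] = _pct(cnt, n)
    v["discontinued_naive_n"] = float(df["discontinued_naive"].astype(bool).sum())
    v["censored_n"] = float(df["censored"].astype(bool).sum())

    if report_adult_off_label:
        a_n, a_d = _flag_counts(df["adult_off_label"])
        v["adult_off_label_n"], v["adult_off_label_denom"] = a_n, a_d
        v["adult_off_label_pct"] = _pct(a_n, a_d)
    else:
        v["adult_off_label_n"] = math.nan
        v["adult_off_label_denom"] = 0.0
        v["adult_off_label_pct"] = math.nan

    for key in ("no_prior_diagnosis", "no_prior_mph", "under_min_age"):
        f_n, f_d = _flag_counts(df[key])
        v[f"{key}_n"], v[f"{key}_denom"] = f_n, f_d
        v[f"{key}_pct"] = _pct(f_n, f_d)

    v["any_off_label_n"] = float(df["any_off_label"].astype(bool).sum())
    v["any_off_label_pct"] = _pct(v["any_off_label_n"], n)
    return CohortSummary(v)


def format_summary(
    summary: CohortSummary,
    decimals: int = 1,
    suppress_small_cells: bool = False,
) -> pd.DataFrame:
    """Human-readable view: rounded values, optional suppression of counts
    below 6 (shown as ``<6``), undefined values shown as ``NA``."""
    rows = []
    for f in SUMMARY_FIELDS:
        val = summary.values[f]
        if math.isnan(val):
            disp = "NA"
        elif f.endswith(("_n", "_denom")) or f in ("n_patients", "n_prescriptions"):
            if suppress_small_cells and 0 < val < 6:
                disp = "<6"
            else:
                disp = f"{val:.0f}"
        else:
            disp = f"{val:.{decimals}f}"
        rows.append({"field": f, "display": disp})
    return pd.DataFrame(rows)


def run_pipeline(
    config: CountryLabelConfig,
    input_dir: str | Path,
    out_dir: str | Path,
    schema: Optional[rio.SchemaConfig] = None,
    gap_days: int = 30,
    default_supply_days: Optional[int] = 30,
    boundary: str = "inclusive",
    overlap: str = "shift",
    suppress_small_cells: bool = False,
) -> dict[str, Path]:
    """Execute read -> episodes -> patterns -> off-label -> summary.

    Expects ``patients.csv``, ``prescriptions.csv`` and optionally
    ``diagnoses.csv`` in ``input_dir``; writes the per-patient table, the
    cohort summary (raw and formatted), the rejection log and a run log of
    all parameters to ``out_dir``.  Deterministic for fixed inputs.
    """
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = rio.read_cohort(
        input_dir / "patients.csv",
        input_dir / "prescriptions.csv",
        input_dir / "diagnoses.csv",
        schema=schema,
        sources=config.source_map,
    )
    patient_table = build_patient_table(
        tables.patients,
        tables.prescriptions,
        tables.diagnoses,
        config,
        gap_days,
        default_supply_days,
        boundary,
        overlap,
    )
    summary = summarize(patient_table, config.report_adult_off_label)

    paths: dict[str, Path] = {}
    pt_out = patient_table.copy()
    for col in pt_out.columns:
        if pd.api.types.is_datetime64_any_dtype(pt_out[col]):
            pt_out[col] = pt_out[col].dt.strftime("%Y-%m-%d")
    paths["patient_summary"] = out_dir / "patient_summary.csv"
    pt_out.to_csv(paths["patient_summary"], index=False)
    paths["cohort_summary"] = rio.write_cohort_summary(summary, out_dir / "cohort_summary.csv")
    paths["cohort_summary_formatted"] = out_dir / "cohort_summary_formatted.csv"
    format_summary(summary, suppress_small_cells=suppress_small_cells).to_csv(
        paths["cohort_summary_formatted"], index=False
    )
    paths["rejections"] = out_dir / "rejections.csv"
    tables.rejections.to_csv(paths["rejections"], index=False)

    run_log = {
        "country": config.country,
        "gap_days": gap_days,
        "default_supply_days": default_supply_days,
        "boundary": boundary,
        "overlap": overlap,
        "suppress_small_cells": suppress_small_cells,
        "observation_start": str(config.observation_start),
        "observation_end": str(config.observation_end),
        "n_patients_read": int(len(tables.patients)),
        "n_prescriptions_read": int(len(tables.prescriptions)),
        "n_diagnoses_read": int(len(tables.diagnoses)),
        "n_rejected_rows": int((tables.rejections["action"] == "rejected").sum()),
        "n_index_users": int(len(patient_table)),
    }
    paths["run_log"] = out_dir / "run_log.json"
    with open(paths["run_log"], "w", encoding="utf-8") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
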