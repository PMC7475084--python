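"""Reading and writing the delimited-text interchange formats.

Three tables travel between pipeline stages: patients, prescriptions and
diagnoses, as UTF-8 delimited text with a header row.  A ``SchemaConfig``
maps source column names and drug/diagnosis vocabularies (e.g. ATC codes)
onto the internal schema, so files from different databases can be ingested
without renaming by hand.

Validation is conservative and auditable: every input row is either loaded,
loaded-with-coercion, or rejected, and the rejection log records the file,
1-based line number, patient and reason — the row counts of input, output
and log always reconcile.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .types import Drug, Sex, SourceProfile

PATIENT_COLUMNS = [
    "patient_id",
    "birth_year",
    "sex",
    "enrolment_start",
    "enrolment_end",
    "source_id",
]
PRESCRIPTION_COLUMNS = [
    "patient_id",
    "drug",
    "issue_date",
    "strength_mg",
    "quantity",
    "daily_dose_instruction_mg",
    "supply_days",
]
DIAGNOSIS_COLUMNS = ["patient_id", "code_class", "diagnosis_date"]

REJECTION_COLUMNS = ["table", "line", "patient_id", "reason", "action"]


class SchemaConfig(BaseModel):
    """How to interpret the three input files.

    ``drug_code_map`` translates source drug codes to :class:`~rxdur.types.Drug`
    role names; codes absent from the map are handled per ``unknown_drug``
    ('reject' the row, or 'map_non_adhd' to treat it as non-study medication).
    """

    delimiter: str = ","
    patient_columns: dict[str, str] = Field(default_factory=dict)
    prescription_columns: dict[str, str] = Field(default_factory=dict)
    diagnosis_columns: dict[str, str] = Field(default_factory=dict)
    drug_code_map: dict[str, str] = Field(
        default_factory=lambda: {d.value: d.value for d in Drug}
    )
    diagnosis_code_map: dict[str, str] = Field(
        default_factory=lambda: {"ADHD": "ADHD", "other": "other"}
    )
    unknown_drug: str = "reject"  # or "map_non_adhd"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SchemaConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})


class CohortTables(NamedTuple):
    """Validated event tables plus the rejection log."""

    patients: pd.DataFrame
    prescriptions: pd.DataFrame
    diagnoses: pd.DataFrame
    rejections: pd.DataFrame


def _empty_rejections() -> pd.DataFrame:
    return pd.DataFrame(columns=REJECTION_COLUMNS)


def _read_raw(path: str | Path, delimiter: str, rename: dict[str, str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=True)
    if rename:
        df = df.rename(columns={v: k for k, v in rename.items()})
    return df


def _lines(df: pd.DataFrame) -> pd.Series:
    # header is line 1; first data row is line 2
    return pd.Series(df.index + 2, index=df.index)


def _parse_dates(df: pd.DataFrame, col: str) -> pd.Series:
    return pd.to_datetime(df.get(col), format="ISO8601", errors="coerce")


def read_cohort(
    patients_path: str | Path,
    prescriptions_path: str | Path,
    diagnoses_path: Optional[str | Path] = None,
    schema: Optional[SchemaConfig] = None,
    sources: Optional[dict[str, SourceProfile]] = None,
) -> CohortTables:
    """Read and validate the three event tables.

    Parameters
    ----------
    patients_path, prescriptions_path, diagnoses_path
        Delimited text files; ``diagnoses_path`` may be ``None`` for sources
        that record no diagnoses.
    schema
        Column/vocabulary mapping; defaults to the identity schema.
    sources
        ``source_id -> SourceProfile``; when given, diagnosis rows whose
        patient belongs to a source with ``records_diagnoses=False`` are
        rejected (such a source cannot legitimately carry diagnoses).

    Returns
    -------
    CohortTables
        Typed tables with all invariants enforced, plus the rejection log.
    """
    schema = schema or SchemaConfig()
    rejects: list[pd.DataFrame] = []

    # ---- patients -------------------------------------------------------
    pat = _read_raw(patients_path, schema.delimiter, schema.patient_columns)
    for col in PATIENT_COLUMNS:
        if col not in pat.columns:
            pat[col] = np.nan
    pat["line"] = _lines(pat)
    pat["enrolment_start"] = _parse_dates(pat, "enrolment_start")
    pat["enrolment_end"] = _parse_dates(pat, "enrolment_end")
    pat["birth_year"] = pd.to_numeric(pat["birth_year"], errors="coerce").astype("Int64")
    pat["sex"] = (
        pat["sex"].str.lower().where(pat["sex"].str.lower().isin([s.value for s in Sex]))
    ).fillna(Sex.unknown.value)
    pat["source_id"] = pat["source_id"].fillna("default")

    bad_dates = pat["enrolment_start"].isna() | pat["enrolment_end"].isna()
    bad_order = ~bad_dates & (pat["enrolment_start"] > pat["enrolment_end"])
    implausible = pat["birth_year"].notna() & ~pat["birth_year"].between(
        1900, dt.date.today().year
    )
    rejects.append(
        _log(pat[bad_dates], "patients", "unparseable enrolment date", "rejected")
    )
    rejects.append(
        _log(pat[bad_order], "patients", "enrolment_start after enrolment_end", "rejected")
    )
    rejects.append(
        _log(pat[implausible], "patients", "implausible birth_year set to missing", "coerced")
    )
    pat.loc[implausible, "birth_year"] = pd.NA
    pat = pat[~(bad_dates | bad_order)].drop(columns="line").reset_index(drop=True)

    enrol = pat.set_index("patient_id")[["enrolment_start", "enrolment_end", "source_id"]]

    # ---- prescriptions --------------------------------------------------
    rx = _read_raw(prescriptions_path, schema.delimiter, schema.prescription_columns)
    for col in PRESCRIPTION_COLUMNS:
        if col not in rx.columns:
            rx[col] = np.nan
    rx["line"] = _lines(rx)
    rx["issue_date"] = _parse_dates(rx, "issue_date")
    for col in ("strength_mg", "quantity", "daily_dose_instruction_mg", "supply_days"):
        rx[col] = pd.to_numeric(rx[col], errors="coerce")

    mapped = rx["drug"].map(schema.drug_code_map)
    unknown = mapped.isna() & rx["drug"].notna()
    if schema.unknown_drug == "map_non_adhd":
        rejects.append(_log(rx[unknown], "prescriptions", "unknown drug code mapped to non_ADHD", "coerced"))
        mapped = mapped.where(~unknown, Drug.NON_ADHD.value)
        unknown = pd.Series(False, index=rx.index)
    rx["drug"] = mapped

    bad_date = rx["issue_date"].isna()
    bad_drug = unknown | rx["drug"].isna()
    nonpos = pd.Series(False, index=rx.index)
    for col in ("strength_mg", "quantity", "daily_dose_instruction_mg", "supply_days"):
        nonpos |= rx[col].notna() & (rx[col] <= 0)
    rx = rx.join(enrol, on="patient_id")
    no_patient = rx["enrolment_start"].isna()
    outside = ~no_patient & ~bad_date & (
        (rx["issue_date"] < rx["enrolment_start"]) | (rx["issue_date"] > rx["enrolment_end"])
    )
    rejects.append(_log(rx[bad_date], "prescriptions", "unparseable issue_date", "rejected"))
    rejects.append(_log(rx[bad_drug & ~bad_date], "prescriptions", "unknown drug code", "rejected"))
    rejects.append(_log(rx[nonpos & ~bad_date & ~bad_drug], "prescriptions", "non-positive strength/quantity/dose/supply", "rejected"))
    rejects.append(_log(rx[no_patient & ~bad_date & ~bad_drug & ~nonpos], "prescriptions", "patient_id not in patients table", "rejected"))
    rejects.append(_log(rx[outside & ~bad_drug & ~nonpos], "prescriptions", "issue_date outside patient enrolment", "rejected"))
    keep = ~(bad_date | bad_drug | nonpos | no_patient | outside)
    rx = (
        rx[keep]
        .drop(columns=["line", "enrolment_start", "enrolment_end", "source_id"])
        .reset_index(drop=True)
    )
    rx["supply_days"] = rx["supply_days"].astype("Int64")

    # ---- diagnoses ------------------------------------------------------
    if diagnoses_path is not None and Path(diagnoses_path).exists():
        dx = _read_raw(diagnoses_path, schema.delimiter, schema.diagnosis_columns)
    else:
        dx = pd.DataFrame(columns=DIAGNOSIS_COLUMNS)
    for col in DIAGNOSIS_COLUMNS:
        if col not in dx.columns:
            dx[col] = np.nan
    dx["line"] = _lines(dx)
    dx["diagnosis_date"] = _parse_dates(dx, "diagnosis_date")
    dx["code_class"] = dx["code_class"].map(schema.diagnosis_code_map)

    bad_date = dx["diagnosis_date"].isna()
    bad_class = ~bad_date & dx["code_class"].isna()
    dx = dx.join(enrol, on="patient_id")
    no_patient = dx["enrolment_start"].isna()
    # historical diagnoses (before enrolment) are allowed; future ones are not
    late = ~no_patient & ~bad_date & (dx["diagnosis_date"] > dx["enrolment_end"])
    if sources:
        records_dx = dx["source_id"].map(
            {k: v.records_diagnoses for k, v in sources.items()}
        ).fillna(True).astype(bool)
    else:
        records_dx = pd.Series(True, index=dx.index)
    no_dx_source = ~no_patient & ~records_dx
    rejects.append(_log(dx[bad_date], "diagnoses", "unparseable diagnosis_date", "rejected"))
    rejects.append(_log(dx[bad_class], "diagnoses", "unknown diagnosis code", "rejected"))
    rejects.append(_log(dx[no_patient & ~bad_date & ~bad_class], "diagnoses", "patient_id not in patients table", "rejected"))
    rejects.append(_log(dx[late & ~bad_class], "diagnoses", "diagnosis_date after enrolment_end", "rejected"))
    rejects.append(_log(dx[no_dx_source & ~bad_date & ~bad_class & ~late], "diagnoses", "source does not record diagnoses", "rejected"))
    keep = ~(bad_date | bad_class | no_patient | late | no_dx_source)
    dx = (
        dx[keep]
        .drop(columns=["line", "enrolment_start", "enrolment_end", "source_id"])
        .reset_index(drop=True)
    )

    nonempty = [r for r in rejects if len(r)]
    rejections = (
        pd.concat(nonempty, ignore_index=True) if nonempty else _empty_rejections()
    )
    return CohortTables(
        pat[PATIENT_COLUMNS], rx[PRESCRIPTION_COLUMNS], dx[DIAGNOSIS_COLUMNS], rejections
    )


def _log(rows: pd.DataFrame, table: str, reason: str, action: str) -> pd.DataFrame:
    if rows.empty:
        return _empty_rejections()
    return pd.DataFrame(
        {
            "table": table,
            "line": rows["line"].to_numpy(),
            "patient_id": rows.get("patient_id", pd.Series(index=rows.index)).to_numpy(),
            "reason": reason,
            "action": action,
        }
    )


def write_cohort(
    tables: CohortTables | tuple,
    out_dir: str | Path,
    delimiter: str = ",",
) -> dict[str, Path]:
    """Write the three event tables (and any rejection log) to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    patients, prescriptions, diagnoses = tables[0], tables[1], tables[2]
    rejections = tables[3] if len(tables) > 3 else None
    paths = {}
    for name, df, cols in (
        ("patients", patients, PATIENT_COLUMNS),
        ("prescriptions", prescriptions, PRESCRIPTION_COLUMNS),
        ("diagnoses", diagnoses, DIAGNOSIS_COLUMNS),
    ):
        path = out_dir / f"{name}.csv"
        out = df.copy()
        for col in out.columns:
            if pd.api.types.is_datetime64_any_dtype(out[col]):
                out[col] = out[col].dt.strftime("%Y-%m-%d")
        out[cols].to_csv(path, sep=delimiter, index=False)
        paths[name] = path
    if rejections is not None:
        path = out_dir / "rejections.csv"
        rejections.to_csv(path, sep=delimiter, index=False)
        paths["rejections"] = path
    return paths


def write_cohort_summary(summary, path: str | Path, delimiter: str = ",") -> Path:
    """Write a cohort summary as a two-column (field, value) delimited file."""
    path = Path(path)
    summary.to_frame().to_csv(path, sep=delimiter, index=False)
    return path


def read_cohort_summary(path: str | Path, delimiter: str = ","):
    """Read a cohort summary written by :func:`write_cohort_summary`."""
    from .reporting import CohortSummary

    df = pd.read_csv(path, sep=delimiter)
    return CohortSummary.from_frame(df)
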