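"""Core domain types for drug-utilization analysis.

The pipeline studies how an index drug — by default lisdexamfetamine (LDX),
a long-acting amphetamine prodrug used in ADHD — is prescribed over time in
longitudinal databases: prescription events, treatment episodes, persistence,
switching, and compliance with the drug label.  Drugs are *roles*, not codes:
the index drug (LDX), the required first-line comparator (MPH,
methylphenidate), other ADHD medication (ATX = atomoxetine kept as its own
role because it is the classic switch destination), and everything else.
A config-supplied mapping translates source vocabularies (e.g. ATC codes)
into these roles, so the machinery is drug-agnostic.

Dates are ISO-8601 calendar dates and every interval is closed-open
``[start, end)`` in whole days.  Ages are computed at year granularity
(event year minus birth year), matching what prescription registries
typically expose.
"""

from __future__ import annotations

import datetime as dt
import enum
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator


class Drug(str, enum.Enum):
    """Drug roles used by the analysis."""

    LDX = "LDX"
    MPH = "MPH"
    ATX = "ATX"
    OTHER_ADHD = "other_ADHD"
    NON_ADHD = "non_ADHD"


#: Roles that count as ADHD medication (eligible as switch evidence).
ADHD_DRUGS = frozenset({Drug.LDX, Drug.MPH, Drug.ATX, Drug.OTHER_ADHD})

#: ADHD medication other than the index drug.
OTHER_ADHD_DRUGS = frozenset({Drug.MPH, Drug.ATX, Drug.OTHER_ADHD})


class Sex(str, enum.Enum):
    male = "male"
    female = "female"
    unknown = "unknown"


#: Age bands used in demographic tables (upper edges inclusive; last open).
AGE_BANDS = (
    ("0-5", 0, 5),
    ("6-12", 6, 12),
    ("13-18", 13, 18),
    ("19-25", 19, 25),
    (">25", 26, 200),
)

AGE_BAND_LABELS = tuple(label for label, _, _ in AGE_BANDS)


def age_band(age: int) -> str:
    """Return the demographic band label for an integer age."""
    for label, lo, hi in AGE_BANDS:
        if lo <= age <= hi:
            return label
    raise ValueError(f"age {age} outside supported range")


class PatientRecord(BaseModel):
    """One patient as known to a source database."""

    patient_id: str
    birth_year: Optional[int] = None
    sex: Sex = Sex.unknown
    enrolment_start: dt.date
    enrolment_end: dt.date
    source_id: str = "default"

    @model_validator(mode="after")
    def _check(self) -> "PatientRecord":
        if self.enrolment_start > self.enrolment_end:
            raise ValueError("enrolment_start after enrolment_end")
        if self.birth_year is not None and not (
            1900 <= self.birth_year <= dt.date.today().year
        ):
            raise ValueError(f"implausible birth_year {self.birth_year}")
        return self


class PrescriptionRecord(BaseModel):
    """One dispensing / prescription issue event.

    ``supply_days`` is the recorded days' supply where the source captures
    it; otherwise coverage length is derived from quantity, strength and the
    dosing instruction, or falls back to a configured default.
    """

    patient_id: str
    drug: Drug
    issue_date: dt.date
    strength_mg: Optional[float] = Field(default=None, gt=0)
    quantity: Optional[float] = Field(default=None, gt=0)
    daily_dose_instruction_mg: Optional[float] = Field(default=None, gt=0)
    supply_days: Optional[int] = Field(default=None, gt=0)


class DiagnosisRecord(BaseModel):
    """A dated diagnosis, classified as the study indication (ADHD) or other."""

    patient_id: str
    code_class: str = "ADHD"
    diagnosis_date: dt.date

    @field_validator("code_class")
    @classmethod
    def _cls(cls, v: str) -> str:
        if v not in {"ADHD", "other"}:
            raise ValueError("code_class must be 'ADHD' or 'other'")
        return v


class SourceProfile(BaseModel):
    """What a source database records.

    Pharmacy panels may lack diagnoses (Swiss PPP/SDPP), ages or supply
    durations (SDPP); flags here drive not-evaluable propagation downstream.
    """

    source_id: str
    records_diagnoses: bool = True
    records_ages: bool = True
    records_durations: bool = True
    description: str = ""


class CountryLabelConfig(BaseModel):
    """Declarative label rules and observation window for one jurisdiction.

    The defaults encode the paediatric label of the index drug: second-line
    after MPH, minimum age 6 years, maximum 70 mg/day.  Adult use is
    off-label unless an adult approval is in force at the prescription date
    (optionally with an age cap, e.g. 55 years in Switzerland) or treatment
    continued from adolescence.
    """

    country: str
    launch_date: dt.date
    adult_approval_date: Optional[dt.date] = None
    adult_age_cap: Optional[int] = None
    observation_start: dt.date
    observation_end: dt.date
    min_label_age: int = 6
    adult_age_threshold: int = 19
    max_daily_dose_mg: float = 70.0
    requires_prior_mph: bool = True
    requires_recorded_diagnosis: bool = True
    mph_lookback_min_enrolment_days: int = 365
    #: report the adult-off-label figure (False where it is not reportable,
    #: e.g. a label extension mid-window makes the pre-extension count moot)
    report_adult_off_label: bool = True
    sources: list[SourceProfile] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "CountryLabelConfig":
        if self.observation_start > self.observation_end:
            raise ValueError("observation_start after observation_end")
        return self

    @property
    def source_map(self) -> dict[str, SourceProfile]:
        return {s.source_id: s for s in self.sources}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CountryLabelConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        payload = self.model_dump(mode="json")
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def load_country_config(country: str) -> CountryLabelConfig:
    """Load a shipped country fixture by name (case-insensitive)."""
    path = Path(__file__).parent / "configs" / f"{country.lower()}.yaml"
    if not path.exists():
        available = sorted(p.stem for p in path.parent.glob("*.yaml"))
        raise FileNotFoundError(
            f"no shipped config for {country!r}; available: {available}"
        )
    return CountryLabelConfig.from_yaml(path)


def available_countries() -> list[str]:
    return sorted(p.stem for p in (Path(__file__).parent / "configs").glob("*.yaml"))
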