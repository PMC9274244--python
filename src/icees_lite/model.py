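"""Canonical in-memory clinical data model.

One simplified common-data-model layer: patients plus dated condition,
encounter, and procedure records. Both the CSV reader and the FHIR-subset
reader produce :class:`ClinicalDataset`, and every downstream stage
(exposure linkage, binning, cohort rules, analytics) consumes it.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional

SEXES = ("Male", "Female", "Unknown")
RACES = ("Caucasian", "African American", "Asian", "Other", "Unknown")
ETHNICITIES = ("Hispanic or Latino", "Not Hispanic or Latino", "Missing")
ENCOUNTER_CLASSES = ("ED", "inpatient", "outpatient", "NICU")


class DomainError(ValueError):
    """Input outside the operation's stated domain (bad coordinate, negative age, ...)."""


class IntegrityError(ValueError):
    """Referential or uniqueness violation in a dataset (orphan event, duplicate id)."""


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


def normalize_code(code: str) -> str:
    """Normalize a diagnosis/procedure code for prefix matching.

    Dots are removed and letters uppercased, so ``"E84.0"`` and ``"e840"``
    both normalize to ``"E840"`` and match the prefix ``"E84"``.
    """
    return code.replace(".", "").strip().upper()


def code_matches(code: str, prefixes) -> bool:
    """True if the normalized code starts with any normalized prefix."""
    norm = normalize_code(code)
    return any(norm.startswith(normalize_code(p)) for p in prefixes)


@dataclass(frozen=True)
class StudyPeriod:
    """A closed date interval; analyses run over one such period (default one calendar year)."""

    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DomainError(f"study period start {self.start} after end {self.end}")

    @classmethod
    def calendar_year(cls, year: int) -> "StudyPeriod":
        return cls(dt.date(year, 1, 1), dt.date(year, 12, 31))

    def contains(self, d: dt.date) -> bool:
        return self.start <= d <= self.end


@dataclass
class PatientRecord:
    """One patient; coordinate sanity is checked by the report-only validator,
    not at construction, so malformed inputs can be loaded and audited."""

    patient_id: str
    birth_date: dt.date
    sex: str = "Unknown"
    race: str = "Unknown"
    ethnicity: str = "Missing"
    geopoint: Optional[tuple[float, float]] = None  # (lat, lon), degrees
    block_group_id: Optional[str] = None
    geocode_timestamp: Optional[dt.date] = None


@dataclass
class ConditionRecord:
    patient_id: str
    code: str
    date: dt.date


@dataclass
class EncounterRecord:
    patient_id: str
    encounter_class: str
    date: dt.date
    location_tag: Optional[str] = None
    reason_codes: list[str] = field(default_factory=list)
    gestational_age_weeks: Optional[float] = None


@dataclass
class ProcedureRecord:
    patient_id: str
    code: str
    date: dt.date


@dataclass
class ClinicalDataset:
    """Patients plus their dated clinical event records.

    ``provenance`` and ``metadata`` describe where the data came from and are
    excluded from equality: two datasets are equal when their records are.
    """

    patients: list[PatientRecord] = field(default_factory=list)
    conditions: list[ConditionRecord] = field(default_factory=list)
    encounters: list[EncounterRecord] = field(default_factory=list)
    procedures: list[ProcedureRecord] = field(default_factory=list)
    provenance: str = field(default="", compare=False)
    metadata: dict = field(default_factory=dict, compare=False)

    def patient_ids(self) -> set[str]:
        return {p.patient_id for p in self.patients}

    def patients_by_id(self) -> dict[str, PatientRecord]:
        return {p.patient_id: p for p in self.patients}

    def events_for(self, patient_id: str):
        """(conditions, encounters, procedures) belonging to one patient."""
        return (
            [c for c in self.conditions if c.patient_id == patient_id],
            [e for e in self.encounters if e.patient_id == patient_id],
            [p for p in self.procedures if p.patient_id == patient_id],
        )


@dataclass(frozen=True)
class RoadSegment:
    """A straight roadway segment between two (lat, lon) endpoints."""

    endpoints: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        a, b = self.endpoints
        if a == b:
            raise DomainError(f"degenerate road segment at {a}")


@dataclass
class SourceRegistry:
    """Environmental point/polyline sources plus block-group populations."""

    cafo_points: list[tuple[float, float]] = field(default_factory=list)
    landfill_points: list[tuple[float, float]] = field(default_factory=list)
    road_segments: list[RoadSegment] = field(default_factory=list)
    block_groups: dict[str, int] = field(default_factory=dict)


@dataclass
class ExposureProfile:
    """Per-patient exposure estimates; all fields absent iff the patient lacks a valid geocode."""

    dist_cafo_m: Optional[float] = None
    dist_landfill_m: Optional[float] = None
    dist_road_m: Optional[float] = None
    block_population: Optional[int] = None
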