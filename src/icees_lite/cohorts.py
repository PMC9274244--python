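"""Rule-based cohort selection and the respiratory-visit outcome.

The rare pulmonary disease cohort is defined by two criterion groups —
(1) hospital/clinic locations visited and (2) qualifying diagnoses or
procedures, several with age-at-event bounds — combined with AND or OR.
The cystic-fibrosis subcohort is patients with ≥1 in-period E84 diagnosis
code and an active record (≥1 encounter of any class in-period). The health
outcome is the count of ED or inpatient encounters with a respiratory reason
code, dichotomized 0 (better) vs ≥1 (poor).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional

from .model import (
    ClinicalDataset,
    ConfigError,
    DomainError,
    StudyPeriod,
    code_matches,
)

CRITERION_KINDS = ("visit_location", "diagnosis", "procedure", "nicu_admission")

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class Criterion:
    """One inclusion rule: a location-visit, diagnosis, procedure, or NICU-admission test.

    ``age_at_event_max`` is a strict upper bound in years on age at the event
    date, evaluated on exact day arithmetic so sub-year bounds (0.5 years for
    echocardiograms, 1 year for tympanostomy tubes) behave correctly.
    """

    kind: str
    match: frozenset[str] = frozenset()
    age_at_event_max: Optional[float] = None
    gestational_age_min_weeks: Optional[float] = None
    min_occurrences: int = 1

    def __post_init__(self) -> None:
        if self.kind not in CRITERION_KINDS:
            raise ConfigError(f"unknown criterion kind {self.kind!r}")
        if self.min_occurrences < 1:
            raise ConfigError("min_occurrences must be ≥ 1")
        if self.gestational_age_min_weeks is not None and self.kind != "nicu_admission":
            raise ConfigError("gestational_age_min_weeks only applies to nicu_admission")
        if self.kind in ("visit_location", "nicu_admission") and self.age_at_event_max is not None:
            raise ConfigError(f"age_at_event_max does not apply to kind {self.kind!r}")


@dataclass(frozen=True)
class CriteriaConfig:
    location_criteria: tuple[Criterion, ...] = ()
    clinical_criteria: tuple[Criterion, ...] = ()
    combiner: str = "AND"

    def __post_init__(self) -> None:
        if self.combiner not in ("AND", "OR"):
            raise ConfigError(f"combiner must be AND or OR, got {self.combiner!r}")
        if not self.location_criteria and not self.clinical_criteria:
            raise ConfigError("at least one criterion is required")


@dataclass(frozen=True)
class OutcomeSpec:
    """ED/inpatient visits whose reason codes match the respiratory prefix set."""

    period: StudyPeriod
    encounter_classes: frozenset[str] = frozenset({"ED", "inpatient"})
    reason_code_prefixes: frozenset[str] = frozenset({"J"})

    def __post_init__(self) -> None:
        if not self.encounter_classes:
            raise ConfigError("encounter_classes must be non-empty")
        if not self.reason_code_prefixes:
            raise ConfigError("reason_code_prefixes must be non-empty")


def _age_years_at(birth_date: dt.date, event_date: dt.date) -> float:
    return (event_date - birth_date).days / DAYS_PER_YEAR


def evaluate_criterion(patient_events, patient, c: Criterion) -> bool:
    """True iff the patient has ≥ min_occurrences events qualifying under the criterion."""
    conditions, encounters, procedures = patient_events
    hits = 0
    if c.kind == "visit_location":
        hits = sum(1 for e in encounters if e.location_tag in c.match)
    elif c.kind == "nicu_admission":
        hits = sum(
            1 for e in encounters
            if e.encounter_class == "NICU"
            and (c.gestational_age_min_weeks is None
                 or (e.gestational_age_weeks is not None
                     and e.gestational_age_weeks >= c.gestational_age_min_weeks))
        )
    elif c.kind in ("diagnosis", "procedure"):
        records = conditions if c.kind == "diagnosis" else procedures
        for r in records:
            if not code_matches(r.code, c.match):
                continue
            if c.age_at_event_max is not None and \
                    _age_years_at(patient.birth_date, r.date) >= c.age_at_event_max:
                continue
            hits += 1
    return hits >= c.min_occurrences


def select_cohort(ds: ClinicalDataset, cfg: CriteriaConfig, period: StudyPeriod) -> set[str]:
    """Patient ids satisfying (any location criterion) COMBINER (any clinical criterion).

    Events outside the study period are ignored. An empty criterion group is
    treated as unconstrained under AND (so a location-only config still works).
    """
    result: set[str] = set()
    conditions_by, encounters_by, procedures_by = {}, {}, {}
    for c in ds.conditions:
        if period.contains(c.date):
            conditions_by.setdefault(c.patient_id, []).append(c)
    for e in ds.encounters:
        if period.contains(e.date):
            encounters_by.setdefault(e.patient_id, []).append(e)
    for p in ds.procedures:
        if period.contains(p.date):
            procedures_by.setdefault(p.patient_id, []).append(p)

    for patient in ds.patients:
        pid = patient.patient_id
        events = (
            conditions_by.get(pid, []),
            encounters_by.get(pid, []),
            procedures_by.get(pid, []),
        )
        loc = any(evaluate_criterion(events, patient, c) for c in cfg.location_criteria)
        clin = any(evaluate_criterion(events, patient, c) for c in cfg.clinical_criteria)
        if cfg.combiner == "AND":
            ok = (loc or not cfg.location_criteria) and (clin or not cfg.clinical_criteria)
        else:
            ok = loc or clin
        if ok:
            result.add(pid)
    return result


def is_active(patient_id: str, ds: ClinicalDataset, period: StudyPeriod) -> bool:
    """Active record: at least one encounter of any class within the period."""
    if patient_id not in ds.patient_ids():
        raise DomainError(f"unknown patient id {patient_id!r}")
    return any(
        e.patient_id == patient_id and period.contains(e.date) for e in ds.encounters
    )


def select_cf_subcohort(ds: ClinicalDataset, period: StudyPeriod,
                        cf_prefixes=("E84",)) -> set[str]:
    """Patients with ≥1 in-period cystic-fibrosis (E84) diagnosis code and an active record."""
    with_cf = {
        c.patient_id for c in ds.conditions
        if period.contains(c.date) and code_matches(c.code, cf_prefixes)
    }
    active = {
        e.patient_id for e in ds.encounters if period.contains(e.date)
    }
    return with_cf & active & ds.patient_ids()


def respiratory_visit_count(patient_id: str, ds: ClinicalDataset, spec: OutcomeSpec) -> int:
    """In-period ED/inpatient encounters with ≥1 reason code matching the respiratory prefixes."""
    if patient_id not in ds.patient_ids():
        raise DomainError(f"unknown patient id {patient_id!r}")
    return sum(
        1 for e in ds.encounters
        if e.patient_id == patient_id
        and e.encounter_class in spec.encounter_classes
        and spec.period.contains(e.date)
        and any(code_matches(code, spec.reason_code_prefixes) for code in e.reason_codes)
    )


def respiratory_visit_counts(ds: ClinicalDataset, spec: OutcomeSpec) -> dict[str, int]:
    """Per-patient respiratory visit counts for the whole dataset in one pass."""
    counts = {p.patient_id: 0 for p in ds.patients}
    for e in ds.encounters:
        if (e.patient_id in counts
                and e.encounter_class in spec.encounter_classes
                and spec.period.contains(e.date)
                and any(code_matches(c, spec.reason_code_prefixes) for c in e.reason_codes)):
            counts[e.patient_id] += 1
    return counts


def dichotomize(count: int) -> str:
    """0 visits → ``better`` outcome; ≥1 → ``poor``."""
    if count < 0:
        raise DomainError(f"negative visit count {count}")
    return "better" if count == 0 else "poor"


HISTOGRAM_LABELS = ("0", "1", "2", "3", "4", "5", "6", "7", "8", "9+")


def visit_histogram(counts) -> dict[str, int]:
    """Visit-count histogram with exact bins 0–8 and a top-coded 9+ bin."""
    hist = {label: 0 for label in HISTOGRAM_LABELS}
    for n in counts:
        if n < 0:
            raise DomainError(f"negative visit count {n}")
        hist[str(n) if n < 9 else "9+"] += 1
    return hist


# Default inclusion criteria for the rare pulmonary disease cohort. Location
# tags and several code sets (CPT respiratory/physical-therapy qualifiers,
# semen analysis) have no published enumeration, so these are configurable
# placeholders shaped like the clinical intent.
DEFAULT_CRITERIA = CriteriaConfig(
    location_criteria=(
        Criterion("visit_location", frozenset({"adult_pulmonary_clinic"})),
        Criterion("visit_location", frozenset({"pediatric_clinic"})),
        Criterion("visit_location", frozenset({"male_infertility_clinic"})),
        Criterion("visit_location", frozenset({"adult_inpatient"})),
        Criterion("visit_location", frozenset({"pediatric_inpatient_resp_pt"})),
        Criterion("nicu_admission", gestational_age_min_weeks=35.0),
    ),
    clinical_criteria=(
        # congenital heart disease with laterality defect
        Criterion("diagnosis", frozenset({"Q20", "Q893"})),
        Criterion("procedure", frozenset({"SINUS"}), age_at_event_max=6.0),
        Criterion("procedure", frozenset({"TYMP"}), age_at_event_max=1.0),
        Criterion("procedure", frozenset({"ECHO"}), age_at_event_max=0.5),
        Criterion("diagnosis", frozenset({"Q893"})),       # Kartagener's / situs inversus
        Criterion("diagnosis", frozenset({"J47"})),        # bronchiectasis
        Criterion("procedure", frozenset({"SEMEN"})),
        Criterion("diagnosis", frozenset({"N46"})),        # male infertility
    ),
    combiner="AND",
)
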