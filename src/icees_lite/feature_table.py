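"""De-identified integrated feature table.

Coarsens patient-level clinical + exposure data into one row per patient of
binned categorical values, per the HIPAA Safe-Harbor-plus-binning design:
ages computed at day one of the study period and capped at 89, diagnosis
counts recoded 0 / 1 / >1, exposure distances and residential density binned,
and direct identifiers replaced by a salted pseudonymous key. The emitted
table carries no raw birth date, address, coordinate, or free text.
"""

from __future__ import annotations

import datetime as dt
import hashlib
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .model import (
    ClinicalDataset,
    ConfigError,
    DomainError,
    SourceRegistry,
    StudyPeriod,
    code_matches,
)
from .geospatial import exposure_profile

MISSING = "Missing"


@dataclass(frozen=True)
class Bin:
    label: str
    lo: float          # inclusive unless lo_open
    hi: float          # exclusive unless hi_closed
    lo_open: bool = False
    hi_closed: bool = False

    def contains(self, x: float) -> bool:
        above = x > self.lo if self.lo_open else x >= self.lo
        below = x <= self.hi if self.hi_closed else x < self.hi
        return above and below


@dataclass(frozen=True)
class BinningScheme:
    """Ordered, mutually exclusive, jointly exhaustive bins for one numeric feature."""

    feature: str
    bins: tuple[Bin, ...]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(b.label for b in self.bins)

    def bin(self, x: float) -> str:
        if x < 0:
            raise DomainError(f"{self.feature}: negative value {x}")
        matches = [b.label for b in self.bins if b.contains(x)]
        if len(matches) != 1:
            raise DomainError(
                f"{self.feature}: value {x} matched {len(matches)} bins (scheme not total/exclusive)"
            )
        return matches[0]


INF = float("inf")

AGE_SCHEME = BinningScheme("age", (
    Bin("<5", 0, 5),
    Bin("5–17", 5, 18),
    Bin("18–44", 18, 45),
    Bin("45–64", 45, 65),
    Bin("65–89", 65, 90),
))

COUNT_SCHEME = BinningScheme("diagnosis_count", (
    Bin("0", 0, 1),
    Bin("1", 1, 2),
    Bin(">1", 2, INF, hi_closed=True),
))

ROADWAY_SCHEME = BinningScheme("roadway_distance", (
    Bin("0–49", 0, 50),
    Bin("50–99", 50, 100),
    Bin("100–149", 100, 150),
    Bin("150–199", 150, 200),
    Bin("200–249", 200, 250),
    Bin("≥250", 250, INF, hi_closed=True),
))

# the ">4,000" label forces a strict bound, so 4,000 m falls in the fourth bin
SITE_SCHEME = BinningScheme("site_distance", (
    Bin("<500", 0, 500),
    Bin("500–1,000", 500, 1000),
    Bin("1,000–2,000", 1000, 2000),
    Bin("2,000–4,000", 2000, 4000, hi_closed=True),
    Bin(">4,000", 4000, INF, lo_open=True, hi_closed=True),
))

DENSITY_SCHEME = BinningScheme("residential_density", (
    Bin("rural", 0, 2500),
    Bin("urban cluster", 2500, 50000),
    Bin("urbanized area", 50000, INF, hi_closed=True),
))

SEX_LEVELS = ("Male", "Female", "Unknown")
RACE_LEVELS = ("Caucasian", "African American", "Asian", "Other", "Unknown")
ETHNICITY_LEVELS = ("Hispanic or Latino", "Not Hispanic or Latino", "Missing")
OUTCOME_LEVELS = ("better", "poor")

EXPOSURE_COLUMNS = {
    "cafo_distance": SITE_SCHEME,
    "landfill_distance": SITE_SCHEME,
    "roadway_distance": ROADWAY_SCHEME,
    "residential_density": DENSITY_SCHEME,
}


def level_order(column: str, diagnosis_features=()) -> tuple[str, ...]:
    """Ordered category labels for a feature-table column (scan row order)."""
    if column == "age":
        return AGE_SCHEME.labels
    if column == "sex":
        return SEX_LEVELS
    if column == "race":
        return RACE_LEVELS
    if column == "ethnicity":
        return ETHNICITY_LEVELS
    if column in EXPOSURE_COLUMNS:
        return EXPOSURE_COLUMNS[column].labels
    if column == "outcome":
        return OUTCOME_LEVELS
    return COUNT_SCHEME.labels


# Default diagnosis feature → ICD-10-CM prefix lists. The published analysis
# does not enumerate its code sets, so these are configurable defaults chosen
# from the obvious ICD-10 chapters for each label.
DEFAULT_CODE_LISTS: dict[str, tuple[str, ...]] = {
    "anxiety": ("F41",),
    "asthma": ("J45",),
    "bronchiectasis": ("J47",),
    "chronic_nasal_congestion": ("R0981",),
    "chronic_obstructive_pulmonary_disease": ("J44",),
    "congenital_malformation_of_respiratory_system": ("Q30", "Q31", "Q32", "Q33", "Q34"),
    "cough": ("R05",),
    "croup": ("J050",),
    "cystic_fibrosis": ("E84",),
    "depression": ("F32", "F33"),
    "diabetes": ("E08", "E09", "E10", "E11", "E13"),
    "male_infertility": ("N46",),
    "middle_ear_disease": ("H65", "H66"),
    "neonatal_respiratory_distress": ("P22",),
    "obesity": ("E66",),
    "pneumonia": ("J12", "J13", "J14", "J15", "J16", "J17", "J18"),
    "reactive_airway_disease": ("J6802",),
    "situs_inversus_or_heterotaxy": ("Q893",),
}


def age_at(birth_date: dt.date, period: StudyPeriod) -> int:
    """Completed years at day one of the study period, ceiling 89 per Safe Harbor."""
    if birth_date > period.start:
        raise DomainError(f"birth date {birth_date} after period start {period.start}")
    ref = period.start
    years = ref.year - birth_date.year - (
        (ref.month, ref.day) < (birth_date.month, birth_date.day)
    )
    return min(years, 89)


def bin_age(age: float) -> str:
    if age < 0:
        raise DomainError(f"negative age {age}")
    if age > 89:
        raise DomainError(f"age {age} above the 89-year ceiling; cap before binning")
    return AGE_SCHEME.bin(age)


def bin_count(n: int) -> str:
    if n < 0:
        raise DomainError(f"negative count {n}")
    return COUNT_SCHEME.bin(n)


def bin_roadway_distance(d: float) -> str:
    return ROADWAY_SCHEME.bin(d)


def bin_site_distance(d: float) -> str:
    return SITE_SCHEME.bin(d)


def bin_density(population: Optional[int]) -> str:
    if population is None:
        return MISSING
    return DENSITY_SCHEME.bin(population)


def pseudonymize(patient_id: str, salt: str) -> str:
    """Stable salted hash key; joins across runs without exposing raw ids."""
    return hashlib.sha256(f"{salt}|{patient_id}".encode()).hexdigest()[:16]


def diagnosis_count(conditions, prefixes, period: StudyPeriod) -> int:
    """Distinct condition-record dates matching the feature's code prefixes in-period.

    Repeat same-day codes count once; the 0/1/>1 recode is applied downstream.
    """
    return len({
        c.date for c in conditions
        if period.contains(c.date) and code_matches(c.code, prefixes)
    })


def build_feature_table(
    ds: ClinicalDataset,
    registry: SourceRegistry,
    period: StudyPeriod,
    code_lists: Optional[dict] = None,
    outcome_spec=None,
    salt: str = "icees-lite",
) -> pd.DataFrame:
    """One de-identified row per patient: binned demographics, diagnosis counts, exposures.

    ``code_lists`` maps feature name → iterable of code prefixes (defaults to
    :data:`DEFAULT_CODE_LISTS`). When ``outcome_spec`` is given, the table also
    carries the ED/inpatient respiratory visit count and its better/poor
    dichotomy (see :mod:`icees_lite.cohorts`).
    """
    from . import cohorts  # deferred: cohorts imports nothing from here

    if code_lists is None:
        code_lists = DEFAULT_CODE_LISTS
    for feature, prefixes in code_lists.items():
        if not prefixes:
            raise ConfigError(f"feature {feature!r} has an empty code list")

    conditions_by_patient: dict[str, list] = {}
    for c in ds.conditions:
        conditions_by_patient.setdefault(c.patient_id, []).append(c)

    visit_counts = (
        cohorts.respiratory_visit_counts(ds, outcome_spec)
        if outcome_spec is not None else {}
    )

    rows = []
    for patient in sorted(ds.patients, key=lambda p: p.patient_id):
        row: dict[str, object] = {"patient_key": pseudonymize(patient.patient_id, salt)}
        row["age"] = bin_age(age_at(patient.birth_date, period))
        row["sex"] = patient.sex
        row["race"] = patient.race
        row["ethnicity"] = patient.ethnicity

        conds = conditions_by_patient.get(patient.patient_id, [])
        for feature, prefixes in code_lists.items():
            row[feature] = bin_count(diagnosis_count(conds, prefixes, period))

        profile = exposure_profile(patient, registry)
        if profile.dist_cafo_m is None and profile.dist_landfill_m is None \
                and profile.dist_road_m is None and profile.block_population is None:
            row["cafo_distance"] = MISSING
            row["landfill_distance"] = MISSING
            row["roadway_distance"] = MISSING
            row["residential_density"] = MISSING
        else:
            row["cafo_distance"] = (
                MISSING if profile.dist_cafo_m is None else bin_site_distance(profile.dist_cafo_m)
            )
            row["landfill_distance"] = (
                MISSING if profile.dist_landfill_m is None
                else bin_site_distance(profile.dist_landfill_m)
            )
            row["roadway_distance"] = (
                MISSING if profile.dist_road_m is None
                else bin_roadway_distance(profile.dist_road_m)
            )
            row["residential_density"] = bin_density(profile.block_population)

        if outcome_spec is not None:
            n_visits = visit_counts[patient.patient_id]
            row["respiratory_visits"] = n_visits
            row["outcome"] = cohorts.dichotomize(n_visits)
        rows.append(row)

    columns = ["patient_key", "age", "sex", "race", "ethnicity",
               *code_lists.keys(), *EXPOSURE_COLUMNS.keys()]
    if outcome_spec is not None:
        columns += ["respiratory_visits", "outcome"]
    return pd.DataFrame(rows, columns=columns)
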