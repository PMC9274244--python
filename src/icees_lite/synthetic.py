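"""Reproducible synthetic EHR + exposure-registry generator with known ground truth.

The generator emulates the study conditions of the desk-scale analysis:
a one-calendar-year period, ~4,840 patients with the observed demographic
mix, per-feature diagnosis-count distributions over {0, 1, >1}, partial
geocode coverage (~27.42%), and ED/inpatient respiratory visit counts whose
zero mass (~77.4%) and long tail (maximum in the mid-30s) follow a
zero-or-shifted-negative-binomial shape. Configured effects act as odds
ratios on the dichotomized ≥1-visit outcome through a logistic model, so an
effect of OR = 1 for every feature is an exact null for the downstream
contingency scan.

All randomness flows from one ``numpy.random.default_rng(seed)`` stream;
a fixed seed reproduces the dataset bit-for-bit.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .model import (
    ClinicalDataset,
    ConditionRecord,
    EncounterRecord,
    PatientRecord,
    RoadSegment,
    SourceRegistry,
    StudyPeriod,
)
from . import geospatial, ingest

AGE_STRATA_YEARS = {"<5": (0, 5), "5–17": (5, 18), "18–44": (18, 45),
                    "45–64": (45, 65), "65–89": (65, 90)}


class DiagnosisFeature(BaseModel):
    """One synthetic diagnosis feature: code prefix + P(count level ∈ {0, 1, >1})."""

    name: str
    code_prefix: str
    level_probs: tuple[float, float, float]

    @field_validator("level_probs")
    @classmethod
    def _sums_to_one(cls, v):
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError(f"level_probs must sum to 1, got {sum(v)}")
        if any(p < 0 for p in v):
            raise ValueError("level_probs must be non-negative")
        return v


class Effect(BaseModel):
    feature: str
    odds_ratio: float = Field(gt=0)


class VisitModel(BaseModel):
    """P(≥1 ED/inpatient respiratory visit) at zero features, plus the
    shifted-negative-binomial shape of positive counts."""

    baseline_p_any: float = Field(default=0.2256, gt=0, lt=1)
    nb_mean: float = Field(default=1.9, gt=0)     # mean of the (count − 1) part
    nb_size: float = Field(default=0.6, gt=0)     # NB dispersion; smaller = heavier tail


def _default_demographics() -> dict[str, dict[str, float]]:
    return {
        "age": {"<5": 0.0558, "5–17": 0.0818, "18–44": 0.1450,
                "45–64": 0.2285, "65–89": 0.4889},
        "sex": {"Male": 0.399, "Female": 0.601},
        "race": {"Caucasian": 0.7085, "African American": 0.1925,
                 "Asian": 0.0170, "Other": 0.0820},
        "ethnicity": {"Hispanic or Latino": 0.012, "Not Hispanic or Latino": 0.938,
                      "Missing": 0.050},
    }


def _default_diagnosis_features() -> list[DiagnosisFeature]:
    mk = lambda name, prefix, p: DiagnosisFeature(name=name, code_prefix=prefix, level_probs=p)
    return [
        mk("anxiety", "F41", (0.8539, 0.0184, 0.1277)),
        mk("asthma", "J45", (0.8508, 0.0227, 0.1265)),
        mk("bronchiectasis", "J47", (0.7917, 0.0310, 0.1773)),
        mk("chronic_nasal_congestion", "R0981", (0.9787, 0.0110, 0.0103)),
        mk("cough", "R05", (0.8298, 0.0533, 0.1169)),
        mk("cystic_fibrosis", "E84", (0.9663, 0.0017, 0.0320)),
        mk("depression", "F32", (0.8680, 0.0151, 0.1169)),
        mk("diabetes", "E11", (0.8490, 0.0120, 0.1390)),
        mk("middle_ear_disease", "H66", (0.9684, 0.0124, 0.0192)),
        mk("pneumonia", "J18", (0.9169, 0.0143, 0.0688)),
    ]


class SynthConfig(BaseModel):
    """Study conditions for one synthetic cohort."""

    n_patients: int = Field(default=4840, gt=0)
    study_year: int = 2020
    demographics: dict[str, dict[str, float]] = Field(default_factory=_default_demographics)
    diagnosis_features: list[DiagnosisFeature] = Field(
        default_factory=_default_diagnosis_features)
    visit_model: VisitModel = Field(default_factory=VisitModel)
    effects: list[Effect] = Field(default_factory=list)
    geocode_coverage: float = Field(default=0.2742, ge=0.0, le=1.0)
    n_cafo: int = Field(default=25, ge=0)
    n_landfill: int = Field(default=10, ge=0)
    n_road_segments: int = Field(default=40, ge=0)
    bbox: tuple[float, float, float, float] = (34.5, -80.0, 36.5, -78.0)  # lat0, lon0, lat1, lon1
    block_grid: int = Field(default=12, gt=0)
    outpatient_rate: float = Field(default=2.0, ge=0)  # mean background visits per patient
    seed: int = 0

    @field_validator("demographics")
    @classmethod
    def _probs_sum(cls, v):
        for feature, probs in v.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"demographics[{feature!r}] probabilities sum to {total}, not 1")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"demographics[{feature!r}] has a negative probability")
        return v

    @model_validator(mode="after")
    def _effects_reference_features(self):
        names = {f.name for f in self.diagnosis_features}
        for e in self.effects:
            if e.feature not in names:
                raise ValueError(f"effects: unknown feature {e.feature!r}")
        return self

    @property
    def period(self) -> StudyPeriod:
        return StudyPeriod.calendar_year(self.study_year)


@dataclass
class GroundTruth:
    """Latent quantities the generator knows exactly, for oracle-style tests."""

    outcome_group: dict[str, str]                    # patient_id → better / poor
    visit_counts: dict[str, int]
    effect_by_feature: dict[str, float]              # feature → true odds ratio (1.0 if none)
    true_distances: dict[str, Optional[tuple[float, float, float]]]  # (cafo, landfill, road)
    feature_positive: dict[str, dict[str, bool]]     # feature → patient_id → count ≥ 1


def draw_feature_levels(config: SynthConfig, rng: np.random.Generator, n: Optional[int] = None
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized latent draw shared by the full generator and calibration studies.

    Returns (levels, poor, visits): ``levels`` is an (n, F) array over
    {0, 1, 2} (2 ⇒ the >1 stratum), ``poor`` the Bernoulli outcome of the
    logistic model, ``visits`` the respiratory visit counts (0 for better,
    1 + NB(nb_mean, nb_size) for poor).
    """
    if n is None:
        n = config.n_patients
    feats = config.diagnosis_features
    probs = np.array([f.level_probs for f in feats])           # F × 3
    u = rng.random((n, len(feats)))
    cum = probs.cumsum(axis=1)
    levels = (u[:, :, None] > cum[None, :, :-1]).sum(axis=2)   # n × F in {0,1,2}

    or_by_name = {e.feature: e.odds_ratio for e in config.effects}
    log_or = np.array([math.log(or_by_name.get(f.name, 1.0)) for f in feats])
    base = config.visit_model.baseline_p_any
    logit = math.log(base / (1.0 - base)) + (levels >= 1) @ log_or
    p_poor = 1.0 / (1.0 + np.exp(-logit))
    poor = rng.random(n) < p_poor

    mu, size = config.visit_model.nb_mean, config.visit_model.nb_size
    extra = rng.negative_binomial(size, size / (size + mu), n)
    visits = np.where(poor, 1 + extra, 0)
    return levels, poor, visits


def _draw_categorical(rng, categories: dict[str, float], n: int) -> np.ndarray:
    labels = list(categories.keys())
    p = np.array(list(categories.values()), dtype=float)
    return rng.choice(np.array(labels, dtype=object), size=n, p=p / p.sum())


def _block_group_id(i: int, j: int) -> str:
    return f"BG-{i:02d}-{j:02d}"


def _make_registry(config: SynthConfig, rng) -> SourceRegistry:
    lat0, lon0, lat1, lon1 = config.bbox
    def points(k):
        lats = rng.uniform(lat0, lat1, k)
        lons = rng.uniform(lon0, lon1, k)
        return [(float(a), float(b)) for a, b in zip(lats, lons)]

    registry = SourceRegistry()
    registry.cafo_points = points(config.n_cafo)
    registry.landfill_points = points(config.n_landfill)
    for _ in range(config.n_road_segments):
        (a,) = points(1)
        # segments a few km long in a random direction
        bearing = rng.uniform(0, 2 * math.pi)
        length_deg = rng.uniform(0.01, 0.05)
        b = (a[0] + length_deg * math.cos(bearing), a[1] + length_deg * math.sin(bearing))
        registry.road_segments.append(RoadSegment((a, b)))

    g = config.block_grid
    # rural-heavy population mix: no urbanized block groups at default settings
    for i in range(g):
        for j in range(g):
            if rng.random() < 0.68:
                pop = int(rng.integers(100, 2500))
            else:
                pop = int(rng.integers(2500, 50000))
            registry.block_groups[_block_group_id(i, j)] = pop
    return registry


def _assign_block(config: SynthConfig, lat: float, lon: float) -> str:
    lat0, lon0, lat1, lon1 = config.bbox
    g = config.block_grid
    i = min(int((lat - lat0) / (lat1 - lat0) * g), g - 1)
    j = min(int((lon - lon0) / (lon1 - lon0) * g), g - 1)
    return _block_group_id(i, j)


def _true_distances(geopoint, registry: SourceRegistry):
    dists = []
    for kind in ("cafo", "landfill", "road"):
        d = geospatial.nearest_source_distance(geopoint, registry, kind)
        dists.append(d if d is not None else float("nan"))
    return tuple(dists)


def generate_population(config: SynthConfig
                        ) -> tuple[ClinicalDataset, SourceRegistry, GroundTruth]:
    """Generate one synthetic cohort, its exposure registry, and the ground truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    period = config.period
    year_days = (period.end - period.start).days + 1

    registry = _make_registry(config, rng)

    ids = [f"P{i:06d}" for i in range(n)]
    age_bins = _draw_categorical(rng, config.demographics["age"], n)
    sexes = _draw_categorical(rng, config.demographics["sex"], n)
    races = _draw_categorical(rng, config.demographics["race"], n)
    ethnicities = _draw_categorical(rng, config.demographics["ethnicity"], n)
    geocoded = rng.random(n) < config.geocode_coverage
    lat0, lon0, lat1, lon1 = config.bbox
    lats = rng.uniform(lat0, lat1, n)
    lons = rng.uniform(lon0, lon1, n)

    ds = ClinicalDataset(provenance=f"synthetic:seed={config.seed}")
    truth = GroundTruth({}, {}, {e.feature: e.odds_ratio for e in config.effects}, {}, {})
    for f in config.diagnosis_features:
        truth.effect_by_feature.setdefault(f.name, 1.0)
        truth.feature_positive[f.name] = {}

    for i, pid in enumerate(ids):
        lo, hi = AGE_STRATA_YEARS[age_bins[i]]
        age_days = int(rng.integers(int(lo * 365.25), int(hi * 365.25)))
        birth = period.start - dt.timedelta(days=max(age_days, 0))
        geopoint = (float(lats[i]), float(lons[i])) if geocoded[i] else None
        ds.patients.append(PatientRecord(
            patient_id=pid, birth_date=birth, sex=str(sexes[i]), race=str(races[i]),
            ethnicity=str(ethnicities[i]),
            geopoint=geopoint,
            block_group_id=_assign_block(config, *geopoint) if geopoint else None,
            geocode_timestamp=period.start if geopoint else None,
        ))
        truth.true_distances[pid] = _true_distances(geopoint, registry) if geopoint else None

    levels, poor, visits = draw_feature_levels(config, rng)

    for j, feat in enumerate(config.diagnosis_features):
        for i, pid in enumerate(ids):
            level = levels[i, j]
            truth.feature_positive[feat.name][pid] = bool(level >= 1)
            if level == 0:
                continue
            count = 1 if level == 1 else 2 + int(rng.poisson(1.0))
            days = rng.choice(year_days, size=min(count, year_days), replace=False)
            for day in sorted(int(d) for d in days):
                ds.conditions.append(ConditionRecord(
                    pid, f"{feat.code_prefix}.0", period.start + dt.timedelta(days=day)))

    tags = np.array([None, "adult_pulmonary_clinic", "pediatric_clinic"], dtype=object)
    tag_p = np.array([0.60, 0.25, 0.15])
    for i, pid in enumerate(ids):
        truth.outcome_group[pid] = "poor" if poor[i] else "better"
        truth.visit_counts[pid] = int(visits[i])
        for _ in range(int(visits[i])):
            klass = "ED" if rng.random() < 0.7 else "inpatient"
            day = int(rng.integers(year_days))
            ds.encounters.append(EncounterRecord(
                pid, klass, period.start + dt.timedelta(days=day),
                reason_codes=["J06.9"]))
        for _ in range(int(rng.poisson(config.outpatient_rate))):
            day = int(rng.integers(year_days))
            tag = rng.choice(tags, p=tag_p)
            ds.encounters.append(EncounterRecord(
                pid, "outpatient", period.start + dt.timedelta(days=day),
                location_tag=None if tag is None else str(tag)))

    return ds, registry, truth


def write_fixture(dataset: ClinicalDataset, registry: SourceRegistry, directory) -> None:
    """Emit the flat CSVs, the source registry CSVs, and a FHIR-subset bundle."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ingest.write_flat_tables(dataset, directory)
    geospatial.write_sources(registry, directory)
    ingest.write_fhir_bundle(dataset, directory / "bundle.json")
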