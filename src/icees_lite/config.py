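"""Run configuration: one YAML file drives every CLI stage."""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, ValidationError

from .model import ConfigError, StudyPeriod
from .synthetic import SynthConfig


class OutcomeConfig(BaseModel):
    encounter_classes: list[str] = ["ED", "inpatient"]
    reason_code_prefixes: list[str] = ["J"]


class RunConfig(BaseModel):
    input_dir: Path = Path("data")
    sources_dir: Optional[Path] = None          # defaults to input_dir
    output_dir: Path = Path("out")
    study_year: int = 2020
    code_lists_file: Optional[Path] = None      # YAML: feature → [code prefixes]
    criteria_file: Optional[Path] = None        # YAML cohort criteria
    outcome: OutcomeConfig = Field(default_factory=OutcomeConfig)
    alpha: float = Field(default=0.05, gt=0, lt=1)
    suppression_threshold: int = Field(default=10, ge=2)
    salt: str = "icees-lite"
    seed: int = 0
    synth: SynthConfig = Field(default_factory=SynthConfig)

    @property
    def period(self) -> StudyPeriod:
        return StudyPeriod.calendar_year(self.study_year)

    def resolved_sources_dir(self) -> Path:
        return self.sources_dir if self.sources_dir is not None else self.input_dir


def load_config(path) -> RunConfig:
    """Load and validate a YAML run config; referenced files must exist."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        cfg = RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc
    for field_name in ("code_lists_file", "criteria_file"):
        ref = getattr(cfg, field_name)
        if ref is not None and not Path(ref).exists():
            raise FileNotFoundError(f"{field_name} references missing file: {ref}")
    return cfg


def load_code_lists(cfg: RunConfig) -> dict[str, tuple[str, ...]]:
    from .feature_table import DEFAULT_CODE_LISTS

    if cfg.code_lists_file is None:
        return dict(DEFAULT_CODE_LISTS)
    with open(cfg.code_lists_file) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {}
    for feature, prefixes in raw.items():
        if not prefixes:
            raise ConfigError(f"code list for {feature!r} is empty")
        out[feature] = tuple(str(p) for p in prefixes)
    return out


def load_criteria(cfg: RunConfig):
    from .cohorts import Criterion, CriteriaConfig, DEFAULT_CRITERIA

    if cfg.criteria_file is None:
        return DEFAULT_CRITERIA
    with open(cfg.criteria_file) as fh:
        raw = yaml.safe_load(fh) or {}

    def parse(items):
        return tuple(
            Criterion(
                kind=item["kind"],
                match=frozenset(item.get("match", [])),
                age_at_event_max=item.get("age_at_event_max"),
                gestational_age_min_weeks=item.get("gestational_age_min_weeks"),
                min_occurrences=item.get("min_occurrences", 1),
            )
            for item in items
        )

    return CriteriaConfig(
        location_criteria=parse(raw.get("location_criteria", [])),
        clinical_criteria=parse(raw.get("clinical_criteria", [])),
        combiner=raw.get("combiner", "AND"),
    )


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(cfg.model_dump_json().encode()).hexdigest()[:12]
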