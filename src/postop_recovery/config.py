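"""Pipeline configuration: one document holding every stage's knobs.

All clinically meaningful constants live here with their standard
defaults: complication drop magnitudes 0.02 / 0.04 / 0.06, discharge
readiness threshold 1.8, activity-count split at 2000, activity-level
split at 3, exercise-bout qualification at 70% of (220 - age), abnormal
HRR-1 below 12 bpm, LOS group threshold 8 days, 10,000 split candidates
and elimination alpha 0.05.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .cohort import GeneratorConfig
from .features import FeatureConfig
from .model import ModelConfig
from .reference import DropSpec


class ConfigValidationError(ValueError):
    """Carries every problem found in a config document at once."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" +
                         "\n".join(f"  - {e}" for e in self.errors))


@dataclass
class SplitConfig:
    fraction: float = 2 / 3
    n_candidates: int = 10_000
    yates_correction: bool = False
    seed: int = 0


@dataclass
class ClinicalConfig:
    los_threshold: int = 8
    readiness_threshold: float = 1.8
    decline_k: int = 3
    hrr_abnormal_bpm: float = 12.0


@dataclass
class PipelineConfig:
    seed: int = 0
    horizon: int = 21               # reference-profile horizon, days
    eliminate: bool = True          # run backward feature elimination
    output_dir: str | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    drops: DropSpec = field(default_factory=DropSpec)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    split: SplitConfig = field(default_factory=SplitConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    clinical: ClinicalConfig = field(default_factory=ClinicalConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTIONS = {
    "generator": GeneratorConfig,
    "drops": DropSpec,
    "features": FeatureConfig,
    "split": SplitConfig,
    "model": ModelConfig,
    "clinical": ClinicalConfig,
}
_SCALARS = ("seed", "horizon", "eliminate", "output_dir")


def _build_section(name, cls, payload, errors):
    if not isinstance(payload, dict):
        errors.append(f"{name}: expected a mapping, got {type(payload).__name__}")
        return cls()
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - known
    for key in sorted(unknown):
        errors.append(f"{name}.{key}: unknown key")
    kwargs = {k: v for k, v in payload.items() if k in known}
    if cls is DropSpec:
        for mapname in ("magnitude_by_grade", "lead_days_by_grade"):
            if mapname in kwargs:
                kwargs[mapname] = {int(g): v for g, v in kwargs[mapname].items()}
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        errors.append(f"{name}: {exc}")
        return cls()


def validate_config(document: dict | None) -> PipelineConfig:
    """Normalize a (possibly partial) config mapping into a PipelineConfig.

    Defaults fill every omitted key; unknown keys are rejected; all
    violations are reported together in one ConfigValidationError.
    """
    document = dict(document or {})
    errors = []
    unknown = set(document) - set(_SECTIONS) - set(_SCALARS)
    for key in sorted(unknown):
        errors.append(f"{key}: unknown top-level key")

    sections = {}
    for name, cls in _SECTIONS.items():
        sections[name] = _build_section(name, cls, document.get(name, {}), errors)

    cfg = PipelineConfig(
        seed=document.get("seed", 0),
        horizon=document.get("horizon", 21),
        eliminate=bool(document.get("eliminate", True)),
        output_dir=document.get("output_dir"),
        **sections,
    )
    if not isinstance(cfg.seed, int):
        errors.append(f"seed: expected an integer, got {cfg.seed!r}")
    if not isinstance(cfg.horizon, int) or cfg.horizon < 1:
        errors.append(f"horizon: must be a positive integer, got {cfg.horizon!r}")
    for check in (cfg.generator.validate, cfg.model.validate):
        try:
            check()
        except ValueError as exc:
            errors.append(str(exc))
    if not 0 < cfg.split.fraction <= 1:
        errors.append(f"split.fraction: must be in (0, 1], got {cfg.split.fraction}")
    if cfg.split.n_candidates < 1:
        errors.append("split.n_candidates: must be >= 1")
    if cfg.clinical.readiness_threshold <= 0:
        errors.append("clinical.readiness_threshold: must be positive")
    if cfg.clinical.decline_k < 2:
        errors.append("clinical.decline_k: must be >= 2")
    if errors:
        raise ConfigValidationError(errors)
    return cfg


def load_config(path) -> PipelineConfig:
    import yaml

    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})
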