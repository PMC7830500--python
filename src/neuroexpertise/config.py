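"""Study configuration: nested sections, YAML round-trip, seed derivation.

A single master seed drives every stage; per-stage seeds are derived by
hashing the stage name against the master seed, so any stage can be re-run
in isolation and reproduce its part of a full run.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .fnirs_prep import FIXED_GRID_LEN, QCThresholds
from .models import CLASSIFIER_NAMES
from .synthdata import CohortConfig

__all__ = ["StudyConfig", "FeaturesConfig", "ModelsConfig",
           "EvaluationConfig", "load_config", "derive_seed"]


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class FeaturesConfig:
    n_kernels: int = 100
    fnirs_grid_len: int = FIXED_GRID_LEN
    emotion_grid_len: int = 18
    flatten_emotion_scores: bool = False


@dataclass
class ModelsConfig:
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES
    params: dict = field(default_factory=dict)
    deep_epochs: int = 1000

    def __post_init__(self) -> None:
        bad = set(self.classifiers) - set(CLASSIFIER_NAMES)
        if bad:
            raise ValueError(f"unknown classifiers {sorted(bad)}")


@dataclass
class EvaluationConfig:
    n_repeats: int = 10
    n_splits: int = 5
    alpha: float = 0.05
    group_by_participant: bool = False


@dataclass
class PreprocessingConfig:
    cutoff_hz: float = 0.14
    outlier_k: float = 3.0
    saturation_level: float = QCThresholds().saturation_level
    low_signal_floor: float = QCThresholds().low_signal_floor
    leakage_cv_max: float = QCThresholds().leakage_cv_max

    def thresholds(self) -> QCThresholds:
        return QCThresholds(
            saturation_level=self.saturation_level,
            low_signal_floor=self.low_signal_floor,
            leakage_cv_max=self.leakage_cv_max,
        )


@dataclass
class StudyConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    features: FeaturesConfig = field(default_factory=FeaturesConfig)
    models: ModelsConfig = field(default_factory=ModelsConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    out_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        # cohort seed follows the master seed unless explicitly overridden
        if self.cohort.seed == 0 and self.seed != 0:
            self.cohort.seed = derive_seed(self.seed, "cohort")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["models"]["classifiers"] = list(d["models"]["classifiers"])
        d["cohort"]["class_counts"] = list(d["cohort"]["class_counts"])
        Path(path).write_text(yaml.safe_dump(d))


_SECTION_TYPES = {
    "cohort": CohortConfig,
    "preprocessing": PreprocessingConfig,
    "features": FeaturesConfig,
    "models": ModelsConfig,
    "evaluation": EvaluationConfig,
}


def _build_section(cls, data: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in section {section!r}; "
            f"valid keys: {sorted(valid)}"
        )
    if "class_counts" in data:
        data["class_counts"] = tuple(data["class_counts"])
    if "classifiers" in data:
        data["classifiers"] = tuple(data["classifiers"])
    if "block_sizes" in data:
        data["block_sizes"] = tuple(data["block_sizes"])
    return cls(**data)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> StudyConfig:
    """Load a YAML study config; omitted fields fall back to the defaults.

    Unknown keys are rejected by name.  ``overrides`` is merged on top
    (one level deep per section).
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"config root must be a mapping, got {type(loaded)}")
            data = loaded
    if overrides:
        for k, v in overrides.items():
            if isinstance(v, dict):
                data.setdefault(k, {})
                data[k].update(v)
            else:
                data[k] = v

    top_valid = {f.name for f in dataclasses.fields(StudyConfig)}
    unknown = set(data) - top_valid
    if unknown:
        raise ValueError(
            f"unknown top-level key(s) {sorted(unknown)}; "
            f"valid keys: {sorted(top_valid)}"
        )
    kwargs: dict = {}
    for name, cls in _SECTION_TYPES.items():
        if name in data:
            kwargs[name] = _build_section(cls, dict(data[name]), name)
    for scalar in ("out_dir", "seed"):
        if scalar in data:
            kwargs[scalar] = data[scalar]
    return StudyConfig(**kwargs)
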