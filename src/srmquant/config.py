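"""Pipeline configuration: a flat, YAML-round-trippable parameter block.

Defaults encode the study conditions the pipeline targets: the 19-level
calibration series, QC levels 100/1000/10000 ng mL^-1, at least five
calibration points with an 80–120% accuracy band, a strict >70% detection
filter, 25+25 balanced subsampling over one million draws, and BH
significance at alpha 0.05. Unknown keys are rejected rather than ignored so
misspelled options fail loudly.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .associate import DEFAULT_MODEL_TERMS
from .simulate import DEFAULT_LEVELS, DEFAULT_QC_LEVELS

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    seed: int = 0
    panel_path: str = "diabetes-t1d-34"
    istd_path: str | None = None
    level_list: tuple[float, ...] = DEFAULT_LEVELS
    qc_levels: tuple[float, ...] = DEFAULT_QC_LEVELS
    min_points: int = 5
    accuracy_band: tuple[float, float] = (0.80, 1.20)
    detection_threshold: float = 0.70
    k_per_group: int = 25
    n_draws: int = 1_000_000
    alpha: float = 0.05
    model_terms: tuple[str, ...] = DEFAULT_MODEL_TERMS
    log10_response: bool = True
    # synthetic-cohort parameters (used by the simulate / run-all stages)
    n_per_group: int = 25
    n_replicates: int = 3
    group_effect_log10: float = 0.0
    residual_sd_log10: float = 0.2
    replicate_cv: float = 0.05
    missingness_rate: float = 0.0

    def __post_init__(self) -> None:
        band = tuple(self.accuracy_band)
        if not (0 < band[0] < 1 < band[1]):
            raise ValueError("accuracy_band must straddle 1, e.g. (0.8, 1.2)")
        if not 0 <= self.detection_threshold <= 1:
            raise ValueError("detection_threshold must be in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_points < 2:
            raise ValueError("min_points must be >= 2")
        self.level_list = tuple(float(x) for x in self.level_list)
        self.qc_levels = tuple(float(x) for x in self.qc_levels)
        self.accuracy_band = (float(band[0]), float(band[1]))
        self.model_terms = tuple(self.model_terms)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("level_list", "qc_levels", "accuracy_band", "model_terms"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data or {})

    def config_hash(self) -> str:
        """Stable short hash of the canonical serialized configuration."""
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
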