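"""Pipeline configuration: one serialisable object holding every tunable."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from accelethogram.errors import InvalidArgumentError


@dataclass
class PipelineConfig:
    """All pipeline tunables with their protocol defaults.

    Durations in seconds unless suffixed otherwise; see the methods note for
    the provenance of each default.
    """

    sample_rate: float = 50.0
    static_window_s: float = 3.0
    period_min_s: float = 0.2
    period_max_s: float = 2.0
    n_periods: int = 50
    feature_window_s: float = 1.0
    predictor_set: str = "full66"
    train_fraction: float = 0.7
    ntree: int = 1000
    mtry: int | None = None  # None -> floor(sqrt(p))
    stratify: bool = False
    smoothing: bool = True
    settling_exclusion_min: float = 60.0
    clustering_gap_min: float = 30.0
    diel_half_width_h: float = 1.0
    generator_seed: int = 11
    split_seed: int = 5
    forest_seed: int = 7

    def __post_init__(self) -> None:
        for name in (
            "sample_rate",
            "static_window_s",
            "period_min_s",
            "period_max_s",
            "n_periods",
            "feature_window_s",
            "ntree",
            "diel_half_width_h",
        ):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be > 0")
        if not (0 < self.train_fraction < 1):
            raise InvalidArgumentError("train_fraction must be in (0, 1)")
        if self.period_min_s >= self.period_max_s:
            raise InvalidArgumentError("period_min_s must be < period_max_s")
        if self.settling_exclusion_min < 0 or self.clustering_gap_min < 0:
            raise InvalidArgumentError("exclusion and gap must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        """Stable short hash of the full configuration (for run logs)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
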