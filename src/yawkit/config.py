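"""Pipeline configuration: defaults match the field protocol without edits.

Smoothing 2 s, 40 Hz subsampled to 1 Hz, AVeY scales 1/5/10 s, turn
thresholds 20/45/90/180°, CuHe bin 1°, dive minimum depth 3 m.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class PipelineConfig:
    """Validated configuration for :func:`yawkit.pipeline.run_pipeline`.

    ``inputs`` is a list of dicts with keys ``raw`` (path), optional ``cal``
    (calibration segment path; omitted means identity calibration) and
    ``animal_id``.
    """

    inputs: list = field(default_factory=list)
    schema: dict | None = None
    rate_hz: float = 40.0
    window_s: float = 2.0
    subsample_n: int = 40
    avey_scales: tuple = (1, 5, 10)
    turn_thresholds: tuple = (20.0, 45.0, 90.0, 180.0)
    turn_reset: str = "remainder"
    cuhe_bin_deg: float = 1.0
    surface_threshold_m: float = 0.5
    min_depth_m: float = 3.0
    bottom_fraction: float = 0.8
    flatness_max: float = 0.1
    min_bottom_s: float = 30.0
    seed: int = 0
    out_dir: str = "yawkit_out"

    def __post_init__(self) -> None:
        self.avey_scales = tuple(int(s) for s in self.avey_scales)
        self.turn_thresholds = tuple(float(v) for v in self.turn_thresholds)
        if self.window_s <= 0:
            raise ConfigError("window_s must be positive")
        if self.subsample_n < 1:
            raise ConfigError("subsample_n must be >= 1")
        if any(v <= 0 for v in self.turn_thresholds):
            raise ConfigError("turn thresholds must be positive")
        if not self.surface_threshold_m < self.min_depth_m:
            raise ConfigError("surface_threshold_m must be below min_depth_m")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["avey_scales"] = list(self.avey_scales)
        d["turn_thresholds"] = list(self.turn_thresholds)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
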