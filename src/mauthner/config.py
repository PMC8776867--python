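"""Experiment configuration: dataclass, YAML round-trip and provenance hash.

dB and Michelson-index labels are metadata carried through to the outputs; the
simulator itself operates in nA, and the only dB/MI-to-current mapping is the
calibration of intensities against behavioral response probabilities.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .calibration import (
    AUDITORY_BOUNDS_NA,
    DEFAULT_AUDITORY_TARGETS,
    DEFAULT_VISUAL_TARGETS,
    VISUAL_BOUNDS_NA,
)
from .geometry import MICHELSON_LABELS
from .lif import MauthnerParams, TrialConfig

__all__ = ["ExperimentConfig", "DB_LABELS", "DEFAULT_DELAYS"]

#: Auditory amplitude labels, dB re 1 uPa.
DB_LABELS = (133.5, 139.0, 145.5, 152.3, 156.7, 166.1)

#: Auditory-onset delays relative to the end of visual expansion, ms
#: (negative: sound precedes the end of expansion).
DEFAULT_DELAYS = (-40.0, -60.0, -160.0, -260.0, -360.0, -460.0)


@dataclass
class ExperimentConfig:
    """Full configuration of the calibrate -> simulate -> analyze pipeline."""

    params: MauthnerParams = field(default_factory=MauthnerParams)
    trial: TrialConfig = field(default_factory=TrialConfig)
    mi_labels: Sequence[float] = MICHELSON_LABELS
    db_labels: Sequence[float] = DB_LABELS
    visual_targets: Sequence[float] = DEFAULT_VISUAL_TARGETS
    auditory_targets: Sequence[float] = DEFAULT_AUDITORY_TARGETS
    visual_bounds: tuple[float, float] = VISUAL_BOUNDS_NA
    auditory_bounds: tuple[float, float] = AUDITORY_BOUNDS_NA
    calibration_tolerance: float = 0.02
    calibration_n_eval: int = 2000
    n_trials: int = 200          # trials per grid/unisensory condition
    n_delay_trials: int = 100    # trials per delay condition
    delays: Sequence[float] = DEFAULT_DELAYS
    msi_width: float = 40.0
    lp_uv_quantiles: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.mi_labels)) != len(self.mi_labels):
            raise ValueError("MI labels must be unique")
        if len(set(self.db_labels)) != len(self.db_labels):
            raise ValueError("dB labels must be unique")
        if any(d >= 0 for d in self.delays):
            raise ValueError("delays must be negative (sound precedes visual end)")
        if len(self.visual_targets) != len(self.mi_labels):
            raise ValueError("one visual target per MI label required")
        if len(self.auditory_targets) != len(self.db_labels):
            raise ValueError("one auditory target per dB label required")

    @property
    def n_levels(self) -> int:
        return len(self.mi_labels)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("mi_labels", "db_labels", "visual_targets", "auditory_targets",
                    "visual_bounds", "auditory_bounds", "delays", "lp_uv_quantiles"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        data = dict(data)
        if "params" in data and isinstance(data["params"], dict):
            data["params"] = MauthnerParams(**data["params"])
        if "trial" in data and isinstance(data["trial"], dict):
            data["trial"] = TrialConfig(**data["trial"])
        for key in ("visual_bounds", "auditory_bounds", "lp_uv_quantiles"):
            if key in data:
                data[key] = tuple(data[key])
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        """Short provenance hash stamped onto every output row."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha1(blob.encode()).hexdigest()[:10]
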