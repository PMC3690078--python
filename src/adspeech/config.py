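"""Run configuration: every tunable of the pipeline in one serializable object.

The config round-trips through a single YAML file; unknown keys are
rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class AudioParams:
    sample_rate: int = 16_000
    segment_length_s: float = 60.0
    denoise: bool = True
    noise_profile_s: float = 0.25
    over_subtraction: float = 1.0


@dataclass
class VADParams:
    frame_length_s: float = 0.025
    hop_s: float = 0.010
    energy_floor_db: float = -40.0
    zcr_split: float = 0.25
    autocorr_threshold: float = 0.45
    min_interval_s: float = 0.05
    smooth_frames: int = 5


@dataclass
class SSFParams:
    n_bins: int = 10
    relevance_quantile: float = 0.2
    evolution_window_s: float = 10.0
    median_filter: int = 5


@dataclass
class FDParams:
    window_s: float = 1.0
    hop_s: float = 0.5
    kmax: int = 8


@dataclass
class PitchParams:
    fmin: float = 75.0
    fmax: float = 500.0
    frame_length_s: float = 0.040
    hop_s: float = 0.010
    voicing_threshold: float = 0.45


@dataclass
class ETParams:
    frame_length_s: float = 0.5
    hop_s: float = 0.25
    bands_hz: list = field(default_factory=lambda: [[0, 400], [400, 2000], [2000, 5000], [5000, 8000]])
    C: float = 1.0
    gamma: float | None = None


@dataclass
class MLPParams:
    k: int = 10
    hidden: int = 100
    epochs: int = 1000


@dataclass
class RunConfig:
    audio: AudioParams = field(default_factory=AudioParams)
    vad: VADParams = field(default_factory=VADParams)
    ssf: SSFParams = field(default_factory=SSFParams)
    fd: FDParams = field(default_factory=FDParams)
    pitch: PitchParams = field(default_factory=PitchParams)
    et: ETParams = field(default_factory=ETParams)
    mlp: MLPParams = field(default_factory=MLPParams)
    seed: int = 0
    class_mode: str = "binary"  # binary | four-class

    def __post_init__(self):
        if self.class_mode not in ("binary", "four-class"):
            raise ConfigError(f"class_mode must be 'binary' or 'four-class', got {self.class_mode!r}")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        if not isinstance(d, dict):
            raise ConfigError("config root must be a mapping")
        sections = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for key, value in d.items():
            if key not in sections:
                raise ConfigError(f"unknown config key: {key!r}")
            f = sections[key]
            if dataclasses.is_dataclass(f.default_factory() if f.default_factory is not dataclasses.MISSING else None):
                sub_cls = type(f.default_factory())
                sub_fields = {sf.name for sf in dataclasses.fields(sub_cls)}
                if not isinstance(value, dict):
                    raise ConfigError(f"config section {key!r} must be a mapping")
                unknown = set(value) - sub_fields
                if unknown:
                    raise ConfigError(f"unknown keys in section {key!r}: {sorted(unknown)}")
                kwargs[key] = sub_cls(**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            d = yaml.safe_load(Path(path).read_text())
        except FileNotFoundError:
            raise ConfigError(f"config file not found: {path}")
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}")
        return cls.from_dict(d or {})

    def config_hash(self) -> str:
        """Stable short hash of the resolved configuration, for run logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
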