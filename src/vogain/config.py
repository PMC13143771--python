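"""Analysis configuration: every pipeline threshold in one place.

All values default to the package's documented conventions and can be
overridden from a YAML file with top-level keys ``preprocess``,
``kinematics``, ``saccades`` and ``gain``.  The resolved values travel with
every result for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .errors import ParameterError


@dataclass
class PreprocessConfig:
    spike_threshold_dps: float = 800.0
    pad_ms: float = 50.0
    min_cycles: int = 5
    trim_edge_cycles: int = 1
    move_threshold_dps: float = 10.0


@dataclass
class KinematicsConfig:
    hysteresis_dps: float = 5.0
    r2_threshold: float = 0.90
    distortion_threshold: float = 0.10


@dataclass
class SaccadeConfig:
    threshold_dps: float = 60.0
    min_duration_ms: float = 10.0
    refractory_ms: float = 20.0


@dataclass
class GainConfig:
    head_peak_floor_dps: float = 10.0
    smoothing_ms: float = 25.0


@dataclass
class AnalysisConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    kinematics: KinematicsConfig = field(default_factory=KinematicsConfig)
    saccades: SaccadeConfig = field(default_factory=SaccadeConfig)
    gain: GainConfig = field(default_factory=GainConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        sections = {"preprocess": PreprocessConfig, "kinematics": KinematicsConfig,
                    "saccades": SaccadeConfig, "gain": GainConfig}
        kwargs = {}
        for name, klass in sections.items():
            body = data.get(name, {})
            unknown = set(body) - {f for f in klass.__dataclass_fields__}
            if unknown:
                raise ParameterError(f"unknown {name} config keys: {sorted(unknown)}")
            kwargs[name] = klass(**body)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
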