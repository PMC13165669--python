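"""Composed run configuration with YAML round-tripping.

``RunConfig`` nests the per-stage configurations (simulation, preprocessing,
model, training, evaluation) one-to-one with the stage modules.  Every field
has a default; unknown YAML keys are rejected so typos fail loudly; a config
serializes to YAML and back unchanged.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .model import ModelConfig
from .preprocess import AkfConfig
from .synthdata import RadarSimConfig
from .training import TrainConfig

__all__ = ["SimSection", "PreprocessSection", "EvalSection", "RunConfig",
           "load_config", "save_config", "ConfigError"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimSection:
    n_subjects: int = 8
    n_segments: int = 200
    radar: RadarSimConfig = field(default_factory=RadarSimConfig)


@dataclass(frozen=True)
class PreprocessSection:
    wavelet: str = "db4"
    J: int = 6
    cardiac_band: tuple[float, float] = (0.8, 10.0)
    ecg_poly_order: int = 5
    ecg_wavelet_J: int = 4
    akf: AkfConfig = field(default_factory=AkfConfig)


@dataclass(frozen=True)
class EvalSection:
    match_window: float = 0.15
    fs: float = 100.0


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    log_level: str = "INFO"
    out_dir: str = "runs"
    ablation: str = "full"
    sim: SimSection = field(default_factory=SimSection)
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    eval: EvalSection = field(default_factory=EvalSection)


def _nested_class(f: dataclasses.Field):
    """The dataclass type of a nested section field, else None."""
    if f.default_factory is not dataclasses.MISSING:  # type: ignore[misc]
        proto = f.default_factory()
        if dataclasses.is_dataclass(proto):
            return type(proto)
    return None


def _build(cls, data: dict[str, Any], path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping")
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        sub = _nested_class(names[key])
        if sub is not None:
            kwargs[key] = _build(sub, value, f"{path}.{key}")
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; missing keys take defaults."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return _build(RunConfig, data, "config")


def _plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_plain(v) for v in obj]
    return obj


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(_plain(cfg), sort_keys=False))
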