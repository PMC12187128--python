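"""Run configuration: nested dataclasses with strict YAML loading.

Unknown keys are rejected (with the offending key named) rather than
silently ignored, so typos in config files fail fast.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .instance import InstanceSegParams
from .softncuts import AffinityConfig
from .synth import ArtifactSpec, SynthConfig
from .wnet import TrainConfig, WNetArchitectureConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "from_dict", "to_dict"]


class ConfigError(ValueError):
    """Invalid or unknown configuration key/value."""


@dataclass
class RunConfig:
    """Everything needed for a reproducible end-to-end run on synthetic data."""

    seed: int = 0
    output_dir: str = "."
    verbosity: int = 1
    architecture: WNetArchitectureConfig = field(default_factory=WNetArchitectureConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    instance: InstanceSegParams = field(default_factory=InstanceSegParams)
    synth: SynthConfig = field(default_factory=SynthConfig)


_NESTED = {
    "architecture": WNetArchitectureConfig,
    "training": TrainConfig,
    "instance": InstanceSegParams,
    "synth": SynthConfig,
    "affinity": AffinityConfig,
    "artifact": ArtifactSpec,
}

_TUPLE_FIELDS = {"features", "shape", "radius_range", "cell_intensity_range", "center"}


def from_dict(cls, data: dict, path: str = ""):
    """Build a (possibly nested) config dataclass, rejecting unknown keys."""
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config section '{path or cls.__name__}' must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        where = f"{path}.{key}" if path else key
        if key not in names:
            raise ConfigError(f"unknown config key: '{where}'")
        if key in _NESTED and value is not None:
            value = from_dict(_NESTED[key], value, where)
        elif key in _TUPLE_FIELDS and value is not None:
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid config for '{path or cls.__name__}': {exc}") from exc


def to_dict(cfg) -> dict:
    if dataclasses.is_dataclass(cfg):
        return {f.name: to_dict(getattr(cfg, f.name)) for f in dataclasses.fields(cfg)}
    if isinstance(cfg, tuple):
        return list(cfg)
    return cfg


def load_config(path) -> RunConfig:
    """Load a YAML run configuration with strict key checking."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return from_dict(RunConfig, data or {})
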