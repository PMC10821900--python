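"""Run configuration: nested dataclasses with strict YAML (de)serialization.

Every parameter has a documented default; unknown keys are rejected rather
than ignored, and a config round-trips losslessly through
``serialize``/``parse``.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field as dc_field
from typing import Any, get_args, get_origin, get_type_hints

import yaml

from ._errors import ConfigError
from .sections import SectionConfig
from .simulate import FieldParams
from .wholemount import BleedConfig, FollicleConfig, SpotConfig

__all__ = ["RunConfig", "GroupSpec", "SimulationConfig", "PathsConfig",
           "ChannelMap", "StatsOptions", "parse", "serialize",
           "load_config", "save_config", "config_hash"]


@dataclass(frozen=True)
class PathsConfig:
    input_dir: str = ""
    output_dir: str = "out"


@dataclass(frozen=True)
class ChannelMap:
    """Which TIFF page holds which channel (page 0 = green/stain by default)."""

    green: int = 0
    red: int = 1
    stain: int = 0
    dapi: int = 1


@dataclass(frozen=True)
class GroupSpec:
    name: str = "ctrl"
    n_mice: int = 5
    mcsc_rate: float = 0.05


@dataclass(frozen=True)
class SimulationConfig:
    params: FieldParams = FieldParams()
    n_fields: int = 20
    groups: tuple[GroupSpec, ...] = ()


@dataclass(frozen=True)
class StatsOptions:
    test: str = "welch_t"
    scheme: str = "littermate_control"
    alpha: float = 0.05


@dataclass(frozen=True)
class RunConfig:
    paths: PathsConfig = PathsConfig()
    channel_map: ChannelMap = ChannelMap()
    follicle: FollicleConfig = FollicleConfig()
    bleed: BleedConfig = BleedConfig()
    spot: SpotConfig = SpotConfig()
    section: SectionConfig = SectionConfig()
    simulation: SimulationConfig = SimulationConfig()
    stats: StatsOptions = StatsOptions()
    seed: int = 0
    log_level: str = "INFO"
    save_images: bool = False
    save_overlays: bool = False


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def _from_plain(cls: type, data: Any, path: str = "") -> Any:
    if not dataclasses.is_dataclass(cls):
        return data
    if data is None:
        return cls()
    if not isinstance(data, dict):
        raise ConfigError(f"{path or cls.__name__}: expected a mapping")
    hints = get_type_hints(cls)
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{path or cls.__name__}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        tp = hints[f.name]
        origin = get_origin(tp)
        if dataclasses.is_dataclass(tp):
            val = _from_plain(tp, val, f"{path}{f.name}.")
        elif isinstance(val, list):
            # All sequence-valued config fields are tuples (ranges, ROIs,
            # group lists); YAML reads them back as lists.
            args = get_args(tp) if origin is tuple else \
                next((get_args(a) for a in get_args(tp)
                      if get_origin(a) is tuple), ())
            if args and dataclasses.is_dataclass(args[0]):
                val = tuple(_from_plain(args[0], v, f"{path}{f.name}[].")
                            for v in val)
            else:
                val = tuple(val)
        kwargs[f.name] = val
    try:
        return cls(**kwargs)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(f"{path or cls.__name__}: {exc}") from exc


def serialize(config: RunConfig) -> str:
    """Canonical YAML representation (sorted keys) of a RunConfig."""
    return yaml.safe_dump(_to_plain(config), sort_keys=True)


def parse(text: str) -> RunConfig:
    data = yaml.safe_load(text) or {}
    return _from_plain(RunConfig, data)


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return parse(fh.read())


def save_config(config: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(serialize(config))


def config_hash(config: RunConfig) -> str:
    """SHA-256 of the canonical serialization; part of run provenance."""
    return hashlib.sha256(serialize(config).encode("utf-8")).hexdigest()
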