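"""Run configuration: YAML round-tripping and provenance stamps."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import fields, is_dataclass
from pathlib import Path

import yaml

from .agents import EffectConfig, PolicyConfig, PopulationSpec
from .errors import ConfigError
from .kinematics import KinematicsConfig
from .pipeline import StudyConfig

__all__ = ["load_config", "save_config", "config_to_dict", "provenance_stamp"]


def _build(cls, data: dict):
    """Construct a (possibly nested) dataclass, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigError(f"expected a mapping for {cls.__name__}, got {type(data).__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = known[name].type
        target = _NESTED.get((cls, name))
        if target is not None and isinstance(value, dict):
            kwargs[name] = _build(target, value)
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


_NESTED = {
    (StudyConfig, "population"): PopulationSpec,
    (StudyConfig, "kinematics"): KinematicsConfig,
    (StudyConfig, "policy"): PolicyConfig,
    (PopulationSpec, "effects"): EffectConfig,
}


def config_to_dict(config: StudyConfig) -> dict:
    return dataclasses.asdict(config)


def load_config(path: str | Path | None = None, data: dict | None = None) -> StudyConfig:
    """Load a :class:`StudyConfig` from YAML (or a dict); unknown keys error."""
    if data is None:
        if path is None:
            return StudyConfig()
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    return _build(StudyConfig, data)


def save_config(config: StudyConfig, path: str | Path) -> None:
    def _plain(obj):
        if isinstance(obj, tuple):
            return [_plain(v) for v in obj]
        if isinstance(obj, dict):
            return {k: _plain(v) for k, v in obj.items()}
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(_plain(config_to_dict(config)), fh, sort_keys=False)


def config_hash(config: StudyConfig) -> str:
    blob = json.dumps(config_to_dict(config), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def provenance_stamp(config: StudyConfig, stage: str, extra: dict | None = None) -> dict:
    """JSON-able provenance record written next to every stage output."""
    from . import __version__

    stamp = {
        "stage": stage,
        "streetnav_version": __version__,
        "config_hash": config_hash(config),
        "master_seed": config.master_seed,
    }
    if extra:
        stamp.update(extra)
    return stamp
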