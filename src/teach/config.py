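"""Run configuration: loading, validation, seeds and provenance.

A run configuration bundles the stimulus/design parameters, the network
architecture (:class:`~teach.model.TeachConfig`), the phase epoch
counts (:class:`~teach.design.ScheduleParams`) and the experiment-level
settings (number of runs, master seed, variants).  Configurations are
read from YAML; unknown keys are rejected so typos fail loudly, and the
effective configuration is echoed next to the results together with a
content hash for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .design import SLEEP_VARIANTS, ScheduleParams
from .model import TeachConfig

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]

CONFIG_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one experiment."""

    n_scenes: int = 12
    pct_active: float = 0.2
    n_runs: int = 20
    master_seed: int = 2024
    variant: str = "TEACH"
    active_threshold: float = 0.5  # d' scoring: unit counts as "on"
    network: TeachConfig = field(default_factory=TeachConfig)
    schedule: ScheduleParams = field(default_factory=ScheduleParams)
    schema_version: int = CONFIG_SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.n_scenes < 2 or self.n_scenes % 2:
            raise ValueError(
                "n_scenes must be even and >= 2 (half the scenes are "
                f"retrieval practiced), got {self.n_scenes}"
            )
        if not 0.0 < self.pct_active < 1.0:
            raise ValueError("pct_active must be in (0, 1)")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.variant not in SLEEP_VARIANTS:
            raise ValueError(
                f"variant must be one of {SLEEP_VARIANTS}, got {self.variant!r}"
            )
        if not 0.0 < self.active_threshold < 1.0:
            raise ValueError("active_threshold must be in (0, 1)")


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _to_plain(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def _build(cls, data: dict, path: str):
    field_map = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(field_map)
    if unknown:
        raise ValueError(
            f"unknown config keys under {path!r}: {sorted(unknown)}"
        )
    kwargs = {}
    for key, value in data.items():
        f = field_map[key]
        if f.type in ("TeachConfig",) or f.name == "network":
            value = _build(TeachConfig, value or {}, f"{path}.{key}")
        elif f.name == "schedule":
            value = _build(ScheduleParams, value or {}, f"{path}.{key}")
        elif isinstance(value, list):
            value = tuple(
                tuple(v) if isinstance(v, list) else v for v in value
            )
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration, merged over the defaults.

    An empty or missing-keys file yields the default configuration.
    Unknown keys raise with the offending names; invariant violations
    raise with the field concerned.
    """
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw)}")
    return _build(RunConfig, raw, "config")


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the effective configuration as YAML (round-trips exactly)."""
    Path(path).write_text(
        yaml.safe_dump(_to_plain(cfg), sort_keys=True, default_flow_style=None)
    )


def config_hash(cfg: RunConfig) -> str:
    """Short content hash of the effective configuration."""
    blob = json.dumps(_to_plain(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
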