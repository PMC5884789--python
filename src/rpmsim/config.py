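"""Run configuration and structured report output.

A run is described by a flat YAML mapping (or equivalent CLI flags; flags
override file values). Exactly one of ``target_g`` / ``eccentricity`` may be
given for the software mode; every output records the seed so a run can be
reproduced bit-identically (modulo timestamps).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from .exceptions import ConfigError

__all__ = ["RunConfig", "load_config", "dump_config", "write_report", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1

logger = logging.getLogger("rpmsim")

_MODES = ("sw", "hw", "classic", "two_state")


@dataclass
class RunConfig:
    """Validated flat configuration for a simulation or planning run."""

    mode: str
    target_g: float | None = None
    eccentricity: float | None = None
    duration: float = 3600.0  # s
    dt: float = 0.1  # s
    max_rate: float = 60.0  # deg/s
    rpm: float | None = None
    radius: float | None = None  # m
    seed: int = 0
    out_trace: str | None = None
    out_report: str | None = None

    def __post_init__(self) -> None:
        problems = []
        if self.mode not in _MODES:
            problems.append(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.duration <= 0:
            problems.append("duration must be positive")
        if self.dt <= 0:
            problems.append("dt must be positive")
        if self.max_rate <= 0:
            problems.append("max_rate must be positive")
        if self.mode == "sw":
            if (self.target_g is None) == (self.eccentricity is None):
                problems.append(
                    "sw mode needs exactly one of target_g / eccentricity"
                )
        if self.mode == "two_state" and self.target_g is None:
            problems.append("two_state mode needs target_g")
        if self.mode == "hw":
            if self.target_g is None or self.radius is None:
                problems.append("hw mode needs target_g and radius")
        if problems:
            raise ConfigError("; ".join(problems))


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a RunConfig from a flat YAML file and/or a dict of flag overrides.

    Unknown keys are rejected (listed in the error); overrides take
    precedence over file values. The resolved configuration is echoed to the
    package logger at INFO level.
    """
    data: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a flat mapping")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
    if "mode" not in data:
        raise ConfigError("missing required config keys: mode")
    cfg = RunConfig(**data)
    logger.info("resolved config: %s", dump_config(cfg))
    return cfg


def dump_config(cfg: RunConfig) -> dict:
    """Normalized plain-dict form of a config (round-trips through load)."""
    return dataclasses.asdict(cfg)


def write_report(payload: dict, path: str | Path, seed: int | None = None) -> dict:
    """Write a versioned JSON report; returns the full report dict.

    The report embeds the schema version, the seed and a creation timestamp;
    everything except the timestamp is deterministic for a fixed
    (config, seed).
    """
    report = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    report.update(payload)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
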