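"""Run configuration: YAML/JSON loading with strict validation.

An empty file (or no file) yields the base case: published Table-style
parameter defaults, WTP of CNY 242,928 per QALY, 5% discounting, full
adherence, the default synthetic cohort and synthetic rate/HR stand-ins.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .economics import WTP_DEFAULT

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    seed: int = 0
    n_iter: int = 1000
    wtp: float = WTP_DEFAULT
    discount_rate: float = 0.05
    adherence: float = 1.0
    quit_smoking: bool = False
    strategies: str | list = "all"
    horizon: int = 30
    rate_table: str | None = None  # CSV path; None -> synthetic stand-in
    hazard_ratio_table: str | None = None  # CSV path; None -> synthetic stand-in
    model_overrides: dict = field(default_factory=dict)
    econ_overrides: dict = field(default_factory=dict)
    output_dir: str = "results"

    def __post_init__(self):
        if self.wtp <= 0:
            raise ConfigError("wtp must be positive")
        if not 0 <= self.discount_rate <= 0.08:
            raise ConfigError("discount rate outside [0, 0.08]")
        if not 0 < self.adherence <= 1:
            raise ConfigError("adherence must lie in (0, 1]")
        if self.horizon < 1:
            raise ConfigError("horizon must be >= 1")
        for p in (self.rate_table, self.hazard_ratio_table):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"referenced file does not exist: {p}")

    def digest(self) -> str:
        import hashlib
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML/JSON config; unknown keys are rejected by name."""
    if path is None:
        return RunConfig()
    raw = Path(path).read_text()
    data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
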