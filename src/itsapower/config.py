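"""Run configuration: defaults, YAML config files and flag overrides.

Precedence is flags > config file > defaults.  The defaults reproduce the
reference simulation settings: intercept 10, pre-trend 0, innovation SD 1,
alpha 0.05, power target 0.80, 10,000 replicates, HAC lag 1, intervention at
50% of the series.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any

import yaml

__all__ = ["RunConfig", "parse_config"]

MODES = ("simulate", "power", "find-effect", "find-n", "table")


@dataclass(frozen=True)
class RunConfig:
    """Effective configuration of one toolkit run."""

    mode: str = "power"
    n_periods: int = 30
    intervention_fraction: float | None = 0.5
    intervention_index: int | None = None
    intercept: float = 10.0
    pre_trend: float = 0.0
    level_pct: float = 0.0
    trend_pct: float = 0.0
    rho: float = 0.0
    sigma: float = 1.0
    alpha: float = 0.05
    power_target: float = 0.80
    target: str = "trend"
    n_reps: int = 10_000
    seed: int = 0
    lag: int = 1
    # search ranges
    n_min: int = 10
    n_max: int = 60
    n_step: int = 1
    effect_min: float = 5.0
    effect_max: float = 350.0
    effect_step: float = 5.0
    out: str | None = None
    verbose: int = 0

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {', '.join(MODES)}")
        if not abs(self.rho) < 1:
            raise ValueError("autocorrelation must satisfy |rho| < 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.power_target < 1.0:
            raise ValueError("power_target must lie in (0, 1)")
        if self.target not in ("level", "trend"):
            raise ValueError("target must be 'level' or 'trend'")
        if self.n_reps < 1:
            raise ValueError("n_reps must be at least 1")
        if self.lag < 0:
            raise ValueError("lag must be nonnegative")
        if self.n_periods < 4:
            raise ValueError("n_periods must be at least 4")
        if self.intervention_fraction is not None and not (
            0.0 < self.intervention_fraction < 1.0
        ):
            raise ValueError("intervention_fraction must lie strictly between 0 and 1")
        if self.level_pct < 0 or self.trend_pct < 0:
            raise ValueError("percent effects must be nonnegative")


_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


def parse_config(
    path: str | None = None,
    overrides: dict[str, Any] | None = None,
) -> RunConfig:
    """Build the effective RunConfig from a YAML file and flag overrides.

    Unknown keys in either source are an error (listed by name); values are
    range-checked with the constraint named in the message.
    """
    values: dict[str, Any] = {}
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        unknown = sorted(set(loaded) - _FIELDS)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(unknown)}")
        values.update(loaded)
    if overrides:
        unknown = sorted(set(overrides) - _FIELDS)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(unknown)}")
        values.update({k: v for k, v in overrides.items() if v is not None})
    # positioning by explicit index wins over the fraction default
    if values.get("intervention_index") is not None and "intervention_fraction" not in values:
        values["intervention_fraction"] = None
    config = RunConfig(**values)
    config.validate()
    return config
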