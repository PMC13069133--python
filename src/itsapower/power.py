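"""Monte-Carlo power estimation and design searches for ITSA studies.

Power is the proportion of simulated replicates in which the two-sided Wald
test on the target coefficient (level change b2 or trend change b3) rejects at
the chosen alpha.  Two searches are provided: the smallest percent effect that
exceeds a power target at a fixed study length (:func:`find_min_effect`) and
the smallest study length that exceeds a power target at a fixed effect
(:func:`find_min_periods`).  :func:`generate_power_table` fills an
(autocorrelation x study-length) grid of minimum effects.

Seeding: a master seed plus the scenario parameters deterministically key a
per-scenario child seed, so every grid cell's replicate stream is independent
of the other cells and of evaluation order, and re-running any cell alone
reproduces it exactly.  Alpha, the tested coefficient and the HAC lag are
excluded from the key, so rejection sets at nested alphas are evaluated on
identical draws.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .dgp import Ar1Init, ScenarioSpec, simulate_outcomes
from .estimator import fit_itsa_batch

__all__ = [
    "PowerEstimate",
    "EffectSearchResult",
    "SampleSizeResult",
    "PowerTable",
    "estimate_power",
    "find_min_effect",
    "find_min_periods",
    "generate_power_table",
    "regenerate_power_table",
    "default_effect_grid",
]

logger = logging.getLogger(__name__)

Target = Literal["level", "trend"]
_TARGET_COLUMN = {"level": 2, "trend": 3}

#: Marker used in CSV output for a grid cell where no effect reached the target.
NOT_REACHED = "NR"


def default_effect_grid() -> np.ndarray:
    """Percent-effect grid 5, 10, ..., 350 (5% increments)."""
    return np.arange(5.0, 355.0, 5.0)


def _scenario_seed_sequence(seed: int, spec: ScenarioSpec) -> np.random.SeedSequence:
    """Child seed keyed by master seed + scenario parameters only."""
    key = (
        f"{spec.n_periods}|{spec.resolved_index}|{spec.intercept!r}|"
        f"{spec.pre_trend!r}|{spec.level_change_pct!r}|{spec.trend_change_pct!r}|"
        f"{spec.rho!r}|{spec.sigma!r}"
    )
    digest = hashlib.blake2b(key.encode(), digest_size=16).digest()
    words = np.frombuffer(digest, dtype=np.uint32)
    return np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *map(int, words)])


@dataclass(frozen=True)
class PowerEstimate:
    """Monte-Carlo rejection proportion for one scenario."""

    power: float
    n_reps: int
    alpha: float
    target: Target
    mc_se: float
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(self)])


@dataclass(frozen=True)
class EffectSearchResult:
    """Smallest grid effect whose power exceeds the target, plus the curve."""

    n_periods: int
    rho: float
    intervention_fraction: float | None
    target: Target
    alpha: float
    power_target: float
    min_effect_pct: float | None
    power_at_min: float | None
    power_curve: list[tuple[float, float]] = field(default_factory=list)

    @property
    def found(self) -> bool:
        return self.min_effect_pct is not None

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.power_curve, columns=["effect_pct", "power"])


@dataclass(frozen=True)
class SampleSizeResult:
    """Smallest study length whose power exceeds the target, plus the curve."""

    target: Target
    alpha: float
    power_target: float
    rho: float
    intervention_fraction: float
    min_periods: int | None
    power_at_min: float | None
    power_curve: list[tuple[int, float]] = field(default_factory=list)

    @property
    def found(self) -> bool:
        return self.min_periods is not None

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.power_curve, columns=["n_periods", "power"])


def estimate_power(
    spec: ScenarioSpec,
    target: Target = "trend",
    alpha: float = 0.05,
    n_reps: int = 10_000,
    seed: int = 0,
    *,
    lag: int = 1,
    use_t: bool = False,
    small_sample: bool = False,
    init: Ar1Init = "innovation",
) -> PowerEstimate:
    """Monte-Carlo power of the Wald test on the target coefficient.

    Generates ``n_reps`` replicate series under ``spec``, fits each with
    Newey-West standard errors at the given lag and returns the proportion
    with the target p-value strictly below ``alpha``.  Degenerate fits (a
    p-value that is not finite) count as non-rejections.
    """
    if target not in _TARGET_COLUMN:
        raise ValueError("target must be 'level' or 'trend'")
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    rng = np.random.default_rng(_scenario_seed_sequence(seed, spec))
    design, outcomes = simulate_outcomes(spec, n_reps, rng, init=init)
    _, pvals = fit_itsa_batch(
        design, outcomes, lag, use_t=use_t, small_sample=small_sample
    )
    p = pvals[:, _TARGET_COLUMN[target]]
    bad = ~np.isfinite(p)
    if bad.any():
        logger.warning("%d replicate(s) with degenerate fits counted as non-rejections",
                       int(bad.sum()))
        p = np.where(bad, 1.0, p)
    power = float(np.mean(p < alpha))
    return PowerEstimate(
        power=power,
        n_reps=n_reps,
        alpha=alpha,
        target=target,
        mc_se=math.sqrt(power * (1.0 - power) / n_reps),
        seed=seed,
    )


def find_min_effect(
    base_spec: ScenarioSpec,
    target: Target = "trend",
    alpha: float = 0.05,
    power_target: float = 0.80,
    effect_grid: Sequence[float] | None = None,
    n_reps: int = 10_000,
    seed: int = 0,
    *,
    lag: int = 1,
    early_stop: bool = True,
    use_t: bool = False,
    small_sample: bool = False,
    init: Ar1Init = "innovation",
) -> EffectSearchResult:
    """Smallest grid effect whose power strictly exceeds ``power_target``.

    ``base_spec`` carries every scenario parameter except the scanned effect
    (its own effect percents for the target must be zero).  The grid is
    scanned ascending; with ``early_stop`` the scan stops at the first
    success, and the evaluated power curve is retained either way.
    """
    grid = np.asarray(default_effect_grid() if effect_grid is None else effect_grid,
                      dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("effect_grid must be nonempty and strictly increasing")
    if not 0.0 < power_target < 1.0:
        raise ValueError("power_target must lie in (0, 1)")
    effect_field = "level_change_pct" if target == "level" else "trend_change_pct"
    if getattr(base_spec, effect_field) != 0:
        raise ValueError(f"base_spec must leave {effect_field} at 0 for the scan")
    curve: list[tuple[float, float]] = []
    best: tuple[float, float] | None = None
    for pct in grid:
        spec = dataclasses.replace(base_spec, **{effect_field: float(pct)})
        est = estimate_power(
            spec, target, alpha, n_reps, seed,
            lag=lag, use_t=use_t, small_sample=small_sample, init=init,
        )
        curve.append((float(pct), est.power))
        logger.info("effect %.0f%% -> power %.4f", pct, est.power)
        if est.power > power_target:
            best = (float(pct), est.power)
            if early_stop:
                break
    return EffectSearchResult(
        n_periods=base_spec.n_periods,
        rho=base_spec.rho,
        intervention_fraction=base_spec.intervention_fraction,
        target=target,
        alpha=alpha,
        power_target=power_target,
        min_effect_pct=None if best is None else best[0],
        power_at_min=None if best is None else best[1],
        power_curve=curve,
    )


def find_min_periods(
    effect_spec: ScenarioSpec,
    target: Target = "trend",
    alpha: float = 0.05,
    power_target: float = 0.80,
    n_min: int = 10,
    n_max: int = 60,
    n_step: int = 1,
    n_reps: int = 10_000,
    seed: int = 0,
    *,
    lag: int = 1,
    early_stop: bool = True,
    use_t: bool = False,
    small_sample: bool = False,
    init: Ar1Init = "innovation",
) -> SampleSizeResult:
    """Smallest study length whose power strictly exceeds ``power_target``.

    ``effect_spec`` fixes the effect and nuisance parameters; its
    ``n_periods`` is replaced by each candidate length in turn and the
    intervention index is re-resolved from ``intervention_fraction`` (0.5 for
    a balanced design).
    """
    if n_min < 4:
        raise ValueError("n_min must be at least 4")
    if effect_spec.intervention_fraction is None:
        raise ValueError(
            "effect_spec must position the intervention by fraction so it can "
            "be re-resolved for each candidate length"
        )
    curve: list[tuple[int, float]] = []
    best: tuple[int, float] | None = None
    for n in range(n_min, n_max + 1, n_step):
        spec = dataclasses.replace(effect_spec, n_periods=n)
        est = estimate_power(
            spec, target, alpha, n_reps, seed,
            lag=lag, use_t=use_t, small_sample=small_sample, init=init,
        )
        curve.append((n, est.power))
        logger.info("n=%d -> power %.4f", n, est.power)
        if est.power > power_target:
            best = (n, est.power)
            if early_stop:
                break
    return SampleSizeResult(
        target=target,
        alpha=alpha,
        power_target=power_target,
        rho=effect_spec.rho,
        intervention_fraction=effect_spec.intervention_fraction,
        min_periods=None if best is None else best[0],
        power_at_min=None if best is None else best[1],
        power_curve=curve,
    )


@dataclass(frozen=True)
class PowerTable:
    """Grid of minimum effects over (rho x n_periods), with its metadata.

    ``frame`` is indexed by rho with one column per study length; NaN cells
    mean no grid effect reached the power target.  ``metadata`` fully
    determines regeneration via :func:`regenerate_power_table`.
    """

    frame: pd.DataFrame
    metadata: dict

    def to_csv(self, path) -> None:
        """Write the table with '#'-prefixed metadata header lines.

        Cells where no effect reached the target are written as ``NR``.
        A machine-readable sidecar ``<path>.meta.json`` is written alongside.
        """
        path = str(path)
        out = self.frame.copy()
        out.columns = [str(c) for c in out.columns]
        with open(path, "w", encoding="utf-8") as fh:
            for key, value in self.metadata.items():
                fh.write(f"# {key} = {json.dumps(value)}\n")
            out.to_csv(fh, index_label="rho", na_rep=NOT_REACHED)
        with open(path + ".meta.json", "w", encoding="utf-8") as fh:
            json.dump(self.metadata, fh, indent=2)
            fh.write("\n")


def generate_power_table(
    target: Target = "trend",
    alpha: float = 0.05,
    power_target: float = 0.80,
    intervention_fraction: float = 0.5,
    rho_grid: Sequence[float] | None = None,
    n_grid: Sequence[int] | None = None,
    effect_grid: Sequence[float] | None = None,
    n_reps: int = 10_000,
    seed: int = 0,
    *,
    intercept: float = 10.0,
    pre_trend: float = 0.0,
    sigma: float = 1.0,
    lag: int = 1,
    use_t: bool = False,
    small_sample: bool = False,
    init: Ar1Init = "innovation",
) -> PowerTable:
    """Minimum-effect table over an (autocorrelation x study-length) grid.

    Each cell is :func:`find_min_effect` for that (rho, n) scenario; cells
    where no grid effect reaches the power target are NaN (written as ``NR``).
    Deterministic given the seed; each cell depends only on its own scenario.
    """
    rhos = np.round(np.arange(-0.9, 0.91, 0.1), 10) if rho_grid is None \
        else np.asarray(rho_grid, dtype=float)
    ns = np.arange(10, 101, 10) if n_grid is None else np.asarray(n_grid, dtype=int)
    if rhos.size == 0 or ns.size == 0:
        raise ValueError("rho_grid and n_grid must be nonempty")
    effects = default_effect_grid() if effect_grid is None \
        else np.asarray(effect_grid, dtype=float)
    cells = np.full((rhos.size, ns.size), np.nan)
    for i, rho in enumerate(rhos):
        for j, n in enumerate(ns):
            base = ScenarioSpec(
                n_periods=int(n),
                intervention_fraction=intervention_fraction,
                intercept=intercept,
                pre_trend=pre_trend,
                rho=float(rho),
                sigma=sigma,
            )
            result = find_min_effect(
                base, target, alpha, power_target, effects, n_reps, seed,
                lag=lag, use_t=use_t, small_sample=small_sample, init=init,
            )
            cells[i, j] = np.nan if not result.found else result.min_effect_pct
            logger.info(
                "table cell rho=%.2f n=%d -> %s", rho, n,
                NOT_REACHED if not result.found else f"{result.min_effect_pct:.0f}%",
            )
    frame = pd.DataFrame(cells, index=pd.Index(rhos, name="rho"), columns=ns)
    metadata = {
        "target": target,
        "alpha": alpha,
        "power_target": power_target,
        "intervention_fraction": intervention_fraction,
        "rho_grid": [float(r) for r in rhos],
        "n_grid": [int(n) for n in ns],
        "effect_grid": [float(e) for e in effects],
        "n_reps": int(n_reps),
        "seed": int(seed),
        "intercept": intercept,
        "pre_trend": pre_trend,
        "sigma": sigma,
        "lag": int(lag),
        "use_t": use_t,
        "small_sample": small_sample,
        "init": init,
    }
    return PowerTable(frame=frame, metadata=metadata)


def regenerate_power_table(metadata: dict) -> PowerTable:
    """Rebuild a table exactly from the metadata of a previous one."""
    meta = dict(metadata)
    kwargs = {k: meta.pop(k) for k in
              ("intercept", "pre_trend", "sigma", "lag", "use_t", "small_sample", "init")}
    return generate_power_table(**meta, **kwargs)
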