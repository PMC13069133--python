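"""Data-generating process for single-group interrupted time-series studies.

A single aggregated unit is observed at ``n`` equally spaced time points and an
intervention "interrupts" the series at some interior point.  The outcome
follows the standard four-parameter segmented regression

    Y_t = b0 + b1*T_t + b2*X_t + b3*(X_t*T_t) + e_t

where ``T_t`` counts time from 0, ``X_t`` is the intervention indicator
(0 before, 1 from the first post-intervention period on) and ``X_t*T_t`` is a
counter of post-intervention periods (1, 2, ... starting in the first
post-intervention period).  ``b2`` is the immediate level change versus the
counterfactual at the intervention point and ``b3`` the change in slope.
Errors are first-order autoregressive, ``e_t = rho*e_{t-1} + u_t`` with iid
Gaussian innovations ``u_t ~ N(0, sigma^2)`` and ``|rho| < 1``.

Effect sizes are specified as percents: a level effect is a percent of the
counterfactual level at the intervention point, a trend effect is a percent
expressed as a per-period slope in units of the innovation SD (so with
``sigma = 1`` a 20% trend effect is a raw slope of 0.20).  Both mappings live
in :func:`percent_to_coefficients` so an alternative convention is a
one-function change.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "ScenarioSpec",
    "SeriesData",
    "resolve_intervention_index",
    "build_design",
    "design_matrix",
    "draw_ar1_errors",
    "percent_to_coefficients",
    "simulate_series",
    "simulate_outcomes",
]

#: How the first error term is drawn.  ``"innovation"`` starts the recursion at
#: e_0 = u_0 (the error process begins fresh at the study onset, as a recursive
#: generator produces); ``"stationary"`` draws e_0 ~ N(0, sigma^2/(1-rho^2)) so
#: the whole series is a draw from the stationary AR(1) law.
Ar1Init = Literal["innovation", "stationary"]


def resolve_intervention_index(n_periods: int, intervention_fraction: float) -> int:
    """Index (0-based) of the first post-intervention period.

    The intervention position is given as a fraction of the series length
    (e.g. 1/3, 1/2, 2/3).  The index is ``round(fraction * n_periods)`` with
    half-up rounding, clamped so that at least one period lies on each side.
    """
    if n_periods < 4:
        raise ValueError("series too short to form a design (need n_periods >= 4)")
    if not 0.0 < intervention_fraction < 1.0:
        raise ValueError("intervention_fraction must lie strictly between 0 and 1")
    idx = math.floor(intervention_fraction * n_periods + 0.5)  # half-up
    return int(min(max(idx, 1), n_periods - 1))


@dataclass(frozen=True)
class ScenarioSpec:
    """Full parameterization of one simulation scenario.

    Exactly one of ``intervention_fraction`` / ``intervention_index`` must be
    given; a fraction is resolved by :func:`resolve_intervention_index`.

    Parameters
    ----------
    n_periods
        Total number of equally spaced time points.
    intervention_fraction
        Position of the intervention as a fraction of the series length.
    intervention_index
        0-based index of the first post-intervention period.
    intercept
        b0, starting level of the outcome.
    pre_trend
        b1, per-period slope before the intervention.
    level_change_pct
        Level effect as a percent of the counterfactual level at the
        intervention point.
    trend_change_pct
        Trend effect as a percent; the raw slope is pct/100 * sigma.
    rho
        AR(1) coefficient between adjacent error terms, |rho| < 1.
    sigma
        SD of the Gaussian innovations.
    """

    n_periods: int
    intervention_fraction: float | None = None
    intervention_index: int | None = None
    intercept: float = 10.0
    pre_trend: float = 0.0
    level_change_pct: float = 0.0
    trend_change_pct: float = 0.0
    rho: float = 0.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.n_periods < 4:
            raise ValueError("series too short to form a design (need n_periods >= 4)")
        if (self.intervention_fraction is None) == (self.intervention_index is None):
            raise ValueError(
                "exactly one of intervention_fraction or intervention_index must be set"
            )
        if self.intervention_index is not None and not (
            1 <= self.intervention_index <= self.n_periods - 1
        ):
            raise ValueError(
                "intervention_index must leave at least one period on each side"
            )
        if not abs(self.rho) < 1:
            raise ValueError("autocorrelation must satisfy |rho| < 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.level_change_pct < 0 or self.trend_change_pct < 0:
            raise ValueError("percent effects must be nonnegative")

    @property
    def resolved_index(self) -> int:
        """0-based index of the first post-intervention period."""
        if self.intervention_index is not None:
            return int(self.intervention_index)
        return resolve_intervention_index(self.n_periods, self.intervention_fraction)


@dataclass(frozen=True)
class SeriesData:
    """One generated series: design columns, error realization and outcome."""

    time_index: np.ndarray
    intervention_indicator: np.ndarray
    interaction: np.ndarray
    errors: np.ndarray | None = None
    outcome: np.ndarray | None = None

    @property
    def n_periods(self) -> int:
        return self.time_index.shape[0]

    def design(self) -> np.ndarray:
        """(n, 4) regression design: constant, T, X, X*T."""
        return np.column_stack(
            [
                np.ones(self.n_periods),
                self.time_index,
                self.intervention_indicator,
                self.interaction,
            ]
        ).astype(float)

    def to_frame(self) -> pd.DataFrame:
        data = {
            "t": self.time_index,
            "T": self.time_index,
            "X": self.intervention_indicator,
            "XT": self.interaction,
        }
        if self.errors is not None:
            data["epsilon"] = self.errors
        if self.outcome is not None:
            data["Y"] = self.outcome
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_design(n_periods: int, intervention_index: int) -> SeriesData:
    """Design columns for a series with the intervention at a given index.

    ``time_index`` runs 0..n-1; the indicator is 0 before
    ``intervention_index`` and 1 from it on; the interaction counts
    post-intervention periods 1, 2, ... starting at the first post period.
    """
    if n_periods < 4:
        raise ValueError("series too short to form a design (need n_periods >= 4)")
    if not 1 <= intervention_index <= n_periods - 1:
        raise ValueError("intervention_index must leave at least one period on each side")
    t = np.arange(n_periods)
    x = (t >= intervention_index).astype(np.int64)
    xt = np.where(x == 1, t - intervention_index + 1, 0)
    return SeriesData(time_index=t, intervention_indicator=x, interaction=xt)


def design_matrix(n_periods: int, intervention_index: int) -> np.ndarray:
    """(n, 4) matrix of (1, T, X, X*T) columns."""
    return build_design(n_periods, intervention_index).design()


def draw_ar1_errors(
    n_periods: int,
    rho: float,
    sigma: float,
    random_state: np.random.Generator,
    *,
    init: Ar1Init = "innovation",
    size: int | None = None,
) -> np.ndarray:
    """Draw one or many AR(1) error series e_t = rho*e_{t-1} + u_t.

    Innovations are iid N(0, sigma^2).  With ``init="innovation"`` the
    recursion starts at e_0 = u_0; with ``init="stationary"`` the first error
    is drawn from the stationary law N(0, sigma^2/(1-rho^2)).

    Returns shape ``(n_periods,)``, or ``(size, n_periods)`` when ``size`` is
    given (row r is replicate r).
    """
    if not abs(rho) < 1:
        raise ValueError("nonstationary autocorrelation: |rho| must be < 1")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    shape = (1 if size is None else size, n_periods)
    x = random_state.normal(0.0, sigma, shape)
    if init == "stationary":
        x[:, 0] = random_state.normal(0.0, sigma / math.sqrt(1.0 - rho * rho), shape[0])
    elif init != "innovation":
        raise ValueError(f"unknown AR(1) initialization {init!r}")
    # y_t = x_t + rho * y_{t-1}; with y_0 = x_0 this is exactly the recursion.
    eps = lfilter([1.0], [1.0, -rho], x, axis=1)
    return eps[0] if size is None else eps


def percent_to_coefficients(spec: ScenarioSpec) -> tuple[float, float]:
    """Map percent effect sizes to the raw coefficients (b2, b3).

    The level percent is taken relative to the counterfactual level at the
    intervention point: ``b2 = pct/100 * (b0 + b1*t_int)``.  The trend percent
    is a per-period slope in units of the innovation SD: ``b3 = pct/100 *
    sigma`` (a 20% trend effect with sigma 1 is a raw slope of 0.20).
    """
    t_int = spec.resolved_index
    counterfactual_level = spec.intercept + spec.pre_trend * t_int
    beta2 = spec.level_change_pct / 100.0 * counterfactual_level
    beta3 = spec.trend_change_pct / 100.0 * spec.sigma
    return beta2, beta3


def _mean_structure(spec: ScenarioSpec, design: np.ndarray) -> np.ndarray:
    beta2, beta3 = percent_to_coefficients(spec)
    beta = np.array([spec.intercept, spec.pre_trend, beta2, beta3])
    return design @ beta


def simulate_series(
    spec: ScenarioSpec,
    random_state: np.random.Generator,
    *,
    init: Ar1Init = "innovation",
) -> SeriesData:
    """Generate one outcome series under the segmented-regression AR(1) model."""
    base = build_design(spec.n_periods, spec.resolved_index)
    errors = draw_ar1_errors(
        spec.n_periods, spec.rho, spec.sigma, random_state, init=init
    )
    outcome = _mean_structure(spec, base.design()) + errors
    return dataclasses.replace(base, errors=errors, outcome=outcome)


def simulate_outcomes(
    spec: ScenarioSpec,
    n_reps: int,
    random_state: np.random.Generator,
    *,
    init: Ar1Init = "innovation",
) -> tuple[np.ndarray, np.ndarray]:
    """Generate many replicate outcome series at once.

    Returns ``(design, outcomes)`` where ``design`` is the shared (n, 4)
    matrix and ``outcomes`` has shape ``(n_reps, n)``, one replicate per row.
    Replicate r of a given call is deterministic in (spec, generator state).
    """
    design = design_matrix(spec.n_periods, spec.resolved_index)
    errors = draw_ar1_errors(
        spec.n_periods, spec.rho, spec.sigma, random_state, init=init, size=n_reps
    )
    return design, _mean_structure(spec, design) + errors
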