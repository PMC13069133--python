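# Methods

## The design being emulated

The package targets the "N-of-1" interrupted time-series study: one
aggregated unit, a continuous outcome observed at `n` equally spaced periods,
and a single sustained intervention beginning at an interior period.  The
data-generating process is the segmented regression

    Y_t = β0 + β1 T_t + β2 X_t + β3 (X_t T_t) + ε_t,   t = 0 … n−1

with AR(1) errors `ε_t = ρ ε_{t−1} + u_t`, `u_t ~ N(0, σ²)`, `|ρ| < 1`.
Coding conventions: `T_t` starts at 0; `X_t` is 0 strictly before the
intervention index and 1 from it on; the interaction counts post-intervention
periods starting at 1 in the first post period.  With these conventions `β2`
is the jump at the intervention point versus the counterfactual projection of
the pre-intervention line, and `β3` is the difference in slopes.

An intervention given as a fraction `f` of the series resolves to index
`round(f·n)` with half-up rounding, clamped to leave at least one period on
each side.  Linear independence of the four design columns additionally needs
two periods on each side (with a single pre period the interaction column
coincides with time; with a single post period it coincides with the
indicator); fits raise a "degenerate design" error in those cases.

## Error initialization

`draw_ar1_errors` starts the recursion at `ε_0 = u_0` by default
(`init="innovation"`): the error process begins fresh at the study onset with
variance σ² and approaches the stationary variance σ²/(1−ρ²) over the first
periods.  This is what a recursive generator naturally produces and is the
convention under which the package reproduces the reference minimum-effect
tables, including their strong asymmetry between ρ = −0.9 and ρ = +0.9.  A
stationary start (`init="stationary"`, `ε_0 ~ N(0, σ²/(1−ρ²))`) is available
when a fully stationary error law is wanted; at the table scenarios it shifts
only the most negative-ρ cells by one 5% grid step.  Over a long series the
two conventions coincide: the long-run variance is σ²/(1−ρ²) and the lag-1
autocorrelation is ρ either way, which is what the moment tests check.

## Percent effect sizes

Users specify effects as percents; the mapping to raw coefficients is
centralized in `percent_to_coefficients`:

* **level**: `β2 = pct/100 · (β0 + β1 t_int)` — percent of the counterfactual
  level at the intervention point (with the default flat baseline, percent of
  the intercept);
* **trend**: `β3 = pct/100 · σ` — a per-period slope in units of the
  innovation SD, so with σ = 1 a "20% trend increase" is a raw slope of 0.20.

The trend convention deserves a remark: "percent of baseline trend" is
undefined when the baseline trend is 0, which is exactly the reference
configuration; expressing the trend percent in innovation-SD units is the
interpretation consistent with the worked example (0.20 ↔ 20%) and with the
published tables.  An alternative interpretation is a one-function change.

## Estimation and inference

Each series is fit by OLS on (1, T, X, XT).  The covariance is the
Bartlett-kernel HAC sandwich

    V = (X'X)⁻¹ [ Σ_t e_t² x_t x_t' + Σ_{j=1}^{L} (1 − j/(L+1)) Σ_t e_t e_{t−j}(x_t x_{t−j}' + x_{t−j} x_t') ] (X'X)⁻¹

with truncation lag L = 1 by default (first-order autocorrelation).  Wald
tests of β2 and β3 are two-sided.  Defaults: **normal reference, no
finite-sample scaling** — the convention of a GLM fit with HAC standard
errors, which is the estimation model the reference tables were built with.
Options: `use_t=True` switches to Student-t with n−4 df, `small_sample=True`
multiplies the covariance by n/(n−4); both are common in OLS-flavoured
Newey-West implementations and make the tests slightly more conservative.

Known behaviour, not a defect: HAC t/z tests over-reject in small samples.
Under the null at n = 100, ρ = 0, lag 1 the measured size at α = 0.05 is
≈ 0.072 with the default z reference (≈ 0.069 with `use_t=True`); at n = 30
it is ≈ 0.13.  This liberality is part of the estimation model whose power
the package measures — "power" here is the rejection rate of exactly this
test, not of an idealized exact test — and it is why very short studies
(around 10 periods) give unreliable minimum-effect estimates.

Degenerate inputs: a noiseless series (residuals at rounding level relative
to the outcome scale) snaps the covariance to zero and returns the documented
degenerate p-values (0 for a nonzero coefficient, 1 otherwise) with a
warning; tiny negative variance diagonals from floating-point cancellation
are clamped to zero.

## Monte-Carlo power and the searches

`estimate_power` simulates `n_reps` series (default 10,000, the reference
replication count), fits all of them in one vectorized pass (shared design,
batched sandwich via einsum — the reason a full grid search runs in seconds
on one CPU) and reports the proportion with the target p-value strictly below
α, plus the binomial Monte-Carlo SE √(p(1−p)/n_reps).  Non-finite p-values
(pathological fits) count as non-rejections.

`find_min_effect` scans the 5%-increment grid (5–350 by default) in ascending
order and returns the smallest effect whose power **strictly exceeds** the
power target, mirroring the ">80% power" reading of the reference tables; the
evaluated curve is kept for diagnostics.  `find_min_periods` does the same
over study lengths (default 10–60 step 1, balanced split), re-resolving the
intervention index at each length.  `generate_power_table` fills a
(ρ × n) grid with minimum effects, writes CSV with `#`-prefixed metadata
lines plus a JSON sidecar, and marks unreached cells `NR`; the metadata fully
regenerates the table.

Seeding: the master seed and the scenario parameters (length, index,
coefficients, ρ, σ) key a per-scenario `SeedSequence` through a BLAKE2
digest.  Consequences: every grid cell is reproducible in isolation, adding
or removing cells never perturbs the others, and results cannot depend on
evaluation order or worker scheduling.  α, the tested coefficient and the
HAC lag are deliberately *excluded* from the key so that nested significance
levels are evaluated on identical draws — making power(α = 0.01) ≤
power(α = 0.05) an exact, not statistical, invariant.

## What the generator does and does not emulate

It emulates the reference study conditions exactly: Gaussian AR(1) noise
around a piecewise-linear mean, a single sustained intervention, a continuous
outcome.  It does not model seasonality, higher-order or moving-average
autocorrelation, non-Gaussian or heteroskedastic noise, counts/rates with
their own variance laws, multiple intervention phases, or comparison groups.
Passing tests therefore certify the toolkit under the stated model, not that
any empirical series satisfies that model; practitioners should treat the
minimum-effect output as a planning baseline and over-correct the assumed ρ
when in doubt, since positive autocorrelation raises the required effect.

## Numerical and design choices

* Replication counts: behavioural tests run at 2,000 replicates (MC SE
  ≈ 0.009 near power 0.8); the headline regeneration script and the
  end-to-end tests use the full 10,000 (MC SE ≈ 0.004).  Vectorized fitting
  makes the full size cheap, so nothing is scaled down in the shipped
  results.
* The grid search does not interpolate between 5% steps; the reported
  minimum is always a grid member.
* Strict inequality at the power target: a cell estimated at exactly 0.800
  does not qualify.
* Ties/rounding: the intervention fraction uses half-up rounding
  (`floor(f·n + 0.5)`), so 2/3 of 10 periods resolves to index 7.
* The known borderline: in the worked example the power at 38–39 periods
  sits almost exactly on 0.90, so the 90% study length can read 38 or 39
  depending on the seed (MC SE ≈ 0.003 at 10,000 replicates).

## Limitations

Inference quality at very short series (n ≈ 10) is poor — minimum-effect
estimates there reflect test miscalibration as much as signal, and the strong
positive-autocorrelation corner (ρ ≥ 0.9) is the regime where lag-1 HAC
correction is least adequate, so published and regenerated values are most
likely to disagree there.  The toolkit measures the power of the lag-1
HAC-adjusted test only; GLS-style alternatives (Prais-Winsten, ARIMA) and
multiple-group designs are out of scope.
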