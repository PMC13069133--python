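"""Generate one interrupted time series and look at its anatomy.

A 30-week study with the intervention at week 15, a baseline level of 10, no
pre-trend, a 50% trend change and moderately autocorrelated errors.
"""

import numpy as np

from itsapower import ScenarioSpec, percent_to_coefficients, simulate_series

spec = ScenarioSpec(
    n_periods=30,
    intervention_fraction=0.5,
    intercept=10.0,
    trend_change_pct=50.0,  # post-intervention slope +0.50 per period
    rho=0.5,
)

series = simulate_series(spec, np.random.default_rng(42))
beta2, beta3 = percent_to_coefficients(spec)

print(f"generating coefficients: b2 (level change) = {beta2}, "
      f"b3 (trend change) = {beta3}")
print(series.to_frame().round(3).to_string(index=False))
print()
print("T counts time from 0; X flips to 1 at the intervention; XT counts")
print("post-intervention periods, so Y drifts upward by b3 per period after")
print("week 15 on top of the AR(1) noise in the epsilon column.")
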