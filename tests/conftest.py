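import numpy as np
import pytest

from itsapower import ScenarioSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20250923)


@pytest.fixture
def balanced_spec():
    """A moderate balanced scenario with a 50% trend effect."""
    return ScenarioSpec(
        n_periods=30, intervention_fraction=0.5, rho=0.5, trend_change_pct=50.0
    )


@pytest.fixture
def null_spec():
    """No-effect scenario for calibration checks."""
    return ScenarioSpec(n_periods=100, intervention_fraction=0.5, rho=0.0)
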