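import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import rspmf

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def lif_curve_small():
    """Moderate LIF transfer curve (q=1 mV) for fitter/baseline tests."""
    return rspmf.measure_transfer_curve(
        rspmf.LIFParams(), q=1.0, eta=0.5, S=40, duration=20.0, seed=101
    )


@pytest.fixture(scope="session")
def q5_fit():
    """Fitted transfer function for the strong-synapse family (q = 5 mV).

    Protocol: eta = 0.8, 500 rates spanning D in [0, 100] mV^2/ms, 100 s
    per point — the input conditions of the bifurcation analysis.
    """
    curve = rspmf.measure_transfer_curve(
        rspmf.LIFParams(), q=5.0, eta=0.8, S=500, duration=100.0, seed=2024
    )
    return rspmf.fit_refractory_softplus(curve)


@pytest.fixture(scope="session")
def q3_fit():
    """Fitted transfer function for the high-noise family (q = 3 mV)."""
    curve = rspmf.measure_transfer_curve(
        rspmf.LIFParams(), q=3.0, eta=0.8, S=500, duration=100.0, seed=2025
    )
    return rspmf.fit_refractory_softplus(curve)


@pytest.fixture()
def rng():
    return np.random.default_rng(8675309)
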