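import pytest
from hypothesis import HealthCheck, settings

import nanodiss as nd
from nanodiss import datasets

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def compound():
    """Reference compound in pH 3 medium (sigma_sl = 30 mJ/m^2)."""
    return datasets.reference_compound()


@pytest.fixture(scope="session")
def reference_psds():
    return datasets.reference_psds()


@pytest.fixture(scope="session")
def sim_cache():
    """Session-wide memo of 999-class equilibrium simulations.

    Shared across calibration and acceptance tests so each distinct
    (PSD, scenario, sigma_sl) combination is simulated once per run.
    """
    return nd.SimulationCache(999)
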