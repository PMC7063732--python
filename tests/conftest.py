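import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import screensim as ss

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_params() -> ss.SimulationParams:
    """A reduced screen that keeps every structural feature of the default."""
    return ss.SimulationParams(
        n_essential=60, n_null=1200, n_controls=100, seed=11
    )


@pytest.fixture(scope="session")
def small_screen(small_params) -> ss.SimulatedScreen:
    return ss.simulate_screen(small_params)


@pytest.fixture(scope="session")
def default_screen() -> ss.SimulatedScreen:
    """One full-size baseline simulation, shared across tests."""
    return ss.simulate_screen(ss.SimulationParams(seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
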