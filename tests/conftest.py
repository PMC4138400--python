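import numpy as np
import pytest

from gripscore.simulate import SimulationConfig, simulate_cohort
from gripscore.tracking import generate_target


@pytest.fixture(scope="session")
def target():
    return generate_target(duration=45.0, sample_rate=50.0, period=9.0)


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down cohort config so unit tests stay fast."""
    return SimulationConfig(
        n_control=4,
        n_patient=4,
        trial_duration=9.0,
        sample_rate=25.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort under the calibrated default configuration."""
    return simulate_cohort(SimulationConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(20240813)
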