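import numpy as np
import pytest

from aigrading.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Default-noise cohort of 10 cases shared across read-only tests."""
    return simulate_cohort(SimulationConfig(seed=123, n_cases=10))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
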