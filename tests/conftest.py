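import numpy as np
import pytest
from hypothesis import settings

import avkinetics as av

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture
def control():
    return av.control_truth()


@pytest.fixture
def treatment():
    return av.treatment_truth()


@pytest.fixture
def protocols():
    return av.default_protocols()


@pytest.fixture
def noise_free():
    return av.NoiseModel(0.0, 0.0, 0.0, 0.0)


@pytest.fixture(scope="session")
def clean_cohort():
    """A noise-free simulated two-group study (plateaus exactly recoverable)."""
    config = av.SimCohortConfig(seed=42, noise=av.NoiseModel(0, 0, 0, 0))
    return av.simulate_cohort(config)


@pytest.fixture(scope="session")
def noisy_cohort():
    """A default-noise simulated study at the design's sample sizes."""
    return av.simulate_cohort(av.SimCohortConfig(seed=7))


def pytest_configure(config):
    # plateau/exclusion warnings are part of normal operation in many tests
    config.addinivalue_line(
        "filterwarnings", "ignore::UserWarning")
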