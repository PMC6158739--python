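import numpy as np
import pytest

from mdcascade import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete synthetic cohort shared across tests."""
    cfg = CohortConfig(grid_shape=(16, 16, 8), n_carriers=30, n_noncarriers=20, seed=7)
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
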