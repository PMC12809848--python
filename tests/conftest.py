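import numpy as np
import pytest

from dmnflow import synthetic as syn


@pytest.fixture(scope="session")
def small_spec():
    """12-subject cohort on a 16^3 grid, 64 volumes, 3 sources."""
    return syn.CohortSpec(
        group_sizes=(4, 4, 4),
        grid_shape=(16, 16, 16),
        n_volumes=64,
        n_sources=3,
        noise_sd=0.5,
        seed=0,
    )


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return syn.simulate_cohort(small_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
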