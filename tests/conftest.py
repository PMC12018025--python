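import numpy as np
import pytest

from edubrain import SyntheticConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Three-group desk-scale cohort with default planted effects."""
    cfg = SyntheticConfig(
        n_subjects_per_group=(60, 30, 20),
        grid_shape=(8, 8, 8),
        n_rois=20,
        n_countries=12,
        seed=7,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def hc500_cohort():
    """Single-group n=500 cohort at the parameter-recovery conditions."""
    cfg = SyntheticConfig(
        n_subjects_per_group=(500, 0, 0),
        n_rois=10,
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
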