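import numpy as np
import pytest

from szgcn.cohort import CohortConfig, make_atlas_phantom, simulate_cohort


@pytest.fixture(scope="session")
def small_atlas():
    """12 ROIs of 2x2x2 voxels: smallest atlas the generator accepts."""
    return make_atlas_phantom(12, (2, 2, 2))


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_control=6, n_patient=6, seed=7, n_timepoints=64)


@pytest.fixture(scope="session")
def small_cohort(small_atlas, small_config):
    subjects, manifest = simulate_cohort(small_atlas, small_config)
    return subjects, manifest


@pytest.fixture(scope="session")
def subject(small_cohort):
    return small_cohort[0][0]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
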