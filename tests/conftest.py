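import numpy as np
import pytest

from matnets import default_mask, default_truth_spec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_mask():
    """Tiny ellipsoidal mask with mirror pairing (~200 voxels)."""
    return default_mask(shape=(10, 10, 8))


@pytest.fixture(scope="session")
def toy_cohort():
    """Small synthetic cohort shared by read-only tests (K=12, tiny grid)."""
    spec = default_truth_spec(default_mask(shape=(10, 10, 8)), seed=7)
    cohort, series, spec = generate_cohort(spec, n_subjects=12, n_timepoints=60)
    return cohort, series, spec
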