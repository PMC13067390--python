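import numpy as np
import pytest

from dynfc import CohortSpec


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture(scope="session")
def small_spec():
    """Well-separated two-state cohort, small enough for fast tests."""
    return CohortSpec(
        n_subjects=8,
        n_rois=8,
        n_modules=2,
        n_frames=240,
        tr_seconds=0.72,
        within_r=0.6,
        between_r_segregated=0.05,
        between_r_integrated=0.45,
        seed=7,
    )
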