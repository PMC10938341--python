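import numpy as np
import pytest

from surfqc.synthetic import CohortSimParams, PhantomConfig, make_phantom_subject, simulate_cohort


@pytest.fixture(scope="session")
def phantom():
    """Default two-hemisphere ellipsoid phantom (shared; treat as read-only)."""
    return make_phantom_subject(PhantomConfig(seed=7))


@pytest.fixture(scope="session")
def small_phantom():
    """Coarse phantom for I/O round-trips and fast pipeline tests."""
    cfg = PhantomConfig(shape=(48, 56, 48), voxel_size=3.0, subdivisions=2, seed=3)
    return make_phantom_subject(cfg)


@pytest.fixture(scope="session")
def recovery_cohort():
    """Cohort with known mixed-sign regional quality effects, for recovery tests."""
    target = np.array([-0.35, -0.3, -0.25, -0.2] * 2 + [0.0] * 8 + [0.1, 0.15, 0.2, 0.25])
    params = CohortSimParams(n=1200, n_regions=len(target), target_partial_r=target, seed=42)
    cohort, truth = simulate_cohort(params)
    return cohort, truth
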