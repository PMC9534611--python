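import numpy as np
import pytest

from wavemics import CohortConfig, ImageVolume, ROIMask, discretize, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_droi(rng, shape=(4, 4, 4), n_levels=4, full_mask=False):
    """Small discretized ROI with a random (or full) mask, for oracle checks."""
    vals = rng.integers(0, n_levels, size=shape).astype(float) * 10.0
    if full_mask:
        mask = np.ones(shape, dtype=bool)
    else:
        mask = rng.random(shape) < 0.75
        if not mask.any():
            mask[0, 0, 0] = True
    vol = ImageVolume(vals, (1.0, 1.0, 1.0))
    return discretize(vol, ROIMask(mask), bin_width=10.0)


@pytest.fixture
def droi_factory(rng):
    return lambda **kw: random_droi(rng, **kw)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-patient cohort with small volumes, shared across tests."""
    cfg = CohortConfig(n_patients=6, volume_shape=(16, 20, 20),
                       voxel_spacing=(1.5, 1.0, 1.0),
                       tumor_radius_range_per_class={1: (4.5, 7.0), 0: (3.5, 5.5)},
                       seed=42)
    return generate_cohort(cfg)
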