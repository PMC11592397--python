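import numpy as np
import pytest

from petrad.core import Volume
from petrad.synthetic import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def smooth_phantom():
    """Noise-free textured phantom shared across feature tests."""
    spec = PhantomSpec(
        grid_shape=(24, 24, 16),
        spacing_mm=(3.0, 3.0, 3.0),
        lesion_radius_mm=14.0,
        suv_max=10.0,
        background_suv=0.5,
        heterogeneity_sd=0.2,
        noise_sd=0.0,
        seed=7,
    )
    vol, mask = generate_phantom(spec)
    return spec, vol, mask


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_level_image(rng, max_shape=(5, 5, 3), n_levels=4, p_mask=0.8):
    """A random small integer image + mask for oracle equivalence tests."""
    shape = tuple(int(rng.integers(2, m + 1)) for m in max_shape)
    levels = rng.integers(1, n_levels + 1, size=shape)
    mask = rng.random(shape) < p_mask
    if not mask.any():
        mask[0, 0, 0] = True
    # renumber so levels are 1..Ng with no gaps above the max
    return levels.astype(np.int64), mask


@pytest.fixture()
def make_volume():
    def _make(values, spacing=(1.0, 1.0, 1.0)):
        return Volume(np.asarray(values, dtype=float), spacing)

    return _make
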