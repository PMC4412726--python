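import numpy as np
import pytest

from petroi.phantom import PhantomSpec, make_atlas_phantom, simulate_cohort
from petroi.volume_io import Atlas, BrainMask, Volume


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_atlas():
    """3-region 6x6x6 atlas with a 0 background shell."""
    labels = np.zeros((6, 6, 6), dtype=np.int64)
    labels[1:5, 1:5, 1:3] = 1
    labels[1:5, 1:5, 3:4] = 2
    labels[1:5, 1:5, 4:5] = 3
    return Atlas(labels, {1: "front", 2: "mid", 3: "back"})


@pytest.fixture(scope="session")
def tiny_mask(tiny_atlas):
    return BrainMask.from_boolean(tiny_atlas.labels != 0)


@pytest.fixture(scope="session")
def small_phantom():
    """Small deterministic phantom: atlas, mask and baseline volume."""
    spec = PhantomSpec(shape=(12, 14, 12), n_regions=6, seed=11)
    atlas, mask, baseline = make_atlas_phantom(spec)
    return spec, atlas, mask, baseline


@pytest.fixture(scope="session")
def small_cohort():
    """8 NC + 8 AD subjects on a small 6-region phantom."""
    spec = PhantomSpec(shape=(12, 14, 12), n_regions=6, seed=11)
    return simulate_cohort(spec, {"NC": 8, "AD": 8})


def random_volume(shape, rng, low=0.5, high=1.5) -> Volume:
    return Volume(rng.uniform(low, high, size=shape))
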