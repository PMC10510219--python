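from __future__ import annotations

import numpy as np
import pytest

from pet_hetero.voi import SUVolume


@pytest.fixture
def line_volume() -> tuple[SUVolume, tuple[int, int, int]]:
    """A 1D uptake ridge [1,4,8,10,7,3,1] embedded in a 3D unit background.

    Returns the volume and the seed at the 10-valued voxel.  Hand-checkable:
    at 50 % of the local max (level 5.0) the VOI is the {8, 10, 7} run; at
    the absolute 2.5 cut-off it is {4, 8, 10, 7, 3}.
    """
    values = np.ones((5, 5, 7))
    ridge = [1.0, 4.0, 8.0, 10.0, 7.0, 3.0, 1.0]
    values[2, 2, :] = ridge
    return SUVolume(values, (1.0, 1.0, 1.0)), (2, 2, 3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_blob_volume(rng: np.random.Generator, max_side: int = 20) -> SUVolume:
    """A random smooth-ish positive volume for oracle comparisons."""
    from scipy import ndimage

    shape = tuple(int(rng.integers(5, max_side + 1)) for _ in range(3))
    raw = rng.uniform(0.0, 10.0, size=shape)
    smooth = ndimage.gaussian_filter(raw, sigma=1.0)
    return SUVolume(smooth, (2.0, 2.0, 2.0))
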