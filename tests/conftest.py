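import numpy as np
import pytest

from coldmotility import MotilitySimConfig
from skimage.draw import disk as draw_disk


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(20260927))


@pytest.fixture
def tiny_config():
    """Small, fast simulation config (20 frames -> two 3-min pairs)."""
    return MotilitySimConfig(
        n_cells=3,
        n_frames=19,
        field_size_px=(256, 256),
        seed=7,
    )


def disk_mask(radius_px: int, shape=None, center=None) -> np.ndarray:
    """Rasterized disk: pixels whose centers fall within the radius."""
    if shape is None:
        shape = (2 * radius_px + 21, 2 * radius_px + 21)
    if center is None:
        center = (shape[0] // 2, shape[1] // 2)
    m = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk(center, radius_px, shape=shape)
    m[rr, cc] = True
    return m


@pytest.fixture
def make_disk():
    return disk_mask
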