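import numpy as np
import pytest

from nodulecad.preprocessing import ImageSlice


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def disk_mask(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def bar_mask(shape, top_left, height, width):
    m = np.zeros(shape, dtype=bool)
    r, c = top_left
    m[r : r + height, c : c + width] = True
    return m


@pytest.fixture
def disk_image():
    """64x64 image: background 0.2 with a radius-11 disk at 0.8."""
    mask = disk_mask((64, 64), (32, 32), 11)
    px = np.full((64, 64), 0.2)
    px[mask] = 0.8
    return ImageSlice(pixels=px), mask


@pytest.fixture
def bar_image():
    """64x64 image: background 0.2 with a 3x40 bar at 0.8."""
    mask = bar_mask((64, 64), (30, 10), 3, 40)
    px = np.full((64, 64), 0.2)
    px[mask] = 0.8
    return ImageSlice(pixels=px), mask
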