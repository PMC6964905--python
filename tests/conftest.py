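import numpy as np
import pytest

from remodelkit.core import BinaryMask, ImageStack


@pytest.fixture
def disc_mask():
    """Factory for a single-disc 2D cell mask."""

    def make(shape=(64, 64), center=(32, 32), radius=10.0, spacing=(1.0, 1.0, 1.0)):
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        m = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2
        return BinaryMask(m, spacing)

    return make


@pytest.fixture
def two_level_image():
    """A noise-free two-level image: background 10, bright block 200."""
    img = np.full((1, 64, 64), 10.0)
    img[0, 20:44, 20:44] = 200.0
    return ImageStack(img, (1.0, 1.0, 1.0))
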