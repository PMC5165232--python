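import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))   # makes `oracles` importable

from lungtex.image import GrayImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_small_images(rng):
    """50 random images up to 8x8 with up to 4 gray levels."""
    images = []
    for _ in range(50):
        rows = int(rng.integers(2, 9))
        cols = int(rng.integers(2, 9))
        g = int(rng.integers(2, 5))
        px = rng.integers(0, g, size=(rows, cols))
        images.append(GrayImage(px.astype(np.intp), g))
    return images
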