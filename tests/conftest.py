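import numpy as np
import pytest

from cellcoloc.metrics import CellPixels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cell(*channels) -> CellPixels:
    return CellPixels(*[np.asarray(c, dtype=float) for c in channels])


@pytest.fixture
def disc_pair_image():
    """Two touching discs (r=10, centers 15 px apart) on a dark field."""
    img = np.zeros((60, 80))
    yy, xx = np.mgrid[0:60, 0:80]
    for cx in (30, 45):
        img[(yy - 30) ** 2 + (xx - cx) ** 2 <= 100] = 200.0
    return img
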