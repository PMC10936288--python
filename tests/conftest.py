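import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pennatrack import PixelSet

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_pixelset(coords, intensity=200, roi="top"):
    """PixelSet from an iterable of (col, row) pairs with uniform intensity."""
    coords = np.asarray(list(coords), dtype=np.int64)
    if coords.size == 0:
        return PixelSet.empty(roi)
    inten = np.full(len(coords), intensity, dtype=np.int64)
    return PixelSet(coords[:, 0], coords[:, 1], inten, roi)


@pytest.fixture
def pixelset_factory():
    return make_pixelset


def block(c0, r0, w, h):
    """Solid w x h block of (col, row) pairs with top-left (c0, r0)."""
    return [(c0 + dc, r0 + dr) for dr in range(h) for dc in range(w)]


@pytest.fixture
def block_factory():
    return block
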