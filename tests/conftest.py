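import numpy as np
import pytest

from fractalcin.imaging import NucleiMask, RgbTile


@pytest.fixture
def rng():
    return np.random.default_rng(20141010)


@pytest.fixture
def random_masks(rng):
    """A small randomized suite of non-empty binary masks."""
    masks = []
    for i, (size, p) in enumerate([(32, 0.5), (64, 0.2), (64, 0.05), (128, 0.3)]):
        px = rng.random((size, size)) < p
        px[size // 2, size // 2] = True  # guarantee non-empty
        masks.append(NucleiMask(pixels=px, id=f"rand{i}"))
    return masks


def make_tile(pixels, id="t"):
    return RgbTile(pixels=np.asarray(pixels, dtype=np.uint8), id=id)


@pytest.fixture
def uniform_tile_factory():
    def factory(rgb, size=8):
        px = np.empty((size, size, 3), dtype=np.uint8)
        px[:] = rgb
        return make_tile(px, id=f"uniform{rgb}")

    return factory
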