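import numpy as np
import pytest

from massdesc.io import GrayImage
from massdesc.phantoms import PhantomSpec, make_mask


@pytest.fixture
def disk_mask():
    """Rasterized disk of radius 60 in a 160x160 frame."""
    from skimage.draw import disk as sk_disk

    m = np.zeros((160, 160), bool)
    rr, cc = sk_disk((80, 80), 60, shape=m.shape)
    m[rr, cc] = True
    return m


@pytest.fixture
def star_mask():
    """Five-lobed phantom mask (harmonic k=5, a=0.2)."""
    mask, _ = make_mask(PhantomSpec(patch_size=96, r0=20, harmonics=((0.2, 5, 0.4),), seed=1))
    return mask


def ellipse_mask(aspect: float, b: int = 35, frame: int = 260) -> np.ndarray:
    from skimage.draw import ellipse

    m = np.zeros((frame, frame), bool)
    rr, cc = ellipse(frame // 2, frame // 2, b * aspect, b, shape=m.shape)
    m[rr, cc] = True
    return m


@pytest.fixture
def gray_image():
    rng = np.random.default_rng(0)
    return GrayImage(pixels=rng.integers(0, 256, (32, 32), dtype=np.uint8), L=255, id="g")
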