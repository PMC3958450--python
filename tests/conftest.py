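import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def texture(rng):
    """A high-frequency random texture; blurring it visibly reduces focus."""
    return rng.integers(0, 256, size=(48, 48)).astype(np.uint8)


def synthetic_tube(shape=(96, 96), start=(20, 15), end=(70, 80),
                   width_px=3.5, psf_px=1.3, amplitude=0.6, background=0.06):
    """Noise-free image of one straight tube plus its axis polyline."""
    from scipy import ndimage as ndi

    h, w = shape
    n = 400
    ts = np.linspace(0, 1, n)
    pts = np.array(start)[None] * (1 - ts[:, None]) + np.array(end)[None] * ts[:, None]
    canvas = np.zeros((2 * h, 2 * w), dtype=bool)
    ij = np.round(pts * 2).astype(int)
    canvas[ij[:, 0], ij[:, 1]] = True
    dist = ndi.distance_transform_edt(~canvas)
    coverage = (dist <= width_px).reshape(h, 2, w, 2).mean(axis=(1, 3))
    img = background + amplitude * ndi.gaussian_filter(coverage, psf_px)
    return img, pts
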