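import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mitomorph.imgproc import CellImage
from mitomorph.synthgen import ImagingParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def noise_free_params():
    """Ideal microscope: no blur, no noise, 0.1 µm pixels."""
    return ImagingParams(pixel_size=0.1, psf_sigma=0.0, noise_sd=0.0,
                         image_shape=(160, 160))


def make_image(pixels, pixel_size=1.0, bit_depth=8, **kw):
    return CellImage(np.asarray(pixels, dtype=float), pixel_size, bit_depth, **kw)


@pytest.fixture
def bimodal_image():
    """90% of pixels at 10, 10% at 200 — perfectly separable classes."""
    px = np.full((20, 20), 10.0)
    px.ravel()[:40] = 200.0
    return make_image(px)
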