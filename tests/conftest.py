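import numpy as np
import pytest

from gliofire.phantom import PhantomSpec, generate_slice
from gliofire.preprocessing import apply_foreground, preprocess_slice


@pytest.fixture(scope="session")
def hgg_sample():
    """Small HGG-like phantom with one tumor (96x96, default noise)."""
    spec = PhantomSpec.for_class("HGG", image_height=96, image_width=96,
                                 tumor_radius=9, seed=3)
    return generate_slice(spec)


@pytest.fixture(scope="session")
def hgg_fg(hgg_sample):
    """Preprocessed foreground of the small HGG phantom."""
    return preprocess_slice(hgg_sample.image, out_shape=(96, 96))


@pytest.fixture(scope="session")
def two_band_fg():
    """Noiseless 16x16 two-band image (levels 40 and 220), full-frame mask."""
    img = np.zeros((16, 16))
    img[:8] = 40 / 255.0
    img[8:] = 220 / 255.0
    return apply_foreground(img, np.ones((16, 16), dtype=bool))


def make_fg(values_8bit, mask=None):
    """Foreground from an explicit 8-bit array (test helper)."""
    arr = np.asarray(values_8bit, dtype=float) / 255.0
    if mask is None:
        mask = np.ones(arr.shape, dtype=bool)
    return apply_foreground(arr, mask)
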