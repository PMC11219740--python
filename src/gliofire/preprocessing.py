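"""Slice preprocessing: intensity normalization, histogram equalization,
bilinear resize, and morphological background removal.

The background-removal chain binarizes the slice at an intensity
threshold (default 0.05 of full scale), erodes the binary mask with a
flat 3x3 minimum filter to suppress speckle, keeps the largest
connected component, fills its interior holes, and multiplies the
resulting brain mask into the gray image to obtain the foreground.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = [
    "ForegroundResult",
    "normalize_minmax",
    "equalize_histogram",
    "binarize_background",
    "erode_min_filter",
    "extract_brain_mask",
    "apply_foreground",
    "resize_bilinear",
    "preprocess_slice",
]


class NoTissueError(ValueError):
    """Raised when background removal finds no foreground pixel."""


@dataclass
class ForegroundResult:
    """Background-removed slice: gray foreground, brain mask, brain area."""

    fg_image: np.ndarray   # float in [0, 1]; zero outside brain_mask
    brain_mask: np.ndarray  # bool
    brain_area: int


def normalize_minmax(raw: np.ndarray) -> np.ndarray:
    """Min-max rescale to [0, 1]; a constant input maps to all zeros."""
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise ValueError("cannot normalize an empty image")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.zeros_like(raw)
    return (raw - lo) / (hi - lo)


def equalize_histogram(img: np.ndarray) -> np.ndarray:
    """256-bin cumulative-histogram equalization on the 8-bit quantization.

    Uses the classic normalization ``(cdf - cdf_min) / (1 - cdf_min)``,
    which maps the darkest occupied gray level to 0.  This keeps a dark,
    near-constant background dark, so the 0.05 background binarization
    that follows in the pipeline still recovers the brain.  The result
    is returned on the [0, 1] scale.
    """
    img = np.asarray(img, dtype=float)
    q = np.clip(np.rint(img * 255.0), 0, 255).astype(np.int64)
    hist = np.bincount(q.ravel(), minlength=256)
    cdf = np.cumsum(hist) / q.size
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    if cdf_min >= 1.0:  # single occupied bin: constant image is a fixed point
        return img.copy()
    mapping = (cdf - cdf_min) / (1.0 - cdf_min)
    return mapping[q]


def binarize_background(img: np.ndarray, tau: float = 0.05) -> np.ndarray:
    """Foreground mask: True where intensity >= tau (ties go to foreground)."""
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")
    return np.asarray(img, dtype=float) >= tau


def erode_min_filter(img: np.ndarray, se_size: int = 3) -> np.ndarray:
    """Flat (gray-scale) erosion: each pixel becomes the minimum of its
    se_size x se_size neighborhood, with replicate padding at borders."""
    if se_size < 3 or se_size % 2 == 0:
        raise ValueError("structuring element size must be an odd integer >= 3")
    arr = np.asarray(img)
    out = ndimage.minimum_filter(arr.astype(float), size=se_size, mode="nearest")
    if arr.dtype == bool:
        return out.astype(bool)
    return out


def extract_brain_mask(bin_mask: np.ndarray) -> np.ndarray:
    """Largest 8-connected component of the mask, with interior holes filled."""
    bin_mask = np.asarray(bin_mask, dtype=bool)
    if not bin_mask.any():
        raise NoTissueError("no foreground pixels: nothing resembling tissue found")
    labeled, n = ndimage.label(bin_mask, structure=np.ones((3, 3), dtype=int))
    areas = np.bincount(labeled.ravel())[1:]
    keep = int(np.argmax(areas)) + 1
    component = labeled == keep
    return ndimage.binary_fill_holes(component)


def apply_foreground(img: np.ndarray, brain: np.ndarray) -> ForegroundResult:
    """Eq. FG = B' . I: zero the image outside the brain mask."""
    img = np.asarray(img, dtype=float)
    brain = np.asarray(brain, dtype=bool)
    if img.shape != brain.shape:
        raise ValueError(f"shape mismatch: image {img.shape} vs mask {brain.shape}")
    return ForegroundResult(
        fg_image=img * brain, brain_mask=brain, brain_area=int(brain.sum())
    )


def resize_bilinear(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Bilinear resample to (out_h, out_w); pixel-center grid alignment."""
    if out_h < 1 or out_w < 1:
        raise ValueError("output dimensions must be >= 1")
    img = np.asarray(img, dtype=float)
    if img.shape == (out_h, out_w):
        return img.copy()
    out = _sk_resize(
        img, (out_h, out_w), order=1, mode="edge", anti_aliasing=False, preserve_range=True
    )
    return np.clip(out, 0.0, 1.0) if img.min() >= 0.0 and img.max() <= 1.0 else out


def preprocess_slice(
    raw: np.ndarray,
    tau: float = 0.05,
    out_shape: tuple[int, int] = (200, 200),
    equalize: bool = True,
    se_size: int = 3,
) -> ForegroundResult:
    """Full per-slice chain: normalize -> (equalize) -> resize -> binarize ->
    erode -> largest component + hole fill -> foreground masking."""
    img = normalize_minmax(raw)
    if equalize:
        img = equalize_histogram(img)
    img = resize_bilinear(img, *out_shape)
    mask = binarize_background(img, tau=tau)
    eroded = erode_min_filter(mask, se_size=se_size)
    brain = extract_brain_mask(eroded)
    return apply_foreground(img, brain)
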