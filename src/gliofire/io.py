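"""Reading and writing the pipeline's image and table formats."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "read_gray", "write_gray_png", "write_mask_png", "write_label_png",
    "load_nifti_slice", "write_json", "read_json",
]


def read_gray(path: str | Path) -> np.ndarray:
    """8-bit grayscale PNG/TIFF -> float image in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=float)
    return arr / 255.0


def write_gray_png(path: str | Path, img: np.ndarray) -> None:
    """Float [0, 1] image -> 8-bit grayscale PNG."""
    arr = np.clip(np.rint(np.asarray(img, dtype=float) * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    Image.fromarray((np.asarray(mask, dtype=bool) * 255).astype(np.uint8), mode="L").save(path)


def write_label_png(path: str | Path, labels: np.ndarray) -> None:
    """Integer label map -> 16-bit PNG."""
    Image.fromarray(np.asarray(labels).astype(np.uint16), mode="I;16").save(path)


def load_nifti_slice(path: str | Path, slice_index: int, axis: int = 0) -> np.ndarray:
    """Extract one axial slice from a NIfTI volume as a float array.

    ``axis`` selects the slicing axis of the stored array (0 for the
    155-slice axis of a 155 x 240 x 240 volume).
    """
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(path)).dataobj)
    if not 0 <= slice_index < vol.shape[axis]:
        raise IndexError(f"slice {slice_index} outside axis of length {vol.shape[axis]}")
    return np.take(vol, slice_index, axis=axis).astype(float)


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
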