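"""Suspected-tumor region selection by brightness and area.

Tumors appear as contiguous regions brighter than the surrounding brain
tissue, at least at their rim.  A segment becomes a region of interest
when its mean intensity exceeds the brain mean by ``intensity_k`` brain
standard deviations AND its area fraction of the brain lies inside a
configurable band that excludes both speckle and whole tissue bands.
Residual (scattered sub-threshold) segments are not candidates.  When
nothing qualifies, a single whole-brain fallback ROI is returned so the
classifier always receives input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import ForegroundResult, resize_bilinear
from .segmentation import SegmentSet, quantize_intensities

__all__ = ["ROIConfig", "ROIRecord", "extract_rois", "crop_and_resize"]


@dataclass(frozen=True)
class ROIConfig:
    intensity_k: float = 1.0        # multiplier on the brain intensity sd
    min_area_fraction: float = 0.002
    max_area_fraction: float = 0.3
    patch_size: int = 200

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_area_fraction < self.max_area_fraction <= 1.0:
            raise ValueError("need 0 <= min_area_fraction < max_area_fraction <= 1")


@dataclass
class ROIRecord:
    bbox: tuple[int, int, int, int]  # (r0, r1, c0, c1), half-open
    mask: np.ndarray                 # bool within bbox
    mean_intensity: float            # on the 0..255 scale
    area: int
    source_segment_id: int           # 0 for the whole-brain fallback


def _bbox_of(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    r0, r1 = np.nonzero(rows)[0][[0, -1]]
    c0, c1 = np.nonzero(cols)[0][[0, -1]]
    return int(r0), int(r1) + 1, int(c0), int(c1) + 1


def extract_rois(cs: SegmentSet, fg: ForegroundResult, cfg: ROIConfig | None = None) -> list[ROIRecord]:
    """Select tumor-candidate segments, brightest first.

    Gates: mean intensity >= brain mean + intensity_k * brain sd, and
    brain-area fraction within [min_area_fraction, max_area_fraction].
    """
    if cfg is None:
        cfg = ROIConfig()
    if cs.L == 0:
        raise ValueError("empty segment set")
    q = quantize_intensities(fg)
    brain_vals = q[fg.brain_mask].astype(float)
    gate = brain_vals.mean() + cfg.intensity_k * brain_vals.std()
    records: list[ROIRecord] = []
    for seg in cs.segments:
        if seg.residual:
            continue
        frac = seg.area / fg.brain_area
        if seg.center >= gate and cfg.min_area_fraction <= frac <= cfg.max_area_fraction:
            m = cs.label_image == seg.id
            bbox = _bbox_of(m)
            records.append(
                ROIRecord(
                    bbox=bbox,
                    mask=m[bbox[0] : bbox[1], bbox[2] : bbox[3]],
                    mean_intensity=seg.center,
                    area=seg.area,
                    source_segment_id=seg.id,
                )
            )
    if not records:
        bbox = _bbox_of(fg.brain_mask)
        sub = fg.brain_mask[bbox[0] : bbox[1], bbox[2] : bbox[3]]
        records.append(
            ROIRecord(
                bbox=bbox,
                mask=sub,
                mean_intensity=float(brain_vals.mean()),
                area=int(fg.brain_area),
                source_segment_id=0,
            )
        )
    records.sort(key=lambda r: -r.mean_intensity)
    return records


def crop_and_resize(roi: ROIRecord, fg: ForegroundResult, patch_size: int = 200) -> np.ndarray:
    """Tight bbox crop of the foreground image, bilinearly resized to a
    square patch (aspect ratio not preserved)."""
    r0, r1, c0, c1 = roi.bbox
    if r1 <= r0 or c1 <= c0:
        raise ValueError("zero-area ROI bounding box")
    crop = fg.fg_image[r0:r1, c0:c1]
    return resize_bilinear(crop, patch_size, patch_size)
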