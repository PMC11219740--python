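"""End-to-end orchestration: phantoms -> preprocessing -> FFO segmentation
-> ROI extraction -> LBP features -> cross-validated parallel CNN.

A single master seed deterministically derives every stage seed, so a
rerun with the same configuration reproduces the MetricsReport exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .classifier import TrainConfig
from .evaluation import MetricsReport, SliceSample, cross_validate
from .lbp import LBPConfig, extract_lbp_features
from .phantom import PhantomSpec, generate_dataset
from .preprocessing import ForegroundResult, preprocess_slice
from .roi import ROIConfig, crop_and_resize, extract_rois
from .segmentation import FFOConfig, segment_image

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "featurize_slice",
           "featurize_dataset", "load_config"]

log = logging.getLogger("gliofire")


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    # phantom generation
    n_slices: int = 200
    class_balance: float = 0.51
    image_size: int = 200
    tumor_radius: float = 18.0
    noise_sd: float = 5.0
    band_intensities: tuple[float, ...] = (60.0, 110.0, 160.0)
    # preprocessing
    tau: float = 0.05
    resize_to: int = 200
    equalize: bool = True
    # stage configs
    ffo: FFOConfig = field(default_factory=FFOConfig)
    roi: ROIConfig = field(default_factory=ROIConfig)
    lbp: LBPConfig = field(default_factory=LBPConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    folds: int = 10
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        """Derive a per-stage seed from the master seed."""
        h = np.random.SeedSequence(
            [self.seed, int.from_bytes(stage.encode(), "little") % (2**31)]
        )
        return int(h.generate_state(1)[0] % (2**31 - 1))


_STAGE_KEYS = {"ffo": FFOConfig, "roi": ROIConfig, "lbp": LBPConfig, "train": TrainConfig}


def load_config(path: str | Path) -> PipelineConfig:
    """Read a flat YAML config with optional ffo/roi/lbp/train sections."""
    try:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    except (OSError, yaml.YAMLError) as exc:
        raise PipelineError("config", str(exc)) from exc
    kwargs = {}
    for key, value in raw.items():
        if key in _STAGE_KEYS:
            value = {k: tuple(v) if isinstance(v, list) else v for k, v in value.items()}
            kwargs[key] = _STAGE_KEYS[key](**value)
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    try:
        return PipelineConfig(**kwargs)
    except TypeError as exc:
        raise PipelineError("config", str(exc)) from exc


def featurize_slice(
    fg: ForegroundResult,
    cfg: PipelineConfig,
    ffo_seed: int,
) -> tuple[np.ndarray, np.ndarray, list]:
    """Segment one preprocessed slice and return (features, patches, rois)."""
    ffo = replace(cfg.ffo, seed=ffo_seed)
    segs = segment_image(fg, ffo)
    rois = extract_rois(segs, fg, cfg.roi)
    feats, patches = [], []
    for roi in rois:
        patch = crop_and_resize(roi, fg, cfg.roi.patch_size)
        feats.append(extract_lbp_features(patch, cfg.lbp))
        patches.append(patch)
    return np.stack(feats), np.stack(patches), rois


def featurize_dataset(cfg: PipelineConfig) -> tuple[list[SliceSample], list[dict]]:
    """Generate phantoms and run preprocess -> segment -> ROI -> LBP for each.

    Returns the classifier-ready slice samples plus one ROI-table row per
    extracted region.  This is the shared front half of the pipeline; the
    classifier stage (and its ablations) can be run on the result without
    repeating the segmentation work.
    """
    log.info("generating %d phantom slices", cfg.n_slices)
    try:
        template = PhantomSpec(
            image_height=cfg.image_size,
            image_width=cfg.image_size,
            tumor_radius=cfg.tumor_radius,
            noise_sd=cfg.noise_sd,
            band_intensities=cfg.band_intensities,
        )
        dataset = generate_dataset(
            cfg.n_slices, cfg.class_balance, template, seed=cfg.stage_seed("phantom")
        )
    except (ValueError, TypeError) as exc:
        raise PipelineError("phantom", str(exc)) from exc

    slices: list[SliceSample] = []
    roi_rows: list[dict] = []
    seg_seed = cfg.stage_seed("ffo")
    for i, sample in enumerate(dataset):
        try:
            fg = preprocess_slice(
                sample.image, tau=cfg.tau,
                out_shape=(cfg.resize_to, cfg.resize_to), equalize=cfg.equalize,
            )
        except ValueError as exc:
            raise PipelineError("preprocess", f"slice {i}: {exc}") from exc
        try:
            feats, patches, rois = featurize_slice(fg, cfg, seg_seed + i)
        except ValueError as exc:
            raise PipelineError("segment", f"slice {i}: {exc}") from exc
        label = 1 if sample.class_label == "HGG" else 0
        slices.append(SliceSample(features=feats, patches=patches, label=label))
        for roi in rois:
            roi_rows.append(
                {"slice": i, "label": sample.class_label, "r0": roi.bbox[0],
                 "r1": roi.bbox[1], "c0": roi.bbox[2], "c1": roi.bbox[3],
                 "area": roi.area, "mean_intensity": roi.mean_intensity,
                 "segment_id": roi.source_segment_id}
            )
        if (i + 1) % 25 == 0:
            log.info("featurized %d/%d slices", i + 1, cfg.n_slices)
    return slices, roi_rows


def run_pipeline(cfg: PipelineConfig, outdir: str | Path | None = None) -> MetricsReport:
    """Execute the full study and return the cross-validated MetricsReport."""
    slices, roi_rows = featurize_dataset(cfg)
    log.info("running %d-fold cross-validation (%s mode)", cfg.folds, cfg.train.mode)
    try:
        train_cfg = replace(cfg.train, seed=cfg.stage_seed("train"))
        report = cross_validate(slices, folds=cfg.folds, train_cfg=train_cfg,
                                seed=cfg.stage_seed("cv"))
    except ValueError as exc:
        raise PipelineError("evaluate", str(exc)) from exc

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(roi_rows).to_csv(outdir / "rois.csv", index=False)
        gio.write_json(outdir / "metrics.json", report.as_dict())
        pd.DataFrame(report.per_fold).to_csv(outdir / "per_fold_metrics.csv", index=False)
        gio.write_json(outdir / "run_config.json", {"seed": cfg.seed, "n_slices": cfg.n_slices,
                                                    "folds": cfg.folds, "mode": cfg.train.mode})
    return report
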