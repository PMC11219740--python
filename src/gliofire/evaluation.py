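"""Confusion-matrix metrics, ROC/AUC, and stratified cross-validation.

HGG is the positive class, LGG the negative class.  The metric suite
reports accuracy (percent), precision, recall, F-measure, the Matthews
correlation coefficient and the critical success index; degenerate
denominators yield 0 with a warning.  Cross-validation is stratified at
the slice level — every ROI of a slice stays in the same fold and
inherits the slice label — and reports per-fold metrics, their mean,
and metrics pooled over all test predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .classifier import PCNN, TrainConfig, predict_proba, train_parallel

__all__ = [
    "ConfusionCounts", "MetricsReport", "SliceSample",
    "confusion", "metric_suite", "roc_auc", "cross_validate",
]

METRIC_NAMES = ("accuracy", "precision", "recall", "f_measure", "mcc", "csi")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(labels: np.ndarray, predictions: np.ndarray) -> ConfusionCounts:
    """Counts with label 1 = HGG (positive), 0 = LGG (negative)."""
    labels = np.asarray(labels, dtype=np.int64)
    predictions = np.asarray(predictions, dtype=np.int64)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    return ConfusionCounts(
        tp=int(np.sum((labels == 1) & (predictions == 1))),
        tn=int(np.sum((labels == 0) & (predictions == 0))),
        fp=int(np.sum((labels == 0) & (predictions == 1))),
        fn=int(np.sum((labels == 1) & (predictions == 0))),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"degenerate denominator in {name}; reporting 0", stacklevel=3)
        return 0.0
    return num / den


def metric_suite(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy (%), precision, recall, F-measure, MCC and CSI."""
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    f_measure = _safe_div(2.0 * precision * recall, precision + recall, "f_measure")
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, "mcc")
    return {
        "accuracy": _safe_div(tp + tn, c.total, "accuracy") * 100.0,
        "precision": precision,
        "recall": recall,
        "f_measure": f_measure,
        "mcc": float(mcc),
        "csi": _safe_div(tp, tp + fp + fn, "csi"),
    }


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve for positive-class scores."""
    labels = np.asarray(labels, dtype=np.int64)
    if np.unique(labels).size < 2:
        raise ValueError("ROC AUC requires both classes to be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class SliceSample:
    """Classifier-ready representation of one slice: its ROI feature/patch
    pairs and the slice label (1 = HGG)."""

    features: np.ndarray  # (n_roi, F)
    patches: np.ndarray   # (n_roi, H, W)
    label: int


@dataclass
class MetricsReport:
    per_fold: list[dict[str, float]] = field(default_factory=list)
    mean: dict[str, float] = field(default_factory=dict)
    pooled: dict[str, float] = field(default_factory=dict)
    auc: float = float("nan")

    def as_dict(self) -> dict:
        return {"per_fold": self.per_fold, "mean": self.mean,
                "pooled": self.pooled, "auc": self.auc}


def _slice_probs(model: PCNN, s: SliceSample) -> np.ndarray:
    return predict_proba(model, s.features, s.patches).mean(axis=0)


def cross_validate(
    slices: list[SliceSample],
    folds: int = 10,
    train_cfg: TrainConfig | None = None,
    seed: int = 0,
) -> MetricsReport:
    """Stratified k-fold cross-validation at the slice level."""
    if train_cfg is None:
        train_cfg = TrainConfig()
    labels = np.array([s.label for s in slices], dtype=np.int64)
    counts = np.bincount(labels, minlength=2)
    if counts.min() < folds:
        raise ValueError("each class needs at least `folds` slices")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    report = MetricsReport()
    all_true, all_pred, all_scores = [], [], []
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(slices)), labels)):
        x1 = np.concatenate([slices[i].features for i in train_idx])
        x2 = np.concatenate([slices[i].patches for i in train_idx])
        y = np.concatenate(
            [np.full(len(slices[i].features), slices[i].label) for i in train_idx]
        )
        fold_cfg = replace(train_cfg, seed=train_cfg.seed + fold)
        model, _ = train_parallel(x1, x2, y, fold_cfg)
        true = labels[test_idx]
        probs = np.stack([_slice_probs(model, slices[i]) for i in test_idx])
        pred = probs.argmax(axis=1)
        report.per_fold.append(metric_suite(confusion(true, pred)))
        all_true.append(true)
        all_pred.append(pred)
        all_scores.append(probs[:, 1])
    report.mean = {
        k: float(np.mean([f[k] for f in report.per_fold])) for k in METRIC_NAMES
    }
    true = np.concatenate(all_true)
    report.pooled = metric_suite(confusion(true, np.concatenate(all_pred)))
    report.auc = roc_auc(np.concatenate(all_scores), true)
    return report
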