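"""Parallel 1D + 2D CNN glioma-grade classifier with late fusion.

Two branches are trained jointly.  The 1D branch consumes the uniform-
LBP feature vector through three sigmoid convolution blocks
(kernel/filters 8/16, 5/24, 3/30, each followed by stride-2 max
pooling) and two fully connected layers of 100 and 2 units.  The 2D
branch consumes the gray ROI patch through three ReLU convolution
blocks (7x7/6, 5x5/18, 3x3/20 with 2x2 max pooling) and the same FC
head.  The two 2-unit FC outputs are concatenated into a 4-vector and a
trainable 4 -> 2 linear map plus softmax produces the class
probabilities (HGG is the positive class).  Single-branch ablations
reuse the same architecture with softmax applied directly to that
branch's FC2 output.

Training uses Adam (lr0 = 0.005, beta1 = 0.9, beta2 = 0.999,
eps = 1e-8), batch size 32, L2 weight decay 1e-4, global L2 gradient
clipping at 1.0, and an exponential schedule that multiplies the
learning rate by 0.9 after every epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    Adam,
    Center,
    Conv1d,
    Conv2d,
    Dense,
    Flatten,
    MaxPool1d,
    MaxPool2d,
    ReLU,
    Sequential,
    Sigmoid,
    softmax,
    softmax_cross_entropy,
)

__all__ = [
    "TrainConfig", "PCNN", "build_branch_1d", "build_branch_2d",
    "train_parallel", "predict_proba", "predict_slice", "count_parameters",
]

BLOCKS_1D = ((8, 16), (5, 24), (3, 30))
BLOCKS_2D = ((7, 6), (5, 18), (3, 20))


@dataclass(frozen=True)
class TrainConfig:
    lr0: float = 0.005
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    batch_size: int = 32
    epochs: int = 100
    weight_decay: float = 1e-4
    lr_decay: float = 0.9          # multiplicative, applied after each epoch
    grad_clip: float = 1.0
    mode: str = "fused"            # "fused" | "1d" | "2d"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("fused", "1d", "2d"):
            raise ValueError("mode must be 'fused', '1d' or '2d'")
        for name in ("lr0", "batch_size", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def build_branch_1d(input_length: int, rng: np.random.Generator) -> Sequential:
    """Three sigmoid conv blocks + FC(100) + FC(2) on a length-F vector."""
    if input_length < 64:
        raise ValueError("1D input length must be >= 64 to survive three poolings")
    layers: list = []
    c_in = 1
    length = input_length
    # two numerical choices keep the deep logistic stack trainable:
    # init gain 4 (inverse of the logistic slope at 0) preserves signal
    # variance, and a fixed -0.5 centering after each block hands the next
    # layer zero-mean activations (absorbable into its bias, so the
    # function class is untouched)
    for k, f in BLOCKS_1D:
        layers += [Conv1d(c_in, f, k, rng, gain=4.0), Sigmoid(), MaxPool1d(), Center()]
        c_in = f
        length //= 2
    layers += [Flatten(), Dense(length * c_in, 100, rng), Dense(100, 2, rng)]
    return Sequential(layers)


def build_branch_2d(patch_size: int, rng: np.random.Generator) -> Sequential:
    """Three ReLU conv blocks + FC(100) + FC(2) on a square gray patch."""
    if patch_size < 8:
        raise ValueError("2D input must be at least 8x8")
    layers: list = []
    c_in = 1
    size = patch_size
    for k, f in BLOCKS_2D:
        layers += [Conv2d(c_in, f, k, rng), ReLU(), MaxPool2d()]
        c_in = f
        size //= 2
    layers += [Flatten(), Dense(size * size * c_in, 100, rng), ReLU(), Dense(100, 2, rng)]
    return Sequential(layers)


class PCNN:
    """Two-branch parallel CNN with a trainable 4 -> 2 fusion head."""

    def __init__(self, input_length: int = 1888, patch_size: int = 200,
                 mode: str = "fused", seed: int = 0):
        if mode not in ("fused", "1d", "2d"):
            raise ValueError("mode must be 'fused', '1d' or '2d'")
        self.mode = mode
        self.input_length = input_length
        self.patch_size = patch_size
        rng = np.random.default_rng(seed)
        self.branch1d = build_branch_1d(input_length, rng) if mode != "2d" else None
        self.branch2d = build_branch_2d(patch_size, rng) if mode != "1d" else None
        self.fusion = Dense(4, 2, rng) if mode == "fused" else None

    def params(self):
        out = []
        for part in (self.branch1d, self.branch2d, self.fusion):
            if part is not None:
                out += part.params()
        return out

    def forward(self, x1d: np.ndarray | None, x2d: np.ndarray | None) -> np.ndarray:
        if self.mode == "1d":
            return self.branch1d.forward(x1d[:, None, :].astype(np.float32))
        if self.mode == "2d":
            return self.branch2d.forward(x2d.astype(np.float32))
        o1 = self.branch1d.forward(x1d[:, None, :].astype(np.float32))
        o2 = self.branch2d.forward(x2d.astype(np.float32))
        self._cat = np.concatenate([o1, o2], axis=1)
        return self.fusion.forward(self._cat)

    def backward(self, dlogits: np.ndarray) -> None:
        if self.mode == "1d":
            self.branch1d.backward(dlogits)
            return
        if self.mode == "2d":
            self.branch2d.backward(dlogits)
            return
        dcat = self.fusion.backward(dlogits)
        self.branch1d.backward(dcat[:, :2])
        self.branch2d.backward(dcat[:, 2:])


def count_parameters(model: PCNN | Sequential) -> int:
    """Total learnable scalars (weights and biases)."""
    return int(sum(p.value.size for p in model.params()))


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    accuracy: list[float] = field(default_factory=list)


def train_parallel(
    features: np.ndarray,
    patches: np.ndarray,
    labels: np.ndarray,
    cfg: TrainConfig,
) -> tuple[PCNN, TrainHistory]:
    """Joint end-to-end training of the parallel model.

    ``features`` is (n, F) LBP vectors, ``patches`` is (n, H, W) gray
    patches, ``labels`` is (n,) int with 1 = HGG.  Deterministic for a
    fixed ``cfg.seed``.
    """
    labels = np.asarray(labels, dtype=np.int64)
    if np.unique(labels).size < 2:
        raise ValueError("training requires samples from both classes")
    n = labels.size
    x1 = np.asarray(features, dtype=np.float32)
    x2 = np.asarray(patches, dtype=np.float32)[:, None, :, :]
    model = PCNN(
        input_length=x1.shape[1], patch_size=x2.shape[2], mode=cfg.mode, seed=cfg.seed
    )
    opt = Adam(
        model.params(), lr=cfg.lr0, beta1=cfg.beta1, beta2=cfg.beta2,
        eps=cfg.epsilon, weight_decay=cfg.weight_decay, grad_clip=cfg.grad_clip,
    )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xC1A55]).generate_state(1)[0])
    history = TrainHistory()
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model.forward(x1[idx], x2[idx])
            loss, dlogits = softmax_cross_entropy(logits, labels[idx])
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == labels[idx]).sum())
        history.loss.append(float(np.mean(losses)))
        history.lr.append(opt.lr)
        history.accuracy.append(correct / n)
        opt.lr *= cfg.lr_decay
    return model, history


def predict_proba(model: PCNN, features: np.ndarray | None, patches: np.ndarray | None,
                  batch_size: int = 64) -> np.ndarray:
    """Class probabilities (n, 2), column 1 = HGG."""
    if features is not None:
        n = len(features)
        features = np.asarray(features, dtype=np.float32)
    else:
        n = len(patches)
    if patches is not None:
        patches = np.asarray(patches, dtype=np.float32)
        if patches.ndim == 3:
            patches = patches[:, None, :, :]
    out = []
    for start in range(0, n, batch_size):
        f = features[start : start + batch_size] if features is not None else None
        p = patches[start : start + batch_size] if patches is not None else None
        out.append(softmax(model.forward(f, p)))
    return np.concatenate(out, axis=0)


def predict_slice(model: PCNN, rois: list[tuple[np.ndarray, np.ndarray]]) -> tuple[int, float]:
    """Slice-level decision: softmax averaged over the slice's ROIs.

    Returns (label, probability of that label); label 1 = HGG.
    """
    if not rois:
        raise ValueError("at least one ROI is required")
    feats = np.stack([f for f, _ in rois])
    patches = np.stack([p for _, p in rois])
    probs = predict_proba(model, feats, patches).mean(axis=0)
    label = int(np.argmax(probs))
    return label, float(probs[label])
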