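"""Minimal CNN engine: layers, softmax cross-entropy, and Adam.

Implements exactly the pieces the parallel classifier needs — 1D/2D
'same'-padded convolutions (im2col), stride-2 max pooling, dense layers,
sigmoid/ReLU, softmax cross-entropy, and Adam with L2 weight decay,
global gradient-norm clipping and per-epoch exponential learning-rate
decay.  All computation is float32 numpy; initialization and batching
are driven by a seeded Generator, so training is bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Layer", "Dense", "Conv1d", "Conv2d", "MaxPool1d", "MaxPool2d",
    "Sigmoid", "ReLU", "Center", "Flatten", "Sequential", "Adam",
    "softmax", "softmax_cross_entropy",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int,
            gain: float = 1.0) -> np.ndarray:
    # gain compensates the activation's derivative at 0 (logistic sigmoid
    # squashes by 1/4, so sigmoid-fed layers use gain 4 to keep signal
    # variance from collapsing through deep stacks)
    limit = gain * np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, shape).astype(np.float32)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, gain: float = 1.0):
        self.W = Param(_glorot(rng, (n_in, n_out), n_in, n_out, gain))
        self.b = Param(np.zeros(n_out, dtype=np.float32))

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class Sigmoid(Layer):
    def forward(self, x):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class ReLU(Layer):
    def forward(self, x):
        self._m = x > 0
        return x * self._m

    def backward(self, dout):
        return dout * self._m


class Center(Layer):
    """Subtract a fixed offset (default: the logistic midpoint 0.5).

    Placed after sigmoid blocks so downstream layers see zero-mean
    activations.  The offset is absorbable into the next layer's bias,
    so the representable function class is unchanged; it exists purely
    to condition the optimization (centered activations avoid the
    strongly coupled gradient directions a constant-mean input causes).
    """

    def __init__(self, offset: float = 0.5):
        self.offset = np.float32(offset)

    def forward(self, x):
        return x - self.offset

    def backward(self, dout):
        return dout


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Conv1d(Layer):
    """'Same'-padded 1D convolution over (N, C, L) input, stride 1."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 gain: float = 1.0):
        self.k = k
        self.c_in, self.c_out = c_in, c_out
        self.W = Param(_glorot(rng, (c_out, c_in * k), c_in * k, c_out, gain))
        self.b = Param(np.zeros(c_out, dtype=np.float32))
        self.pad = ((k - 1) // 2, k // 2)

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        n, c, L = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), self.pad))
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)  # (N,C,L,k)
        self._cols = cols.transpose(0, 2, 1, 3).reshape(n * L, c * self.k)
        self._dims = (n, c, L)
        out = self._cols @ self.W.value.T + self.b.value
        return out.reshape(n, L, self.c_out).transpose(0, 2, 1)

    def backward(self, dout):
        n, c, L = self._dims
        dmat = dout.transpose(0, 2, 1).reshape(n * L, self.c_out)
        self.W.grad += dmat.T @ self._cols
        self.b.grad += dmat.sum(axis=0)
        dcols = (dmat @ self.W.value).reshape(n, L, c, self.k)
        dxp = np.zeros((n, c, L + sum(self.pad)), dtype=np.float32)
        for t in range(self.k):
            dxp[:, :, t : t + L] += dcols[:, :, :, t].transpose(0, 2, 1)
        return dxp[:, :, self.pad[0] : self.pad[0] + L]


class Conv2d(Layer):
    """'Same'-padded square 2D convolution over (N, C, H, W), stride 1."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.k = k
        self.c_in, self.c_out = c_in, c_out
        self.W = Param(_glorot(rng, (c_out, c_in * k * k), c_in * k * k, c_out))
        self.b = Param(np.zeros(c_out, dtype=np.float32))
        self.pad = ((k - 1) // 2, k // 2)

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        n, c, h, w = x.shape
        p0, p1 = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p0, p1), (p0, p1)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        self._cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * self.k * self.k)
        self._dims = (n, c, h, w)
        out = self._cols @ self.W.value.T + self.b.value
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout):
        n, c, h, w = self._dims
        p0, _ = self.pad
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.W.grad += dmat.T @ self._cols
        self.b.grad += dmat.sum(axis=0)
        dcols = (dmat @ self.W.value).reshape(n, h, w, c, self.k, self.k)
        dxp = np.zeros((n, c, h + sum(self.pad), w + sum(self.pad)), dtype=np.float32)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p0 : p0 + h, p0 : p0 + w]


class MaxPool1d(Layer):
    """Stride-2 max pooling; a trailing odd element is dropped."""

    def forward(self, x):
        n, c, L = x.shape
        Lo = L // 2
        self._L = L
        xr = x[:, :, : 2 * Lo].reshape(n, c, Lo, 2)
        self._idx = xr.argmax(axis=3)
        return np.take_along_axis(xr, self._idx[..., None], axis=3)[..., 0]

    def backward(self, dout):
        n, c, Lo = dout.shape
        dxr = np.zeros((n, c, Lo, 2), dtype=np.float32)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=3)
        dx = np.zeros((n, c, self._L), dtype=np.float32)
        dx[:, :, : 2 * Lo] = dxr.reshape(n, c, 2 * Lo)
        return dx


class MaxPool2d(Layer):
    """2x2 stride-2 max pooling; trailing odd rows/cols are dropped."""

    def forward(self, x):
        n, c, h, w = x.shape
        ho, wo = h // 2, w // 2
        self._hw = (h, w)
        xr = x[:, :, : 2 * ho, : 2 * wo].reshape(n, c, ho, 2, wo, 2)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, 4)
        self._idx = xr.argmax(axis=4)
        return np.take_along_axis(xr, self._idx[..., None], axis=4)[..., 0]

    def backward(self, dout):
        n, c, ho, wo = dout.shape
        h, w = self._hw
        dxr = np.zeros((n, c, ho, wo, 4), dtype=np.float32)
        np.put_along_axis(dxr, self._idx[..., None], dout[..., None], axis=4)
        dxr = dxr.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dx = np.zeros((n, c, h, w), dtype=np.float32)
        dx[:, :, : 2 * ho, : 2 * wo] = dxr.reshape(n, c, 2 * ho, 2 * wo)
        return dx


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and the gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, (dlogits / n).astype(np.float32)


class Adam:
    """Adam with coupled L2 weight decay and global-norm gradient clipping."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 0.005,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 1e-4,
        grad_clip: float = 1.0,
    ):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.grad_clip = grad_clip
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        grads = [p.grad + self.weight_decay * p.value for p in self.params]
        if self.grad_clip is not None:
            total = float(np.sqrt(sum(float((g.astype(np.float64) ** 2).sum()) for g in grads)))
            if total > self.grad_clip:
                scale = np.float32(self.grad_clip / (total + 1e-12))
                grads = [g * scale for g in grads]
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.beta1 * m + (1.0 - self.beta1) * g
            v[...] = self.beta2 * v + (1.0 - self.beta2) * g * g
            p.value -= np.float32(self.lr) * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
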