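"""Minimal numpy neural-network layers with reverse-mode gradients.

Implements exactly the pieces the encoder-decoder segmenter needs:
same-padded convolution (im2col), ReLU, 2x2 max-pool, 2x2 stride-2
transposed convolution, dropout, a masked sparse-categorical cross-entropy
head, and the Adam optimizer.  Layers cache their forward activations and
release them on the backward pass; arrays are float32 NCHW.

This is deliberately a small, fully deterministic engine: given a seed the
same inputs produce bit-identical weights and predictions on rerun.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Conv2d",
    "ConvTranspose2x2",
    "ReLU",
    "MaxPool2",
    "Dropout",
    "Adam",
    "masked_cross_entropy",
    "softmax",
]

DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Conv2d:
    """k x k same-padded convolution, He-initialized."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k * k
        self.k = k
        self.cin, self.cout = cin, cout
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, cin * k * k)))
        self.b = Param(np.zeros(cout))
        self._cols = None
        self._shape = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.k, self.k // 2
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x
        sw = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = np.ascontiguousarray(sw.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * k * k
        )
        out = cols @ self.w.value.T + self.b.value
        self._cols, self._shape = cols, (n, c, h, w)
        return out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        k, p = self.k, self.k // 2
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.cout)
        self.w.grad += dflat.T @ self._cols
        self.b.grad += dflat.sum(axis=0)
        dcols = (dflat @ self.w.value).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=DTYPE)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        self._cols = None
        return dxp[:, :, p : p + h, p : p + w] if p else dxp


class ConvTranspose2x2:
    """2x2 stride-2 transposed convolution (exact 2x upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.cin, self.cout = cin, cout
        self.w = Param(rng.normal(0.0, np.sqrt(2.0 / cin), (cin, cout, 2, 2)))
        self.b = Param(np.zeros(cout))
        self._x = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        out6 = np.einsum("ncij,cdab->ndiajb", x, self.w.value, optimize=True)
        out = out6.reshape(n, self.cout, 2 * h, 2 * w) + self.b.value[None, :, None, None]
        self._x = x
        return out.astype(DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x.shape
        d6 = dout.reshape(n, self.cout, h, 2, w, 2)
        self.w.grad += np.einsum("ncij,ndiajb->cdab", self._x, d6, optimize=True)
        self.b.grad += dout.sum(axis=(0, 2, 3))
        dx = np.einsum("ndiajb,cdab->ncij", d6, self.w.value, optimize=True)
        self._x = None
        return dx.astype(DTYPE)


class ReLU:
    params: list = []

    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(DTYPE)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        out = np.where(self._mask, dout, 0.0).astype(DTYPE)
        self._mask = None
        return out


class MaxPool2:
    params: list = []

    def __init__(self):
        self._idx = None
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // 2, w // 2, 4
        )
        self._idx = xr.argmax(axis=-1)
        self._shape = (n, c, h, w)
        return np.take_along_axis(xr, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        d4 = np.zeros((n, c, h // 2, w // 2, 4), dtype=DTYPE)
        np.put_along_axis(d4, self._idx[..., None], dout[..., None], axis=-1)
        dx = d4.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h, w
        )
        self._idx = None
        return dx


class Dropout:
    params: list = []

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(DTYPE) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        out = dout * self._mask
        self._mask = None
        return out


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def masked_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Sparse categorical cross-entropy over labeled pixels only.

    ``logits`` is (N, C, H, W); ``labels`` is (N, H, W) with 0 = unlabeled
    and 1..C = classes.  Returns (loss, accuracy, dlogits); unlabeled
    pixels contribute neither loss nor gradient.
    """
    n, c, h, w = logits.shape
    mask = labels > 0
    m = int(mask.sum())
    if m == 0:
        raise ValueError("no labeled pixels in batch")
    p = softmax(logits.astype(np.float64), axis=1)
    tgt = np.where(mask, labels - 1, 0)
    onehot = np.eye(c)[tgt].transpose(0, 3, 1, 2)
    picked = np.take_along_axis(p, tgt[:, None], axis=1)[:, 0]
    loss = float(-np.log(np.maximum(picked[mask], 1e-12)).mean())
    acc = float((p.argmax(axis=1)[mask] == tgt[mask]).mean())
    dlogits = (p - onehot) * mask[:, None] / m
    return loss, acc, dlogits.astype(DTYPE)


class Adam:
    """Adam with bias correction; one state slot per parameter."""

    def __init__(self, params: list[Param], lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
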