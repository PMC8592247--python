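"""Minimal NumPy neural-network layers with explicit backpropagation.

The dual-stream classifier is small enough (three conv blocks per
stream, ~10^5 parameters) that a hand-rolled, BLAS-backed implementation
trains in seconds-to-minutes on one CPU.  Convolution uses im2col plus a
single matmul; every layer caches what its backward pass needs.  All
randomness is injected through ``numpy.random.Generator`` instances so
runs are exactly reproducible.

Layout convention: activations are ``(N, C, H, W)`` float arrays.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = value
        self.grad = np.zeros_like(value)
        self.name = name


class Layer:
    kind = "layer"

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def describe(self) -> dict:
        return {"kind": self.kind}


class Conv2D(Layer):
    """Same-padded 2-D convolution with square kernels."""

    kind = "conv"

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        std = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.W = Param((rng.standard_normal((c_out, c_in * kernel * kernel)) * std).astype(dtype), "conv.W")
        self.b = Param(np.zeros(c_out, dtype=dtype), "conv.b")
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        n, c, h, w = x.shape
        k = self.kernel
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))      # (n,c,h,w,k,k)
        cols = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(
            n, c * k * k, h * w
        )
        out = np.matmul(self.W.value, cols).reshape(n, self.c_out, h, w)
        out += self.b.value[None, :, None, None]
        self._cache = (cols, (n, c, h, w))
        return out

    def backward(self, grad):
        cols, (n, c, h, w) = self._cache
        k, p = self.kernel, self.kernel // 2
        gm = grad.reshape(n, self.c_out, h * w)
        self.W.grad += np.tensordot(gm, cols, axes=([0, 2], [0, 2]))
        self.b.grad += gm.sum(axis=(0, 2))
        gcols = np.matmul(self.W.value.T, gm).reshape(n, c, k, k, h, w)
        gx = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=grad.dtype)
        for ki in range(k):
            for kj in range(k):
                gx[:, :, ki : ki + h, kj : kj + w] += gcols[:, :, ki, kj]
        return gx[:, :, p : p + h, p : p + w]

    def describe(self):
        return {
            "kind": "conv",
            "kernel": self.kernel,
            "in_channels": self.c_in,
            "out_channels": self.c_out,
            "padding": "same",
        }


class BatchNorm2D(Layer):
    """Per-channel batch normalization with running inference statistics."""

    kind = "batchnorm"

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Param(np.ones(channels, dtype=dtype), "bn.gamma")
        self.beta = Param(np.zeros(channels, dtype=dtype), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self.channels = channels
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train):
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(x.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(x.dtype)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad):
        xhat, inv, train, shape = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.value[None, :, None, None]
        if not train:
            return g * inv[None, :, None, None]
        m = shape[0] * shape[2] * shape[3]
        sum_g = g.sum(axis=(0, 2, 3), keepdims=True)
        sum_gx = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv[None, :, None, None] / m) * (m * g - sum_g - xhat * sum_gx)

    def describe(self):
        return {"kind": "batchnorm", "channels": self.channels}


class ReLU(Layer):
    kind = "relu"

    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    kind = "dropout"

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, train):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask

    def describe(self):
        return {"kind": "dropout", "rate": self.rate}


class MaxPool2(Layer):
    """2x2 max pooling with stride 2 (requires even spatial sides)."""

    kind = "maxpool"

    def forward(self, x, train):
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(n, c, h // 2, w // 2, 4)
        self._idx = r.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(r, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        n, c, h, w = self._shape
        scat = np.zeros((n, c, h // 2, w // 2, 4), dtype=grad.dtype)
        np.put_along_axis(scat, self._idx[..., None], grad[..., None], axis=-1)
        return (
            scat.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )

    def describe(self):
        return {"kind": "maxpool", "size": 2}


class Dense(Layer):
    kind = "dense"

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        std = np.sqrt(2.0 / n_in)
        self.W = Param((rng.standard_normal((n_in, n_out)) * std).astype(dtype), "dense.W")
        self.b = Param(np.zeros(n_out, dtype=dtype), "dense.b")
        self.n_in, self.n_out = n_in, n_out

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T

    def describe(self):
        return {"kind": "dense", "in": self.n_in, "out": self.n_out}


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def squash(s: np.ndarray, axis: int = -1, eps: float = 1e-12):
    """Squashing map v = (|s|^2 / (1 + |s|^2)) * s/|s|.

    Bounds each class-embedding vector's norm below 1 so the 0.5
    decision threshold and the margin-loss margins are meaningful.
    Returns the squashed vectors and a cache for :func:`squash_backward`.
    """
    n2 = np.sum(s * s, axis=axis, keepdims=True)
    n = np.sqrt(n2 + eps)
    coeff = n / (1.0 + n2)
    v = coeff * s
    return v, (s, n, n2, coeff, axis)


def squash_backward(grad_v: np.ndarray, cache) -> np.ndarray:
    """Jacobian-vector product of the squashing map."""
    s, n, n2, coeff, axis = cache
    # d coeff / d n = (1 - n^2) / (1 + n^2)^2
    dcoeff = (1.0 - n2) / (1.0 + n2) ** 2
    dot = np.sum(grad_v * s, axis=axis, keepdims=True)
    return coeff * grad_v + dcoeff * (dot / n) * s
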