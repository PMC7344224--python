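"""Minimal CPU neural-network layer stack (numpy, float32).

Implements exactly the pieces the segmentation network needs — 2D convolution
(im2col + one BLAS matmul per layer), batch normalization, ReLU, 2x2 max
pooling, parameter-free 2x bilinear upsampling, inverted dropout, pixel-wise
softmax cross-entropy, and SGD with momentum. Every layer has a hand-written
backward pass; correctness is established by finite-difference gradient
checks in the test suite.

All forward/backward passes are deterministic given the generator passed to
the stochastic layers.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np


class Layer:
    """Base class: `params` maps name -> array, `grads` name -> gradient."""

    def __init__(self) -> None:
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """Same-padded 2D convolution (cross-correlation), kernel 3x3 or 1x1.

    Hidden convolutions are bias-free (batch norm absorbs the shift); the
    1x1 output head carries a bias.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, bias: bool,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        self.pad = kernel // 2
        fan_in = c_in * kernel * kernel
        std = np.sqrt(2.0 / fan_in)  # He initialization for ReLU stacks
        self.params["W"] = rng.normal(0.0, std, (c_out, c_in, kernel, kernel)).astype(np.float32)
        if bias:
            self.params["b"] = np.zeros(c_out, dtype=np.float32)
        self._cols: Optional[np.ndarray] = None
        self._x_shape: Optional[Tuple[int, ...]] = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        # batch-first layout (N, C*k*k, H*W): built from k*k plain slice
        # copies (no transposes), feeding one batched GEMM per layer.
        n, c, h, w = x.shape
        k, p = self.k, self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = np.empty((n, c, k, k, h, w), dtype=np.float32)
        for ky in range(k):
            for kx in range(k):
                cols[:, :, ky, kx] = x[:, :, ky:ky + h, kx:kx + w]
        return cols.reshape(n, c * k * k, h * w)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        self._x_shape = x.shape
        cols = self._im2col(x)
        self._cols = cols if train else None
        wmat = self.params["W"].reshape(self.c_out, -1)
        out = np.matmul(wmat, cols)  # (N, C_out, H*W)
        if "b" in self.params:
            out += self.params["b"][None, :, None]
        return out.reshape(n, self.c_out, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._x_shape
        k, p = self.k, self.pad
        dmat = dout.reshape(n, self.c_out, h * w)
        dw = np.matmul(dmat, self._cols.transpose(0, 2, 1)).sum(axis=0)
        self.grads["W"] = dw.reshape(self.params["W"].shape)
        if "b" in self.params:
            self.grads["b"] = dmat.sum(axis=(0, 2))
        wmat = self.params["W"].reshape(self.c_out, -1)
        dcols = np.matmul(wmat.T, dmat).reshape(n, c, k, k, h, w)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for ky in range(k):
            for kx in range(k):
                dxp[:, :, ky:ky + h, kx:kx + w] += dcols[:, :, ky, kx]
        self._cols = None
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics for eval mode."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(channels, dtype=np.float32)
        self.params["beta"] = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._xhat, self._inv = xhat, inv
        return self.params["gamma"][None, :, None, None] * xhat \
            + self.params["beta"][None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2, 3))
        self.grads["beta"] = dout.sum(axis=(0, 2, 3))
        g = self.params["gamma"]
        dxhat = dout * g[None, :, None, None]
        dx = (dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True)
              - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)) \
            * inv[None, :, None, None]
        self._xhat = self._inv = None
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dout, 0.0).astype(np.float32)
        self._mask = None
        return dx


class MaxPool2x2(Layer):
    """2x2 max pooling, stride 2; input spatial dims must be even."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        self._arg = flat.argmax(axis=-1)
        self._shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dflat = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(dflat, self._arg[..., None], dout[..., None], axis=-1)
        dx = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._arg = None
        return np.ascontiguousarray(dx.reshape(n, c, h, w))


_UP_CACHE: Dict[int, np.ndarray] = {}


def _up_matrix(n: int) -> np.ndarray:
    """(2n, n) interpolation matrix for 2x bilinear upsampling (half-pixel centres)."""
    if n not in _UP_CACHE:
        a = np.zeros((2 * n, n), dtype=np.float32)
        for i in range(2 * n):
            src = (i + 0.5) / 2.0 - 0.5
            i0 = int(np.floor(src))
            t = src - i0
            i0c = min(max(i0, 0), n - 1)
            i1c = min(max(i0 + 1, 0), n - 1)
            a[i, i0c] += 1.0 - t
            a[i, i1c] += t
        _UP_CACHE[n] = a
    return _UP_CACHE[n]


class BilinearUp2x(Layer):
    """Parameter-free 2x bilinear upsampling (separable fixed matrices)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        self._hw = (h, w)
        ah, aw = _up_matrix(h), _up_matrix(w)
        return np.matmul(ah, x @ aw.T).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        h, w = self._hw
        ah, aw = _up_matrix(h), _up_matrix(w)
        return np.matmul(ah.T, dout @ aw).astype(np.float32)


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng
        self._mask: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape, dtype=np.float32) < keep) / np.float32(keep)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        dx = dout * self._mask
        self._mask = None
        return dx


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: np.ndarray, target: np.ndarray):
    """Mean pixel-wise cross-entropy over a (N, C, H, W) batch of logits.

    Returns ``(loss, dlogits)`` with the gradient already normalized by the
    number of pixels.
    """
    n, c, h, w = logits.shape
    p = softmax(logits)
    idx = target[:, None, :, :]
    picked = np.take_along_axis(p, idx, axis=1)[:, 0]
    loss = float(-np.log(np.maximum(picked, 1e-12)).mean())
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, idx, 1.0, axis=1)
    dlogits = (p - onehot) / np.float32(n * h * w)
    return loss, dlogits.astype(np.float32)


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, layers: List[Layer], lr: float, momentum: float = 0.9) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.momentum = momentum
        self._vel = [{k: np.zeros_like(v) for k, v in l.params.items()}
                     for l in self.layers]

    def step(self) -> None:
        for layer, vel in zip(self.layers, self._vel):
            for name, p in layer.params.items():
                g = layer.grads[name]
                v = vel[name]
                v *= self.momentum
                v -= self.lr * g
                p += v
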