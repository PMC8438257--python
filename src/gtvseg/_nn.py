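"""Minimal NumPy neural-network engine for the U-Net models.

Arrays are ``(batch, channels, *spatial)`` with 2 or 3 spatial dims.  Only
the pieces the encoder–decoder architecture needs are implemented: strided
convolution and transposed convolution (via im2col / col2im), batch
normalization, LeakyReLU/ReLU/sigmoid, dropout and Adam.  Every layer
provides an explicit ``backward``; there is no autodiff.

Convolutions are expressed as one matrix product per layer:
``im2col`` gathers the receptive-field patches into a ``(batch, L, C*K)``
matrix (L = number of output positions, K = kernel volume), and ``col2im``
scatter-adds patches back — the exact adjoint, implemented with a
precomputed flat index map and ``np.bincount``.  Transposed convolution is
the adjoint of convolution, so the same two primitives serve both
directions.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Sequence

import numpy as np

# ----------------------------------------------------------- im2col/col2im


def _out_shape(spatial: tuple[int, ...], k: int, stride: int, pad: int) -> tuple[int, ...]:
    return tuple((s + 2 * pad - k) // stride + 1 for s in spatial)


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N, C, *S) -> (N, L, C*K) patch matrix."""
    nd = x.ndim - 2
    if pad:
        x = np.pad(x, [(0, 0), (0, 0)] + [(pad, pad)] * nd)
    win = np.lib.stride_tricks.sliding_window_view(x, (k,) * nd, axis=tuple(range(2, 2 + nd)))
    # win: (N, C, *valid, *k); subsample valid positions by stride
    sub = win[(slice(None), slice(None)) + (slice(None, None, stride),) * nd]
    n, c = sub.shape[:2]
    out_sp = sub.shape[2 : 2 + nd]
    # -> (N, *out, C, *k) -> (N, L, C*K)
    perm = (0,) + tuple(range(2, 2 + nd)) + (1,) + tuple(range(2 + nd, 2 + 2 * nd))
    return np.ascontiguousarray(sub.transpose(perm)).reshape(n, int(np.prod(out_sp)), c * k**nd)


@lru_cache(maxsize=64)
def _col2im_index(
    c: int, spatial: tuple[int, ...], k: int, stride: int, pad: int
) -> tuple[np.ndarray, tuple[int, ...], int]:
    """Flat index map from patch entries into the padded (C, *S_pad) array."""
    padded = tuple(s + 2 * pad for s in spatial)
    size = c * int(np.prod(padded))
    ref = np.arange(size, dtype=np.int64).reshape((1, c) + padded)
    idx = im2col(ref, k, stride, pad=0)[0]  # already padded
    return idx, padded, size


def col2im(
    patches: np.ndarray, c: int, spatial: tuple[int, ...], k: int, stride: int, pad: int
) -> np.ndarray:
    """Adjoint of :func:`im2col`: (N, L, C*K) -> (N, C, *S), scatter-adding overlaps."""
    idx, padded, size = _col2im_index(c, tuple(spatial), k, stride, pad)
    n = patches.shape[0]
    offsets = (np.arange(n, dtype=np.int64) * size)[:, None, None]
    flat = np.bincount(
        (idx[None] + offsets).ravel(), weights=patches.ravel(), minlength=n * size
    )
    out = flat.reshape((n, c) + padded)
    if pad:
        sl = (slice(None), slice(None)) + (slice(pad, -pad),) * len(spatial)
        out = out[sl]
    return out.astype(patches.dtype, copy=False)


# ----------------------------------------------------------------- layers


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv(Layer):
    """Strided convolution; kernel k, stride s, symmetric zero padding p."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, k, stride, pad
        self._nd: int | None = None
        self._rng = rng
        self.W: np.ndarray | None = None  # lazily shaped (c_out, c_in*K) once nd known
        self.b = np.zeros(c_out, dtype=np.float32)

    def _init(self, nd: int) -> None:
        self._nd = nd
        fan_in = self.c_in * self.k**nd
        std = np.sqrt(2.0 / fan_in)  # He init for (leaky) ReLU inputs
        self.W = (self._rng.normal(0.0, std, size=(self.c_out, fan_in))).astype(np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        nd = x.ndim - 2
        if self.W is None:
            self._init(nd)
        self._in_spatial = x.shape[2:]
        P = im2col(x, self.k, self.stride, self.pad)
        self._P = P
        out_sp = _out_shape(x.shape[2:], self.k, self.stride, self.pad)
        y = P @ self.W.T + self.b
        perm = (0, 1 + nd) + tuple(range(1, 1 + nd))
        return np.ascontiguousarray(
            y.reshape((x.shape[0],) + out_sp + (self.c_out,)).transpose(perm)
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        nd = dy.ndim - 2
        n = dy.shape[0]
        perm = (0,) + tuple(range(2, 2 + nd)) + (1,)
        dy2 = np.ascontiguousarray(dy.transpose(perm)).reshape(n, -1, self.c_out)
        self.grads[0][...] = np.einsum("nlo,nlk->ok", dy2, self._P)
        self.grads[1][...] = dy2.sum(axis=(0, 1))
        dP = dy2 @ self.W
        self._P = None
        return col2im(dP, self.c_in, self._in_spatial, self.k, self.stride, self.pad)


class ConvTranspose(Layer):
    """Stride-s transposed convolution (adjoint of :class:`Conv`).

    With kernel 4 / pad 1 or kernel 2 / pad 0 and stride 2, every spatial
    extent exactly doubles.
    """

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, pad: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, k, stride, pad
        self._rng = rng
        self.W: np.ndarray | None = None  # (c_in, c_out*K)
        self.b = np.zeros(c_out, dtype=np.float32)

    def _init(self, nd: int) -> None:
        fan_in = self.c_in * self.k**nd
        std = np.sqrt(2.0 / fan_in)
        self.W = (self._rng.normal(0.0, std, size=(self.c_in, self.c_out * self.k**nd))).astype(
            np.float32
        )
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def out_spatial(self, in_spatial: Sequence[int]) -> tuple[int, ...]:
        return tuple((s - 1) * self.stride - 2 * self.pad + self.k for s in in_spatial)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        nd = x.ndim - 2
        if self.W is None:
            self._init(nd)
        n = x.shape[0]
        self._in_spatial = x.shape[2:]
        perm = (0,) + tuple(range(2, 2 + nd)) + (1,)
        x2 = np.ascontiguousarray(x.transpose(perm)).reshape(n, -1, self.c_in)
        self._x2 = x2
        P = x2 @ self.W  # (N, L_in, c_out*K)
        out_sp = self.out_spatial(x.shape[2:])
        y = col2im(P, self.c_out, out_sp, self.k, self.stride, self.pad)
        return y + self.b.reshape((1, -1) + (1,) * nd)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        nd = dy.ndim - 2
        n = dy.shape[0]
        dP = im2col(dy, self.k, self.stride, self.pad)  # (N, L_in, c_out*K)
        self.grads[0][...] = np.einsum("nlc,nlk->ck", self._x2, dP)
        self.grads[1][...] = dy.sum(axis=(0,) + tuple(range(2, 2 + nd)))
        dx2 = dP @ self.W.T  # (N, L_in, c_in)
        self._x2 = None
        perm = (0, 1 + nd) + tuple(range(1, 1 + nd))
        return np.ascontiguousarray(
            dx2.reshape((n,) + self._in_spatial + (self.c_in,)).transpose(perm)
        )


class BatchNorm(Layer):
    """Per-channel batch normalization over (batch, *spatial).

    Running statistics (momentum 0.9) are used at inference, so prediction
    is deterministic and batch-size independent.
    """

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.9) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        nd = x.ndim - 2
        axes = (0,) + tuple(range(2, 2 + nd))
        shape = (1, -1) + (1,) * nd
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._axes, self._shape = axes, shape
            self._inv = 1.0 / np.sqrt(var + self.eps)
            self._xhat = (x - mu.reshape(shape)) * self._inv.reshape(shape)
            return self.gamma.reshape(shape) * self._xhat + self.beta.reshape(shape)
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean.reshape(shape)) * inv.reshape(shape)
        return self.gamma.reshape(shape) * xhat + self.beta.reshape(shape)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        axes, shape = self._axes, self._shape
        m = dy.size // dy.shape[1]
        self.grads[0][...] = (dy * self._xhat).sum(axis=axes)
        self.grads[1][...] = dy.sum(axis=axes)
        g = (self.gamma * self._inv).reshape(shape)
        mean_dy = dy.mean(axis=axes).reshape(shape)
        mean_dy_xhat = (dy * self._xhat).mean(axis=axes).reshape(shape)
        dx = g * (dy - mean_dy - self._xhat * mean_dy_xhat)
        self._xhat = None
        return dx


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2) -> None:
        super().__init__()
        self.alpha = alpha

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._neg = x < 0
        return np.where(self._neg, self.alpha * x, x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._neg, self.alpha * dy, dy)


class ReLU(LeakyReLU):
    def __init__(self) -> None:
        super().__init__(alpha=0.0)


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate, self._rng = rate, rng

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self._rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


# -------------------------------------------------------------------- Adam


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ----------------------------------------------------------- dice loss


def soft_dice_loss_and_grad(
    pred: np.ndarray, target: np.ndarray, eps: float = 1.0
) -> tuple[float, np.ndarray]:
    """Per-sample soft Dice loss 1 - (2Σpt + ε)/(Σp + Σt + ε), averaged over batch.

    Returns the scalar loss and its gradient with respect to ``pred``.
    """
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    n = pred.shape[0]
    axes = tuple(range(1, pred.ndim))
    inter = (pred * target).sum(axis=axes)
    denom = pred.sum(axis=axes) + target.sum(axis=axes) + eps
    num = 2.0 * inter + eps
    loss = float(np.mean(1.0 - num / denom))
    shape = (n,) + (1,) * (pred.ndim - 1)
    grad = -(2.0 * target * denom.reshape(shape) - num.reshape(shape)) / (
        denom.reshape(shape) ** 2
    )
    return loss, grad / n
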