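"""Minimal CPU layer zoo for image-to-image regression.

Internals use channels-last float32 arrays (batch, height, width, channel):
with that layout the im2col patch matrix gathers contiguous ``k * C`` spans,
so the whole convolution reduces to one cache-friendly copy plus one BLAS
GEMM, forward and backward.  Only what the slice-wise parametric-map
estimator needs: 3x3/1x1 'same' convolutions, ReLU, 2x2 max-pooling and
nearest x2 upsampling, each with an explicit backward pass.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "GroupNorm", "ReLU", "MaxPool2", "UpsampleNearest2"]


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(B,H,W,C) -> (B, H, W, k*k*C) patch matrix for stride-1 'same' conv."""
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    win = sliding_window_view(x, (k, k), axis=(1, 2))  # (B,H',W',C,k,k)
    b, h, w, c = win.shape[:4]
    # (kh, kw, C) flatten order: (kw, C) spans are contiguous in memory
    return win.transpose(0, 1, 2, 4, 5, 3).reshape(b, h, w, k * k * c)


class Conv2d:
    """Stride-1 'same' convolution (k in {1, 3}) with bias, He-initialized.

    Weights are stored as (k, k, C_in, C_out) to match the im2col order.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        self.w = (rng.standard_normal((k, k, c_in, c_out))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k, self.pad = k, k // 2
        self.c_in, self.c_out = c_in, c_out
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        cols = x if self.k == 1 else _im2col(x, self.k, self.pad)
        if train:
            self._cols = cols
        out = cols @ self.w.reshape(-1, self.c_out)
        out += self.b
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g2 = gout.reshape(-1, self.c_out)
        cols2 = self._cols.reshape(-1, self._cols.shape[-1])
        self.gw += (cols2.T @ g2).reshape(self.w.shape)
        self.gb += g2.sum(axis=0)
        self._cols = None
        if self.k == 1:
            return (g2 @ self.w.reshape(-1, self.c_out).T).reshape(
                gout.shape[:-1] + (self.c_in,))
        # dx = 'same' conv of gout with the 180-degree-rotated, transposed kernel
        wrot = self.w[::-1, ::-1].transpose(0, 1, 3, 2)  # (k,k,C_out,C_in)
        gcols = _im2col(gout, self.k, self.pad)
        return gcols @ wrot.reshape(-1, self.c_in)

    def params(self):
        return [(self.w, self.gw), (self.b, self.gb)]


class GroupNorm:
    """Group normalization over (H, W, C/G) per sample, learnable affine.

    Batch-size independent, so training on crops and inferring on full
    slices see identical statistics semantics.
    """

    def __init__(self, c: int, groups: int = 8, eps: float = 1e-5):
        if c % groups:
            raise ValueError("channel count must be divisible by the group count")
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.g, self.eps = groups, eps
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)

    def _grouped(self, x):
        b, h, w, c = x.shape
        return x.reshape(b, h, w, self.g, c // self.g)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        xg = self._grouped(x)
        mu = xg.mean(axis=(1, 2, 4), keepdims=True)
        var = xg.var(axis=(1, 2, 4), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = ((xg - mu) * inv).reshape(x.shape)
        if train:
            self._xhat, self._inv = xhat, inv
        return xhat * self.gamma + self.beta

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat = self._xhat
        self.ggamma += (gout * xhat).sum(axis=(0, 1, 2))
        self.gbeta += gout.sum(axis=(0, 1, 2))
        dxhat = self._grouped(gout * self.gamma)
        xh = self._grouped(xhat)
        m1 = dxhat.mean(axis=(1, 2, 4), keepdims=True)
        m2 = (dxhat * xh).mean(axis=(1, 2, 4), keepdims=True)
        dx = (dxhat - m1 - xh * m2) * self._inv
        self._xhat = None
        return dx.reshape(gout.shape)

    def params(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]


class ReLU:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return gout * self._mask

    def params(self):
        return []


class MaxPool2:
    """2x2 max pooling, stride 2; ties resolve to the first maximum."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, h, w, c = x.shape
        xb = x.reshape(b, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        xb = xb.reshape(b, h // 2, w // 2, 4, c)
        idx = xb.argmax(axis=3)
        out = np.take_along_axis(xb, idx[:, :, :, None], axis=3)[:, :, :, 0]
        if train:
            self._idx, self._inshape = idx, x.shape
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        b, h, w, c = self._inshape
        g = np.zeros((b, h // 2, w // 2, 4, c), dtype=gout.dtype)
        np.put_along_axis(g, self._idx[:, :, :, None], gout[:, :, :, None], axis=3)
        g = g.reshape(b, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return g.reshape(b, h, w, c)

    def params(self):
        return []


class UpsampleNearest2:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        b, h, w, c = gout.shape
        return gout.reshape(b, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))

    def params(self):
        return []
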