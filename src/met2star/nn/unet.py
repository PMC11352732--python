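"""4-level U-net for slice-to-parametric-map regression.

Encoder-decoder with skip connections at every resolution level: two 3x3
conv+ReLU blocks per level, 2x2 max-pool downsampling (3 pools), nearest x2
upsampling followed by a channel-halving 3x3 conv, skip concatenation, and a
final 1x1 projection to the output channels.  Channel width doubles per
level from ``base_width``.  Fully convolutional: any input whose sides are
multiples of 8 works, so training on random 32x32 crops and inferring on
full 64x64 slices use the same weights.
"""

from __future__ import annotations

import numpy as np

from .layers import Conv2d, MaxPool2, ReLU, UpsampleNearest2

__all__ = ["UNet"]

N_LEVELS = 4


class _Block:
    """conv3-relu, twice.

    No normalization layers: the slice-to-parametric-map regression needs the
    absolute signal scale preserved end to end (the M0 output is calibrated
    to the input intensity), and feature normalization measurably degrades
    the fit here.
    """

    def __init__(self, c_in: int, c_out: int, rng):
        self.layers = [Conv2d(c_in, c_out, 3, rng), ReLU(),
                       Conv2d(c_out, c_out, 3, rng), ReLU()]

    def forward(self, x, train=True):
        for lay in self.layers:
            x = lay.forward(x, train)
        return x

    def backward(self, g):
        for lay in reversed(self.layers):
            g = lay.backward(g)
        return g

    def params(self):
        return [p for lay in self.layers for p in lay.params()]


class UNet:
    def __init__(self, n_in: int, n_out: int, base_width: int = 32, seed: int = 0):
        rng = np.random.default_rng(seed)
        widths = [base_width * 2**l for l in range(N_LEVELS)]
        self.enc = []
        c = n_in
        for wdt in widths:
            self.enc.append(_Block(c, wdt, rng))
            c = wdt
        self.pools = [MaxPool2() for _ in range(N_LEVELS - 1)]
        self.ups = [UpsampleNearest2() for _ in range(N_LEVELS - 1)]
        # channel-halving conv after upsampling, then a block on the concat
        self.upconvs = [Conv2d(widths[l + 1], widths[l], 3, rng)
                        for l in range(N_LEVELS - 2, -1, -1)]
        self.dec = [_Block(2 * widths[l], widths[l], rng)
                    for l in range(N_LEVELS - 2, -1, -1)]
        self.head = Conv2d(widths[0], n_out, 1, rng)
        self.n_in, self.n_out, self.base_width = n_in, n_out, base_width

    # ---- forward / backward -------------------------------------------------
    # Public interface is channels-first (B, C, H, W); internals run
    # channels-last for GEMM efficiency.
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.ascontiguousarray(np.asarray(x, dtype=np.float32).transpose(0, 2, 3, 1))
        skips = []
        for l in range(N_LEVELS - 1):
            x = self.enc[l].forward(x, train)
            skips.append(x)
            x = self.pools[l].forward(x, train)
        x = self.enc[-1].forward(x, train)
        self._skip_channels = [s.shape[-1] for s in skips]
        for i in range(N_LEVELS - 1):
            x = self.ups[i].forward(x, train)
            x = self.upconvs[i].forward(x, train)
            skip = skips[-(i + 1)]
            x = np.concatenate([skip, x], axis=-1)
            x = self.dec[i].forward(x, train)
        out = self.head.forward(x, train)
        return out.transpose(0, 3, 1, 2)

    def backward(self, gout: np.ndarray) -> None:
        g = np.ascontiguousarray(
            np.asarray(gout, dtype=np.float32).transpose(0, 2, 3, 1))
        g = self.head.backward(g)
        gskips = []
        for i in range(N_LEVELS - 2, -1, -1):
            g = self.dec[i].backward(g)
            c_skip = self._skip_channels[-(i + 1)]
            gskips.append(g[..., :c_skip])
            g = self.upconvs[i].backward(np.ascontiguousarray(g[..., c_skip:]))
            g = self.ups[i].backward(g)
        g = self.enc[-1].backward(g)
        for l in range(N_LEVELS - 2, -1, -1):
            g = self.pools[l].backward(g)
            g = g + gskips[l]
            g = self.enc[l].backward(g)

    # ---- parameters ---------------------------------------------------------
    def params(self):
        out = []
        for blk in self.enc + self.dec:
            out += blk.params()
        for conv in self.upconvs:
            out += conv.params()
        out += self.head.params()
        return out

    def zero_grad(self):
        for _, g in self.params():
            g[...] = 0.0

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.params())

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params()]

    def set_weights(self, weights) -> None:
        for (p, _), w in zip(self.params(), weights, strict=True):
            p[...] = w


class Adam:
    """Adam optimizer with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
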