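"""Mono-exponential multi-echo signal model, Rician noise, LLF, echo combination.

The gradient-echo magnitude signal at echo time TE decays mono-exponentially,

    S(TE) = S0 * exp(-TE / T2*) = S0 * exp(-TE * R2*),

with S0 the proton-density-weighted amplitude and R2* = 1/T2*.  Log-linear
fitting (LLF) solves per voxel the linear system

    [log S0, R2*]^T = pinv([[1, -TE_1], ..., [1, -TE_N]]) @ log S

and is exact on noiseless data.  The T2*-weighted echo combination uses

    w_n = TE_n * exp(-TE_n / T2*) / sum_i TE_i * exp(-TE_i / T2*),

which weights each echo by its expected BOLD sensitivity at the voxel's T2*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import ParametricMap

__all__ = [
    "MultiEchoImage",
    "FitResult",
    "EchoWeights",
    "forward_signal",
    "add_rician_noise",
    "loglinear_fit",
    "loglinear_fit_array",
    "echo_combination_weights",
    "combine_echoes",
]

DEFAULT_T2_BOUNDS_MS = (1.0, 500.0)
MAX_SIGMA_FRAC = 0.10


@dataclass(frozen=True)
class MultiEchoImage:
    """Echo-stacked 2D magnitude image: ``data[(echo, row, col)]`` with TE list (ms)."""

    data: np.ndarray
    te_ms: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "te_ms", tuple(float(t) for t in self.te_ms))
        if self.data.ndim != 3 or self.data.shape[0] != len(self.te_ms):
            raise ValueError("data must be (echo, row, col) with one TE per echo")
        if any(t <= 0 for t in self.te_ms):
            raise ValueError("echo times must be positive")
        if any(b <= a for a, b in zip(self.te_ms, self.te_ms[1:])):
            raise ValueError("echo times must be strictly increasing")
        if (self.data < 0).any():
            raise ValueError("magnitude data must be non-negative")

    @property
    def n_echoes(self) -> int:
        return len(self.te_ms)


@dataclass(frozen=True)
class FitResult:
    """Estimated S0 / T2* / R2* maps with a validity mask.

    ``t2star_ms`` is clipped to the fitter's T2* bounds; ``r2star_per_ms`` is
    its reciprocal wherever T2* > 0 and 0 elsewhere.  ``valid`` marks voxels
    where the fit is trustworthy (no floored echo, positive fitted R2*, within
    bounds).  Voxels where every echo sat at the signal floor (background)
    carry the fill value 0 in all channels.
    """

    s0: np.ndarray
    t2star_ms: np.ndarray
    r2star_per_ms: np.ndarray
    valid: np.ndarray


@dataclass(frozen=True)
class EchoWeights:
    """Per-voxel echo-combination weights ``w[(echo, row, col)]`` on the simplex."""

    w: np.ndarray

    def __post_init__(self) -> None:
        if (self.w < 0).any():
            raise ValueError("weights must be non-negative")
        if not np.allclose(self.w.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("weights must sum to 1 per voxel")


def forward_signal(pmap: ParametricMap, te_ms) -> MultiEchoImage:
    """Noiseless mono-exponential signal of a parametric map at the given TEs."""
    te = np.asarray([float(t) for t in te_ms], dtype=float)
    if te.size == 0 or (te <= 0).any():
        raise ValueError("echo times must be positive and non-empty")
    t2 = np.where(pmap.mask, pmap.t2star_ms, np.inf)  # background contributes 0 via m0
    decay = np.exp(-te[:, None, None] / t2[None])
    data = pmap.m0[None] * decay
    data[:, ~pmap.mask] = 0.0
    return MultiEchoImage(data=data, te_ms=tuple(te))


def add_rician_noise(img: MultiEchoImage, sigma_frac: float, seed=None,
                     rng: np.random.Generator | None = None) -> MultiEchoImage:
    """Rician-corrupt magnitude data.

    The complex-noise SD is ``sigma_frac`` times the maximum of the noiseless
    first-echo signal (the largest-amplitude echo), making ``sigma_frac`` a
    per-slice SNR knob: output = |(S + g1) + i g2| with g1, g2 ~ N(0, sigma).
    """
    if not 0.0 <= sigma_frac <= MAX_SIGMA_FRAC:
        raise ValueError(f"sigma_frac must lie in [0, {MAX_SIGMA_FRAC}]")
    if sigma_frac == 0.0:
        return img
    if rng is None:
        rng = np.random.default_rng(seed)
    sigma = sigma_frac * float(img.data[0].max())
    g = rng.standard_normal((2,) + img.data.shape) * sigma
    noisy = np.hypot(img.data + g[0], g[1])
    return MultiEchoImage(data=noisy, te_ms=img.te_ms)


def _design_pinv(te: np.ndarray) -> np.ndarray:
    a = np.column_stack([np.ones_like(te), -te])
    return np.linalg.pinv(a)


def loglinear_fit_array(data: np.ndarray, te_ms, floor: float | None = None,
                        t2_bounds=DEFAULT_T2_BOUNDS_MS):
    """Vectorized LLF over an (echo, ...) array.

    Returns ``(s0, t2star_ms, r2star_per_ms, valid)`` with the leading echo
    axis collapsed.  Signals at or below ``floor`` (default ``1e-6 * max``)
    are replaced by the floor before the log and flagged; non-positive fitted
    R2* clips T2* to the upper bound and is flagged.
    """
    te = np.asarray([float(t) for t in te_ms], dtype=float)
    if te.size < 2:
        raise ValueError("need >= 2 echoes to fit")
    if len(set(te.tolist())) != te.size:
        raise ValueError("duplicate echo times make the design singular")
    data = np.asarray(data, dtype=float)
    if data.shape[0] != te.size:
        raise ValueError("leading axis of data must match the TE list")

    peak = float(data.max())
    if floor is None:
        floor = 1e-6 * peak if peak > 0 else 1e-12
    floored = data <= floor
    logs = np.log(np.maximum(data, floor))

    pinv = _design_pinv(te)  # (2, N), voxel-independent
    coef = np.tensordot(pinv, logs, axes=(1, 0))  # (2, ...)
    log_s0, r2 = coef[0], coef[1]

    t2_min, t2_max = t2_bounds
    all_floored = floored.all(axis=0)
    any_floored = floored.any(axis=0)

    with np.errstate(over="ignore"):
        s0 = np.exp(log_s0)
    t2 = np.full(r2.shape, t2_max)
    pos = r2 > 0
    t2[pos] = 1.0 / r2[pos]
    t2 = np.clip(t2, t2_min, t2_max)

    valid = pos & ~any_floored & (t2 > t2_min) & (t2 < t2_max)
    # background: every echo floored -> documented fill value 0
    s0 = np.where(all_floored, 0.0, s0)
    t2 = np.where(all_floored, 0.0, t2)
    r2star = np.where(t2 > 0, 1.0 / np.where(t2 > 0, t2, 1.0), 0.0)
    return s0, t2, r2star, valid


def loglinear_fit(img: MultiEchoImage, floor: float | None = None,
                  t2_bounds=DEFAULT_T2_BOUNDS_MS) -> FitResult:
    """Per-voxel log-linear fit of S0 and T2* from a multi-echo image."""
    s0, t2, r2, valid = loglinear_fit_array(img.data, img.te_ms, floor, t2_bounds)
    return FitResult(s0=s0, t2star_ms=t2, r2star_per_ms=r2, valid=valid)


def echo_combination_weights(t2star_ms: np.ndarray, te_ms) -> EchoWeights:
    """T2*-weighted combination weights; requires a strictly positive T2* map."""
    te = np.asarray([float(t) for t in te_ms], dtype=float)
    t2 = np.asarray(t2star_ms, dtype=float)
    if (t2 <= 0).any():
        raise ValueError("T2* must be positive everywhere; clip the map first")
    raw = te.reshape((-1,) + (1,) * t2.ndim) * np.exp(
        -te.reshape((-1,) + (1,) * t2.ndim) / t2[None])
    w = raw / raw.sum(axis=0, keepdims=True)
    return EchoWeights(w=w)


def combine_echoes(img, weights: EchoWeights) -> np.ndarray:
    """Weighted sum over the echo axis: ``sum_n w_n * S_n`` per voxel."""
    data = img.data if isinstance(img, MultiEchoImage) else np.asarray(img)
    if data.shape != weights.w.shape:
        raise ValueError(f"shape mismatch: data {data.shape} vs weights {weights.w.shape}")
    return (weights.w * data).sum(axis=0)
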