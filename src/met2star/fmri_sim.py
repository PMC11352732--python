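"""Synthetic 4D multi-echo task fMRI with known ground truth.

Emulates a three-echo gradient-echo EPI acquisition (defaults: TR 2 s, TEs
14/28/42 ms, 210 volumes, 64 x 64 matrix) with a block task design.  The
BOLD effect is injected as an additive, task-locked T2* increase: inside the
activation mask, T2*(t) = baseline + delta * h(t), with h the ON/OFF boxcar
convolved with a canonical double-gamma hemodynamic response and normalized
to peak 1, so ``delta`` is the peak T2* excursion in ms.  Signals follow the
mono-exponential forward model per echo, are modulated by a slow
multiplicative scanner drift, and are Rician-corrupted volume by volume.

Because the drift multiplies all echoes of a volume equally, it enters the
log-signal as a shift of log S0 and leaves the true T2* time course
untouched — exactly the behaviour that makes T2* series attractive for BOLD
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import ParametricMap
from .signal_model import MAX_SIGMA_FRAC

__all__ = [
    "TaskDesign",
    "SimulationTruth",
    "MultiEchoSeries",
    "canonical_hrf",
    "convolved_regressor",
    "make_block_design",
    "simulate_series",
]

# canonical double-gamma HRF shape parameters (SPM convention, seconds)
HRF_PEAK_DELAY_S = 6.0
HRF_UNDERSHOOT_DELAY_S = 16.0
HRF_DISPERSION_S = 1.0
HRF_UNDERSHOOT_DISPERSION_S = 1.0
HRF_UNDERSHOOT_RATIO = 6.0
HRF_DURATION_S = 32.0


@dataclass(frozen=True)
class TaskDesign:
    """Alternating OFF/ON block design, starting OFF."""

    tr_s: float
    n_volumes: int
    block_len_volumes: int
    condition_vector: np.ndarray  # 0 = OFF, 1 = ON, per volume

    @property
    def on_volumes(self) -> np.ndarray:
        return np.flatnonzero(self.condition_vector == 1)

    @property
    def off_volumes(self) -> np.ndarray:
        return np.flatnonzero(self.condition_vector == 0)


@dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth record of a simulated series."""

    templates: tuple[ParametricMap, ...]
    activation_mask: np.ndarray
    delta_t2star_ms: float
    drift: tuple[float, float]
    sigma_frac: float
    seed: int
    bold_regressor: np.ndarray  # peak-normalized h(t), per volume


@dataclass(frozen=True)
class MultiEchoSeries:
    """5D magnitude series ``data[(x, y, slice, echo, time)]`` with TE/TR metadata."""

    data: np.ndarray
    te_ms: tuple[float, ...]
    tr_s: float
    truth: SimulationTruth | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "te_ms", tuple(float(t) for t in self.te_ms))
        if self.data.ndim != 5 or self.data.shape[3] != len(self.te_ms):
            raise ValueError("data must be (x, y, slice, echo, time) with one TE per echo")
        if (self.data < 0).any():
            raise ValueError("magnitude data must be non-negative")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[4]

    @property
    def grid(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


def canonical_hrf(dt_s: float, duration_s: float = HRF_DURATION_S) -> np.ndarray:
    """Double-gamma HRF sampled at ``dt_s``, peak-normalized to 1."""
    from scipy.stats import gamma as gamma_dist

    t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    peak = gamma_dist.pdf(t, HRF_PEAK_DELAY_S / HRF_DISPERSION_S,
                          scale=HRF_DISPERSION_S)
    under = gamma_dist.pdf(t, HRF_UNDERSHOOT_DELAY_S / HRF_UNDERSHOOT_DISPERSION_S,
                           scale=HRF_UNDERSHOOT_DISPERSION_S)
    h = peak - under / HRF_UNDERSHOOT_RATIO
    return h / h.max()


def convolved_regressor(design: TaskDesign, oversample: int = 1,
                        normalize: str = "peak") -> np.ndarray:
    """Task boxcar convolved with the canonical HRF.

    With ``oversample`` > 1 the boxcar is evaluated on a grid of
    ``TR / oversample`` and the convolution returned at that resolution
    (length ``n_volumes * oversample``); with 1, at volume resolution.
    ``normalize='peak'`` scales the result to maximum 1.
    """
    dt = design.tr_s / oversample
    box = np.repeat(design.condition_vector.astype(float), oversample)
    h = canonical_hrf(dt)
    reg = np.convolve(box, h)[: len(box)] * dt
    if normalize == "peak":
        m = np.abs(reg).max()
        if m > 0:
            reg = reg / m
    return reg


def make_block_design(tr_s: float, n_volumes: int, block_len: int) -> TaskDesign:
    """OFF/ON alternation starting OFF, ``block_len`` volumes per condition."""
    if block_len < 1:
        raise ValueError("block_len must be >= 1")
    if n_volumes < 2 * block_len:
        raise ValueError("need at least one full OFF/ON cycle")
    blocks = -(-n_volumes // block_len)  # ceil
    cond = np.tile(np.repeat([0, 1], block_len), -(-blocks // 2) + 1)[:n_volumes]
    return TaskDesign(tr_s=float(tr_s), n_volumes=int(n_volumes),
                      block_len_volumes=int(block_len), condition_vector=cond)


def simulate_series(templates, design: TaskDesign, activation_mask: np.ndarray,
                    delta_t2star_ms: float, drift: tuple[float, float] = (0.0, 0.0),
                    sigma_frac: float = 0.0, te_ms=(14.0, 28.0, 42.0),
                    seed: int = 0) -> MultiEchoSeries:
    """Simulate a multi-echo task series from per-slice parametric templates.

    Parameters
    ----------
    templates
        One ``ParametricMap`` per slice (all the same in-plane shape).
    activation_mask
        (x, y, slice) boolean; must lie inside the joint tissue mask.
    delta_t2star_ms
        Peak task-locked T2* increase (ms) inside the activation mask.
    drift
        (linear, quadratic) coefficients of the multiplicative scanner drift
        ``1 + a u + b u^2`` with u = t / (n_volumes - 1) in [0, 1]; they are
        fractional signal changes over the whole run.
    sigma_frac
        Rician noise SD as a fraction of the maximum baseline first-echo
        signal; each volume gets an independent realization.
    """
    templates = tuple(templates)
    if delta_t2star_ms < 0:
        raise ValueError("delta_t2star_ms must be >= 0")
    if not 0.0 <= sigma_frac <= MAX_SIGMA_FRAC:
        raise ValueError(f"sigma_frac must lie in [0, {MAX_SIGMA_FRAC}]")
    te = np.asarray([float(t) for t in te_ms])
    if (te <= 0).any():
        raise ValueError("echo times must be positive")

    m0 = np.stack([p.m0 for p in templates], axis=2)          # (x, y, z)
    t2_base = np.stack([p.t2star_ms for p in templates], axis=2)
    mask = np.stack([p.mask for p in templates], axis=2)
    if activation_mask.shape != mask.shape:
        raise ValueError("activation_mask shape must match the template grid")
    if (activation_mask & ~mask).any():
        raise ValueError("activation_mask must lie inside the tissue mask")

    h = convolved_regressor(design)                            # (T,), peak 1
    n_t = design.n_volumes
    u = (np.arange(n_t) / (n_t - 1)) if n_t > 1 else np.zeros(1)
    drift_t = 1.0 + drift[0] * u + drift[1] * u**2

    # T2*(x,y,z,t): baseline everywhere, + delta * h(t) inside the mask
    t2 = np.where(mask, t2_base, np.inf)[..., None] + \
        (activation_mask[..., None] * (delta_t2star_ms * h))
    hi = np.max(t2[mask]) if mask.any() else 0.0
    if hi > 500.0:
        raise ValueError("simulated T2* exceeds 500 ms; reduce delta or baseline")

    with np.errstate(over="ignore"):
        signal = m0[..., None, None] * np.exp(
            -te[None, None, None, :, None] / t2[..., None, :])
    signal = np.where(mask[..., None, None], signal, 0.0) * drift_t

    if sigma_frac > 0:
        sigma = sigma_frac * float(signal[..., 0, 0].max())
        rng = np.random.default_rng(seed)
        g = rng.standard_normal((2,) + signal.shape) * sigma
        signal = np.hypot(signal + g[0], g[1])

    truth = SimulationTruth(templates=templates, activation_mask=activation_mask,
                            delta_t2star_ms=float(delta_t2star_ms),
                            drift=(float(drift[0]), float(drift[1])),
                            sigma_frac=float(sigma_frac), seed=int(seed),
                            bold_regressor=h)
    return MultiEchoSeries(data=signal, te_ms=tuple(te), tr_s=design.tr_s, truth=truth)
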