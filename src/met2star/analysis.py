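"""Time-series derivation and BOLD-sensitivity evaluation.

From a preprocessed multi-echo series this module derives the comparison
time series — voxelwise log-linear-fitted T2* (S_LLF), network-fitted T2*
(S_SDDL), and T2*-weighted echo combinations whose static weights come from
either fitter applied to the time-averaged series (S_EC, S_SDDL_EC) — and
computes the evaluation indicators: temporal SNR after quadratic detrending,
percentage signal change from GLM betas, mean task t-values, functional
contrast (ON-mean minus OFF-mean within an ROI), the union-of-FWE analysis
mask, mean squared error against ground truth, and paired t / Cohen's d
comparisons between pipelines.

Externally produced MEICA-denoised series enter only through the
command-line hook in :mod:`met2star.io`; nothing here computes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .fmri_sim import MultiEchoSeries, TaskDesign, convolved_regressor
from .sddl import TrainedEstimator, fit_volume_slicewise, predict_stack
from .signal_model import (DEFAULT_T2_BOUNDS_MS, echo_combination_weights,
                           loglinear_fit_array)

__all__ = [
    "SeriesKind",
    "DerivedSeries",
    "GLMResult",
    "MetricsReport",
    "fit_t2star_series",
    "ec_series",
    "sddl_ec_series",
    "detrend",
    "smooth",
    "glm_fit",
    "tsnr",
    "psc",
    "functional_contrast",
    "ufwe_mask",
    "compare_series",
    "mse",
]

T_SENTINEL = 1e6  # reported instead of +/- inf on zero-residual fits
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class SeriesKind(str, Enum):
    LLF_T2STAR = "LLF_T2STAR"
    SDDL_T2STAR = "SDDL_T2STAR"
    EC = "EC"
    SDDL_EC = "SDDL_EC"
    MEICA = "MEICA"
    SDDL_MEICA = "SDDL_MEICA"


@dataclass(frozen=True)
class DerivedSeries:
    """4D derived time series ``data[(x, y, slice, time)]`` with provenance."""

    kind: SeriesKind
    data: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, slice, time)")


@dataclass(frozen=True)
class GLMResult:
    """First-level GLM output for the task contrast.

    ``betas`` maps column name -> 3D coefficient map; ``tmap`` is the 3D
    t-statistic map of the task regressor; ``dof`` the residual degrees of
    freedom; ``design_matrix`` the (time x regressor) frame used.
    """

    betas: dict
    tmap: np.ndarray
    dof: int
    design_matrix: pd.DataFrame

    @property
    def pmap(self) -> np.ndarray:
        """Two-sided p-values of the task contrast."""
        return 2.0 * stats.t.sf(np.abs(self.tmap), self.dof)

    def summary(self) -> str:
        t = self.tmap
        lines = [
            "First-level GLM (task contrast)",
            f"  regressors: {list(self.design_matrix.columns)}",
            f"  volumes: {len(self.design_matrix)}   residual dof: {self.dof}",
            f"  t-map: max {t.max():.3f} at {np.unravel_index(t.argmax(), t.shape)}, "
            f"median {np.median(t):.3f}",
            f"  voxels with p < 0.001 (uncorrected): {(self.pmap < 1e-3).sum()}",
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class MetricsReport:
    """Per-series scalar indicators within an ROI plus pairwise comparisons."""

    metrics: pd.DataFrame       # columns: series_kind, roi, metric, value
    comparisons: pd.DataFrame   # columns: pair, metric, p_value, cohens_d

    def to_csv(self, metrics_path, comparisons_path) -> None:
        self.metrics.to_csv(metrics_path, index=False)
        self.comparisons.to_csv(comparisons_path, index=False)


# --------------------------------------------------------------------------
# series derivation
# --------------------------------------------------------------------------

def fit_t2star_series(series: MultiEchoSeries, method: str = "LLF",
                      est: TrainedEstimator | None = None,
                      t2_bounds=DEFAULT_T2_BOUNDS_MS) -> DerivedSeries:
    """4D T2* time series: voxelwise LLF or slice-by-slice network fitting."""
    method = method.upper()
    if method == "LLF":
        # (x, y, z, e, t) -> fit over the echo axis for all voxels/volumes at once
        data = np.moveaxis(series.data, 3, 0)
        _, t2, _, _ = loglinear_fit_array(data, series.te_ms, t2_bounds=t2_bounds)
        return DerivedSeries(kind=SeriesKind.LLF_T2STAR, data=t2,
                             provenance={"fitter": "llf", "te_ms": series.te_ms})
    if method == "SDDL":
        if est is None:
            raise ValueError("method='SDDL' requires a trained estimator")
        if est.n_echoes_in != len(series.te_ms):
            raise ValueError("estimator echo count does not match the series")
        nx, ny, nz, ne, nt = series.data.shape
        # every (volume, slice) is an independent network input; batch them all
        stack = np.ascontiguousarray(
            series.data.transpose(4, 2, 3, 0, 1).reshape(nt * nz, ne, nx, ny))
        _, t2, _ = predict_stack(est, stack, t2_bounds)
        t2 = t2.reshape(nt, nz, nx, ny).transpose(2, 3, 1, 0)
        return DerivedSeries(kind=SeriesKind.SDDL_T2STAR,
                             data=np.ascontiguousarray(t2),
                             provenance={"fitter": "sddl", "te_ms": series.te_ms})
    raise ValueError(f"unknown method {method!r}")


def _weighted_combination(series: MultiEchoSeries, t2star_map: np.ndarray,
                          kind: SeriesKind, provenance: dict,
                          t2_bounds=DEFAULT_T2_BOUNDS_MS) -> DerivedSeries:
    t2 = np.clip(t2star_map, t2_bounds[0], t2_bounds[1])  # weights need T2* > 0
    w = echo_combination_weights(t2, series.te_ms).w      # (e, x, y, z)
    w = np.moveaxis(w, 0, 3)                              # (x, y, z, e)
    combined = np.einsum("xyze,xyzet->xyzt", w, series.data)
    provenance = dict(provenance, weights="t2star_weighted", te_ms=series.te_ms)
    return DerivedSeries(kind=kind, data=combined, provenance=provenance)


def ec_series(series: MultiEchoSeries, t2star_map: np.ndarray) -> DerivedSeries:
    """Echo combination with static weights from a caller-supplied T2* map
    (conventionally LLF on the time-averaged series)."""
    if t2star_map.shape != series.grid:
        raise ValueError("t2star_map must match the series grid")
    return _weighted_combination(series, t2star_map, SeriesKind.EC,
                                 {"t2star_source": "caller"})


def sddl_ec_series(series: MultiEchoSeries, est: TrainedEstimator) -> DerivedSeries:
    """Echo combination whose weights come from the network's T2* estimate of
    the time-averaged series; weights are static across time."""
    mean_vol = series.data.mean(axis=4)  # (x, y, z, e)
    fit = fit_volume_slicewise(est, mean_vol, series.te_ms)
    out = _weighted_combination(series, fit.t2star_ms, SeriesKind.SDDL_EC,
                                {"t2star_source": "sddl_time_averaged"})
    return out


def llf_mean_t2star(series: MultiEchoSeries,
                    t2_bounds=DEFAULT_T2_BOUNDS_MS) -> np.ndarray:
    """LLF T2* map of the time-averaged series (the conventional EC input)."""
    data = np.moveaxis(series.data.mean(axis=4), 3, 0)
    _, t2, _, _ = loglinear_fit_array(data, series.te_ms, t2_bounds=t2_bounds)
    return t2


# --------------------------------------------------------------------------
# preprocessing of derived series
# --------------------------------------------------------------------------

def _poly_design(n_t: int, orders) -> np.ndarray:
    u = np.linspace(-1.0, 1.0, n_t)
    cols = [np.ones(n_t)] + [u**k for k in sorted(orders)]
    return np.column_stack(cols)


def detrend(series4d: np.ndarray, orders=(1, 2)) -> np.ndarray:
    """Remove the least-squares constant + polynomial trend per voxel and add
    back the temporal mean, so the output keeps the raw signal level."""
    n_t = series4d.shape[-1]
    if n_t < 4:
        raise ValueError("need >= 4 volumes to detrend")
    x = _poly_design(n_t, orders)
    pinv = np.linalg.pinv(x)
    flat = series4d.reshape(-1, n_t)
    fitted = (flat @ pinv.T) @ x.T
    out = flat - fitted + flat.mean(axis=1, keepdims=True)
    return out.reshape(series4d.shape)


def smooth(series4d: np.ndarray, fwhm_mm: float, voxel_size_mm=(3.5, 3.5, 3.5)
           ) -> np.ndarray:
    """Volume-wise 3D Gaussian smoothing; ``fwhm_mm = 0`` is the identity."""
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return series4d.copy()
    sigma_vox = [fwhm_mm / (FWHM_TO_SIGMA * v) for v in voxel_size_mm]
    out = np.empty_like(series4d, dtype=float)
    for t in range(series4d.shape[-1]):
        out[..., t] = ndimage.gaussian_filter(series4d[..., t].astype(float),
                                              sigma_vox, mode="reflect")
    return out


# --------------------------------------------------------------------------
# GLM and indicators
# --------------------------------------------------------------------------

def glm_fit(series4d: np.ndarray, design: TaskDesign,
            nuisance: np.ndarray | None = None) -> GLMResult:
    """Voxelwise OLS of [task regressor | nuisance | constant].

    The task regressor is the HRF-convolved boxcar, peak-normalized.  The
    task t-statistic uses t = b / sqrt(sigma2 * (X'X)^-1_[task,task]); exact
    fits (zero residual) report the capped sentinel ``T_SENTINEL``.
    """
    n_t = series4d.shape[-1]
    if n_t != design.n_volumes:
        raise ValueError("series length must match the design")
    task = convolved_regressor(design)
    cols = {"task": task}
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n_t:
            raise ValueError("nuisance matrix must have one row per volume")
        for k in range(nuisance.shape[1]):
            cols[f"nuisance_{k}"] = nuisance[:, k]
    cols["constant"] = np.ones(n_t)
    x = np.column_stack(list(cols.values()))
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError(
            f"rank-deficient design matrix (rank {rank} < {x.shape[1]}); "
            f"columns: {list(cols)}")

    xtx_inv = np.linalg.inv(x.T @ x)
    pinv = xtx_inv @ x.T
    flat = series4d.reshape(-1, n_t).T          # (time, voxel)
    beta = pinv @ flat                          # (k, voxel)
    resid = flat - x @ beta
    dof = n_t - x.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[0, 0], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[0] / se
    t = np.where(se == 0, np.sign(beta[0]) * T_SENTINEL, t)
    t = np.clip(np.nan_to_num(t, nan=0.0), -T_SENTINEL, T_SENTINEL)

    shape3 = series4d.shape[:-1]
    betas = {name: beta[i].reshape(shape3) for i, name in enumerate(cols)}
    dm = pd.DataFrame(x, columns=list(cols))
    return GLMResult(betas=betas, tmap=t.reshape(shape3), dof=dof, design_matrix=dm)


def tsnr(series4d: np.ndarray) -> np.ndarray:
    """Temporal SNR: voxelwise signal level / SD after removing linear and
    quadratic trends.

    The denominator is the SD (n-1) of the residual of a constant + linear +
    quadratic fit in raw acquisition time.  The numerator is the fitted
    intercept of that same trend model (the modelled signal level at run
    start): for drift-free data it estimates the temporal mean, and because
    added drift terms ``a t + b t^2`` carry no constant component in this
    basis, tSNR is exactly invariant to them.  (Near-)zero-variance voxels
    are reported as 0.
    """
    n_t = series4d.shape[-1]
    if n_t < 4:
        raise ValueError("need >= 4 volumes")
    t = np.arange(n_t, dtype=float)
    x = np.column_stack([np.ones(n_t), t, t * t])
    pinv = np.linalg.pinv(x)
    flat = series4d.reshape(-1, n_t)
    beta = flat @ pinv.T
    resid = flat - beta @ x.T
    sd = resid.std(axis=1, ddof=1)
    level = beta[:, 0]
    degenerate = sd <= 1e-10 * np.maximum(np.abs(level), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = level / sd
    return np.where(degenerate, 0.0, out).reshape(series4d.shape[:-1])


def psc(glm: GLMResult, design: TaskDesign, oversample: int = 16) -> np.ndarray:
    """Percentage signal change: 100 * SF * beta_task / beta_constant.

    SF is the maximum of a single-trial (one ON block) response evaluated on
    a design grid super-sampled by ``oversample`` relative to the TR, scaled
    consistently with the GLM's peak-normalized task regressor.  Voxels with
    zero constant beta report 0.
    """
    # reference trial: one ON block in an otherwise empty run
    ref_cond = np.zeros(design.n_volumes, dtype=int)
    on = design.on_volumes
    first_on = on[0] if on.size else 0
    ref_cond[first_on: first_on + design.block_len_volumes] = 1
    ref = TaskDesign(tr_s=design.tr_s, n_volumes=design.n_volumes,
                     block_len_volumes=design.block_len_volumes,
                     condition_vector=ref_cond)
    # the GLM regressor is peak-normalized at TR resolution; express the
    # super-sampled single-trial maximum on that same scale
    full_tr = convolved_regressor(design, oversample=1, normalize="none")
    scale = np.abs(full_tr).max()
    ref_fine = convolved_regressor(ref, oversample=oversample, normalize="none")
    sf = ref_fine.max() / scale if scale > 0 else 1.0

    b_task, b_const = glm.betas["task"], glm.betas["constant"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * sf * b_task / b_const
    return np.where(b_const == 0, 0.0, np.nan_to_num(out))


def functional_contrast(series4d: np.ndarray, design: TaskDesign,
                        roi: np.ndarray, fwhm_mm: float = 0.0,
                        voxel_size_mm=(3.5, 3.5, 3.5)) -> float:
    """ON-mean minus OFF-mean of the detrended (and optionally smoothed)
    series, spatially averaged within ``roi`` first."""
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("roi is empty")
    proc = detrend(series4d, orders=(1, 2))
    if fwhm_mm > 0:
        proc = smooth(proc, fwhm_mm, voxel_size_mm)
    ts = proc[roi].mean(axis=0)
    return float(ts[design.on_volumes].mean() - ts[design.off_volumes].mean())


def ufwe_mask(glm_results, alpha: float = 0.001, in_mask: np.ndarray | None = None
              ) -> np.ndarray:
    """Union of family-wise-error-significant voxel sets across series.

    Per series, a voxel is significant when its Bonferroni-corrected
    two-sided task p-value is below ``alpha``; correction counts the voxels
    of ``in_mask`` (whole grid when None).  The returned mask is the union.
    """
    glm_results = list(glm_results)
    if not glm_results:
        raise ValueError("need at least one GLM result")
    shape = glm_results[0].tmap.shape
    if any(g.tmap.shape != shape for g in glm_results):
        raise ValueError("all GLM results must share one grid")
    if in_mask is None:
        in_mask = np.ones(shape, dtype=bool)
    n_vox = int(in_mask.sum())
    union = np.zeros(shape, dtype=bool)
    for g in glm_results:
        p_corr = np.minimum(g.pmap * n_vox, 1.0)
        union |= (p_corr < alpha) & in_mask
    return union


# --------------------------------------------------------------------------
# scalar comparisons
# --------------------------------------------------------------------------

def compare_series(values_a, values_b) -> tuple[float, float]:
    """Two-tailed paired t-test and Cohen's d of ``b - a`` across subjects.

    d = mean(diff) / SD(diff) with the n-1 sample SD; positive d means the
    second pipeline scores higher.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length 1D samples with n >= 3")
    diff = b - a
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: paired test undefined")
    t = stats.ttest_rel(b, a)
    return float(t.pvalue), float(diff.mean() / sd)


def mse(map_a: np.ndarray, map_b: np.ndarray, mask: np.ndarray | None = None
        ) -> float:
    """Mean squared difference within ``mask`` (everywhere when None)."""
    a, b = np.asarray(map_a, dtype=float), np.asarray(map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if mask is None:
        mask = np.ones(a.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    d = a[mask] - b[mask]
    return float((d * d).mean())
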