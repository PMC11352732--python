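"""Model/Results front-end for T2* estimation.

``T2StarModel`` wraps a multi-echo acquisition (one slice or a volume) and
``fit()`` dispatches to either the voxelwise log-linear fit or the trained
slice-wise network estimator, returning a ``T2StarResults`` that carries the
parameter maps, a validity mask, residual diagnostics (for LLF) and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sddl import TrainedEstimator, fit_volume_slicewise, predict_t2star
from .signal_model import (DEFAULT_T2_BOUNDS_MS, FitResult, MultiEchoImage,
                           loglinear_fit)

__all__ = ["T2StarModel", "T2StarResults"]


@dataclass
class T2StarResults:
    """Fitted S0/T2* maps plus fit diagnostics."""

    fit: FitResult
    method: str
    te_ms: tuple[float, ...]
    residual_rms: float | None = None  # RMS log-signal residual (LLF only)

    @property
    def t2star_ms(self) -> np.ndarray:
        return self.fit.t2star_ms

    @property
    def s0(self) -> np.ndarray:
        return self.fit.s0

    @property
    def r2star_per_ms(self) -> np.ndarray:
        return self.fit.r2star_per_ms

    @property
    def valid(self) -> np.ndarray:
        return self.fit.valid

    def summary(self) -> str:
        v = self.valid
        t2 = self.t2star_ms[v]
        lines = [
            "T2* fit results",
            "=" * 40,
            f"method:            {self.method}",
            f"echo times (ms):   {list(self.te_ms)}",
            f"grid:              {self.t2star_ms.shape}",
            f"valid voxels:      {int(v.sum())} / {v.size}",
        ]
        if t2.size:
            lines += [
                f"T2* median (ms):   {np.median(t2):.2f}",
                f"T2* IQR (ms):      [{np.percentile(t2, 25):.2f}, "
                f"{np.percentile(t2, 75):.2f}]",
                f"S0 median:         {np.median(self.s0[v]):.2f}",
            ]
        if self.residual_rms is not None:
            lines.append(f"log-residual RMS:  {self.residual_rms:.3e}")
        return "\n".join(lines)


class T2StarModel:
    """Mono-exponential relaxometry model over a multi-echo acquisition.

    Parameters
    ----------
    data
        Either (echo, row, col) for a single slice or (x, y, slice, echo)
        for a volume.
    te_ms
        Echo times in ms, strictly increasing.
    """

    def __init__(self, data: np.ndarray, te_ms):
        data = np.asarray(data, dtype=float)
        if data.ndim == 3:
            self._slice = MultiEchoImage(data=data, te_ms=tuple(te_ms))
            self._volume = None
        elif data.ndim == 4:
            if data.shape[3] != len(tuple(te_ms)):
                raise ValueError("4D data must be (x, y, slice, echo)")
            self._slice = None
            self._volume = data
        else:
            raise ValueError("data must be 3D (echo, row, col) or 4D (x, y, slice, echo)")
        self.te_ms = tuple(float(t) for t in te_ms)

    @classmethod
    def from_series(cls, series, volume_index: int = 0) -> "T2StarModel":
        """Build from one volume of a :class:`~met2star.fmri_sim.MultiEchoSeries`."""
        return cls(series.data[..., volume_index], series.te_ms)

    def fit(self, method: str = "llf", estimator: TrainedEstimator | None = None,
            t2_bounds=DEFAULT_T2_BOUNDS_MS) -> T2StarResults:
        method = method.lower()
        if method == "llf":
            return self._fit_llf(t2_bounds)
        if method == "sddl":
            if estimator is None:
                raise ValueError("method='sddl' requires a trained estimator")
            if self._slice is not None:
                fr = predict_t2star(estimator, self._slice, t2_bounds)
            else:
                fr = fit_volume_slicewise(estimator, self._volume, self.te_ms, t2_bounds)
            return T2StarResults(fit=fr, method="sddl", te_ms=self.te_ms)
        raise ValueError(f"unknown method {method!r}; use 'llf' or 'sddl'")

    def _fit_llf(self, t2_bounds) -> T2StarResults:
        if self._slice is not None:
            fr = loglinear_fit(self._slice, t2_bounds=t2_bounds)
            echo_first = self._slice.data
        else:
            from .signal_model import loglinear_fit_array

            echo_first = np.moveaxis(self._volume, 3, 0)
            s0, t2, r2, valid = loglinear_fit_array(echo_first, self.te_ms,
                                                    t2_bounds=t2_bounds)
            fr = FitResult(s0=s0, t2star_ms=t2, r2star_per_ms=r2, valid=valid)
        te = np.asarray(self.te_ms)
        with np.errstate(divide="ignore"):
            pred = np.log(np.maximum(fr.s0, 1e-300))[None] - \
                te.reshape((-1,) + (1,) * fr.s0.ndim) * fr.r2star_per_ms[None]
            obs = np.log(np.maximum(echo_first, 1e-300))
        resid = (pred - obs)[:, fr.valid]
        rms = float(np.sqrt((resid**2).mean())) if resid.size else None
        return T2StarResults(fit=fr, method="llf", te_ms=self.te_ms,
                             residual_rms=rms)
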