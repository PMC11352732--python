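"""NIfTI and sidecar I/O, run configuration, and the external MEICA hook.

Multi-echo series are written BIDS-style as one 4D NIfTI per echo plus a
shared JSON sidecar carrying ``EchoTime`` values (ms) and ``RepetitionTime``
(s); a 5D file (x, y, slice, echo, time) can be read but is never written.
Externally computed MEICA-denoised series only ever enter the pipeline
through :func:`meica_hook`, which stages echo files, invokes a user-supplied
command line and ingests its 4D output.
"""

from __future__ import annotations

import json
import logging
import shlex
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .analysis import DerivedSeries, SeriesKind
from .fmri_sim import MultiEchoSeries
from .sddl import TrainingConfig

__all__ = [
    "RunConfig",
    "write_multiecho_nifti",
    "read_multiecho_nifti",
    "write_map_nifti",
    "read_map_nifti",
    "meica_hook",
    "MeicaUnavailable",
]

log = logging.getLogger("met2star")


class FormatError(ValueError):
    pass


class MeicaUnavailable(RuntimeError):
    """The external MEICA command is not on PATH; the pipeline continues
    with the four internally computed series."""


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration with a named seed registry.

    Defaults mirror a three-echo EPI protocol: TR 2 s, TEs 14/28/42 ms,
    64 x 64 matrix.
    """

    te_ms: tuple[float, ...] = (14.0, 28.0, 42.0)
    tr_s: float = 2.0
    grid: tuple[int, int, int] = (64, 64, 2)
    t2_bounds_ms: tuple[float, float] = (1.0, 500.0)
    noise_range: tuple[float, float] = (0.0, 0.05)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    seeds: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)

    _KNOWN = {"te_ms", "tr_s", "grid", "t2_bounds_ms", "noise_range",
              "training", "seeds", "paths"}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - cls._KNOWN
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        if "training" in raw:
            raw["training"] = TrainingConfig(**raw["training"])
        for key in ("te_ms", "tr_s", "grid", "t2_bounds_ms", "noise_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def seed_for(self, name: str, default: int = 0) -> int:
        return int(self.seeds.get(name, default))


# --------------------------------------------------------------------------
# multi-echo series I/O
# --------------------------------------------------------------------------

def write_multiecho_nifti(series: MultiEchoSeries, out_dir, prefix: str = "bold"
                          ) -> list[Path]:
    """One 4D file per echo plus a JSON sidecar; returns the echo file paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for e, te in enumerate(series.te_ms):
        img = nib.Nifti1Image(np.asarray(series.data[:, :, :, e, :]), np.eye(4))
        p = out_dir / f"{prefix}_echo-{e + 1}.nii"
        nib.save(img, p)
        paths.append(p)
    sidecar = {
        "EchoTime": list(series.te_ms),       # ms
        "RepetitionTime": series.tr_s,        # s
        "EchoFiles": [p.name for p in paths],
    }
    (out_dir / f"{prefix}.json").write_text(json.dumps(sidecar, indent=2))
    return paths


def read_multiecho_nifti(paths, sidecar) -> MultiEchoSeries:
    """Read one-4D-file-per-echo (or a single 5D file) plus its sidecar.

    Echoes are returned sorted by ascending TE; supplying them out of order
    logs a warning.  Negative intensities and inconsistent grids are format
    errors naming the offending file.
    """
    sidecar = Path(sidecar)
    meta = json.loads(sidecar.read_text())
    if "EchoTime" not in meta:
        raise FormatError(f"sidecar {sidecar} is missing the EchoTime key")
    te = [float(t) for t in np.atleast_1d(meta["EchoTime"])]
    if "RepetitionTime" not in meta:
        raise FormatError(f"sidecar {sidecar} is missing the RepetitionTime key")
    tr = float(meta["RepetitionTime"])

    paths = [Path(p) for p in (paths if isinstance(paths, (list, tuple)) else [paths])]
    if len(paths) == 1 and len(te) > 1:
        arr = np.asarray(nib.load(paths[0]).dataobj, dtype=float)
        if arr.ndim != 5 or arr.shape[3] != len(te):
            raise FormatError(f"{paths[0]}: expected 5D (x,y,z,echo,t) data "
                              f"with {len(te)} echoes, got shape {arr.shape}")
        data = arr
    else:
        if len(paths) != len(te):
            raise FormatError(f"{len(paths)} echo files but {len(te)} EchoTime "
                              f"entries in {sidecar}")
        vols = []
        shape = None
        for p in paths:
            a = np.asarray(nib.load(p).dataobj, dtype=float)
            if a.ndim == 3:
                a = a[..., None]
            if a.ndim != 4:
                raise FormatError(f"{p}: expected a 4D echo file, got {a.ndim}D")
            if shape is None:
                shape = a.shape
            elif a.shape != shape:
                raise FormatError(f"{p}: grid {a.shape} differs from {shape}")
            vols.append(a)
        data = np.stack(vols, axis=3)
    if (data < 0).any():
        raise FormatError(f"{paths[0].parent}: negative intensities in "
                          "magnitude data")

    order = np.argsort(te)
    if not np.array_equal(order, np.arange(len(te))):
        log.warning("echoes supplied out of TE order; sorting by ascending TE")
        data = data[:, :, :, order, :]
        te = [te[i] for i in order]
    return MultiEchoSeries(data=data, te_ms=tuple(te), tr_s=tr)


def write_map_nifti(arr: np.ndarray, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), np.eye(4)), path)
    return path


def read_map_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(path).dataobj, dtype=float)


# --------------------------------------------------------------------------
# estimator checkpoints
# --------------------------------------------------------------------------

def save_estimator(est, path) -> Path:
    """One-archive checkpoint: weights, normalization spec, TE list, history."""
    from .sddl import TrainedEstimator  # local import avoids a cycle

    assert isinstance(est, TrainedEstimator)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "n_echoes_in": est.n_echoes_in,
        "te_ms": list(est.te_ms),
        "normalization_spec": est.normalization_spec,
        "best_val_loss": est.best_val_loss,
        "history": est.history,
        "n_out": est.net.n_out,
        "base_width": est.net.base_width,
    }
    weights = {f"w{i}": w for i, w in enumerate(est.net.get_weights())}
    np.savez(path, meta=json.dumps(meta), **weights)
    return path


def load_estimator(path):
    from .sddl import build_estimator

    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        weights = [z[f"w{i}"] for i in range(len(z.files) - 1)]
    est = build_estimator(meta["n_echoes_in"], meta["n_out"],
                          base_width=meta["base_width"], te_ms=meta["te_ms"])
    est.net.set_weights(weights)
    est.normalization_spec = meta["normalization_spec"]
    est.best_val_loss = meta["best_val_loss"]
    est.history = [tuple(h) for h in meta["history"]]
    return est


def export_training_curve(est, path) -> Path:
    """Plain-text table (epoch, train_loss, val_loss)."""
    path = Path(path)
    lines = ["epoch\ttrain_loss\tval_loss"]
    lines += [f"{e}\t{tr:.8e}\t{va:.8e}" for e, tr, va in est.history]
    path.write_text("\n".join(lines) + "\n")
    return path


# --------------------------------------------------------------------------
# external MEICA hook
# --------------------------------------------------------------------------

def meica_hook(series: MultiEchoSeries, command_template: str,
               kind: SeriesKind = SeriesKind.MEICA,
               workdir=None) -> DerivedSeries:
    """Run an external multi-echo denoising command on staged echo NIfTIs.

    ``command_template`` may reference ``{echo_files}`` (space-separated
    staged inputs), ``{te_ms}`` (comma-separated echo times), ``{tr_s}`` and
    ``{out}`` (expected 4D output path).  The denoised, optimally combined
    output is ingested as a :class:`DerivedSeries` whose provenance records
    the resolved command line.

    Raises :class:`MeicaUnavailable` when the executable is absent, so
    callers can degrade to the four internal series.
    """
    argv0 = shlex.split(command_template)[0]
    if shutil.which(argv0) is None:
        raise MeicaUnavailable(f"external command {argv0!r} not found on PATH; "
                               "continuing without MEICA series")
    tmp_ctx = tempfile.TemporaryDirectory() if workdir is None else None
    work = Path(workdir) if workdir is not None else Path(tmp_ctx.name)
    try:
        echo_paths = write_multiecho_nifti(series, work, prefix="staged")
        out_path = work / "denoised.nii"
        cmd = command_template.format(
            echo_files=" ".join(str(p) for p in echo_paths),
            te_ms=",".join(str(t) for t in series.te_ms),
            tr_s=series.tr_s, out=out_path)
        proc = subprocess.run(shlex.split(cmd), capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(f"external command failed (exit {proc.returncode}): "
                               f"{cmd}\nstderr: {proc.stderr.strip()}")
        arr = np.asarray(nib.load(out_path).dataobj, dtype=float)
        if arr.ndim != 4:
            raise FormatError(f"{out_path}: expected a 4D denoised series")
        return DerivedSeries(kind=kind, data=arr,
                             provenance={"command": cmd, "source": "external"})
    finally:
        if tmp_ctx is not None:
            tmp_ctx.cleanup()
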