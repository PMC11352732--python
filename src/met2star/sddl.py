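"""Synthetic-data-driven training of the slice-wise T2* estimator.

The estimator is a 4-level U-net mapping an N-echo magnitude slice to two
parametric channels (M0, T2*).  Training pairs are synthesized from
procedural phantoms through the mono-exponential forward model with Rician
noise whose fractional SD is drawn uniformly from a configured range, so the
network learns both the inverse mapping and denoising.  Supervision follows
the standard synthetic-data recipe: the noiseless parametric template is the
label for its own noisy synthetic acquisition.

Normalization: each input echo stack is divided by its first-echo maximum;
the M0 label shares that constant (so inference can de-normalize without a
label) and the T2* label is divided by 200 ms.  Training samples random
``crop_size`` x ``crop_size`` patches; inference runs full slices, valid
because the network is fully convolutional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, UNet
from .phantom import ParametricMap, split_bank_by_subject
from .signal_model import (DEFAULT_T2_BOUNDS_MS, FitResult, MultiEchoImage,
                           add_rician_noise, forward_signal)

__all__ = [
    "TrainingConfig",
    "TrainedEstimator",
    "TrainingDataset",
    "make_training_pairs",
    "build_estimator",
    "train",
    "predict_t2star",
    "fit_volume_slicewise",
]

T2STAR_SCALE_MS = 200.0  # label scale; matches the display range of brain T2*


class TrainingFailure(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the estimator's supervised training."""

    batch_size: int = 16
    crop_size: int = 32
    learning_rate: float = 1e-4
    max_epochs: int = 20
    noise_range: tuple[float, float] = (0.0, 0.05)
    split_fraction: float = 1 / 6  # fraction of subjects held out for validation
    seed: int = 0
    loss_name: str = "mse"
    crops_per_slice: int = 4  # random crops drawn per training slice per epoch

    def __post_init__(self) -> None:
        lo, hi = self.noise_range
        if not 0.0 <= lo <= hi <= 0.10:
            raise ValueError("noise_range must satisfy 0 <= low <= high <= 0.10")
        if self.loss_name != "mse":
            raise ValueError("only the 'mse' loss is implemented")


@dataclass
class TrainedEstimator:
    """U-net weights plus everything needed for self-describing inference."""

    net: UNet
    n_echoes_in: int
    te_ms: tuple[float, ...]
    normalization_spec: dict = field(default_factory=lambda: {
        "input": "first_echo_max", "m0": "first_echo_max",
        "t2star_scale_ms": T2STAR_SCALE_MS})
    best_val_loss: float = np.inf
    history: list = field(default_factory=list)  # (epoch, train_loss, val_loss)

    @property
    def weights(self):
        return self.net.get_weights()


@dataclass
class TrainingDataset:
    """Normalized synthetic pairs, subject-disjoint train/validation split.

    ``*_x`` are (n, echo, H, W) float32 normalized inputs, ``*_y`` the
    (n, 2, H, W) normalized (M0, T2*) labels.
    """

    train_x: np.ndarray
    train_y: np.ndarray
    val_x: np.ndarray
    val_y: np.ndarray
    te_ms: tuple[float, ...]
    train_subjects: tuple[int, ...]
    val_subjects: tuple[int, ...]


def _normalize_pair(img: MultiEchoImage, pmap: ParametricMap):
    scale = float(img.data[0].max())
    scale = scale if scale > 0 else 1.0
    x = (img.data / scale).astype(np.float32)
    y = np.stack([pmap.m0 / scale, pmap.t2star_ms / T2STAR_SCALE_MS]).astype(np.float32)
    return x, y


def make_training_pairs(bank: list[ParametricMap], te_ms, cfg: TrainingConfig
                        ) -> TrainingDataset:
    """Synthesize noisy input / clean label pairs and split subject-disjointly.

    Each slice gets an independent noise fraction ~ U(cfg.noise_range) and an
    independent noise realization, both derived from ``cfg.seed``.
    """
    sids = sorted({p.subject_id for p in bank})
    if len(sids) < 2:
        raise ValueError("bank must span >= 2 subjects for a leakage-free split")
    n_val = max(1, round(len(sids) * cfg.split_fraction))
    n_val = min(n_val, len(sids) - 1)
    train_maps, val_maps = split_bank_by_subject(bank, n_val)

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))

    def synth(maps):
        xs, ys = [], []
        for pmap in maps:
            img = forward_signal(pmap, te_ms)
            frac = float(rng.uniform(*cfg.noise_range))
            img = add_rician_noise(img, frac, rng=rng)
            x, y = _normalize_pair(img, pmap)
            xs.append(x)
            ys.append(y)
        return np.stack(xs), np.stack(ys)

    tx, ty = synth(train_maps)
    vx, vy = synth(val_maps)
    return TrainingDataset(
        train_x=tx, train_y=ty, val_x=vx, val_y=vy,
        te_ms=tuple(float(t) for t in te_ms),
        train_subjects=tuple(sorted({p.subject_id for p in train_maps})),
        val_subjects=tuple(sorted({p.subject_id for p in val_maps})))


def build_estimator(n_echoes: int, n_out_channels: int = 2, base_width: int = 32,
                    te_ms=(), init_seed: int = 0) -> TrainedEstimator:
    """Untrained 4-level U-net estimator (deterministic given ``init_seed``)."""
    if n_echoes < 2:
        raise ValueError("need >= 2 echoes")
    net = UNet(n_echoes, n_out_channels, base_width=base_width, seed=init_seed)
    return TrainedEstimator(net=net, n_echoes_in=n_echoes,
                            te_ms=tuple(float(t) for t in te_ms))


def _eval_loss(net: UNet, x: np.ndarray, y: np.ndarray, chunk: int = 32) -> float:
    tot, n = 0.0, 0
    for i in range(0, len(x), chunk):
        out = net.forward(x[i:i + chunk], train=False)
        d = out - y[i:i + chunk]
        tot += float((d * d).sum())
        n += d.size
    return tot / n


def train(est: TrainedEstimator, dataset: TrainingDataset, cfg: TrainingConfig
          ) -> TrainedEstimator:
    """Adam/MSE training on random crops, checkpointing the best validation loss.

    One epoch draws ``cfg.crops_per_slice`` random ``crop_size`` x ``crop_size``
    patches from every training slice; the default of 4 makes an epoch cover
    each pixel of a 64x64 slice once in expectation (a 32x32 crop is a
    quarter of the slice).
    Validation runs on full slices.  Returns ``est`` with the best-checkpoint
    weights restored, ``best_val_loss`` and per-epoch ``history`` filled in.
    """
    if dataset.train_x.shape[1] != est.n_echoes_in:
        raise ValueError("dataset echo count does not match the estimator")
    if cfg.max_epochs == 0:
        est.history = []
        return est

    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0xA11CE)))
    net = est.net
    opt = Adam(net.params(), lr=cfg.learning_rate)
    n_train = len(dataset.train_x)
    hw = dataset.train_x.shape[-2:]
    cs = cfg.crop_size
    if cs > min(hw):
        raise ValueError("crop_size exceeds the slice size")

    best_w, best_loss = net.get_weights(), np.inf
    history = []
    for epoch in range(cfg.max_epochs):
        order = np.repeat(np.arange(n_train), cfg.crops_per_slice)
        rng.shuffle(order)
        ep_loss, nb = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            r0 = rng.integers(0, hw[0] - cs + 1, size=len(idx))
            c0 = rng.integers(0, hw[1] - cs + 1, size=len(idx))
            xb = np.stack([dataset.train_x[j, :, r:r + cs, c:c + cs]
                           for j, r, c in zip(idx, r0, c0)])
            yb = np.stack([dataset.train_y[j, :, r:r + cs, c:c + cs]
                           for j, r, c in zip(idx, r0, c0)])
            out = net.forward(xb, train=True)
            d = out - yb
            ep_loss += float((d * d).mean())
            nb += 1
            net.zero_grad()
            net.backward((2.0 / d.size) * d)
            opt.step()
        val_loss = _eval_loss(net, dataset.val_x, dataset.val_y)
        if not np.isfinite(val_loss):
            raise TrainingFailure(f"validation loss became non-finite at epoch {epoch}")
        history.append((epoch, ep_loss / max(nb, 1), val_loss))
        if val_loss < best_loss:
            best_loss, best_w = val_loss, net.get_weights()

    net.set_weights(best_w)
    est.best_val_loss = float(best_loss)
    est.history = history
    return est


def _predict_batch(est: TrainedEstimator, stack: np.ndarray, chunk: int = 32
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Run the net on (n, echo, H, W) magnitude slices; returns (m0, t2star_ms)."""
    scales = stack[:, 0].reshape(len(stack), -1).max(axis=1)
    scales = np.where(scales > 0, scales, 1.0)
    x = (stack / scales[:, None, None, None]).astype(np.float32)
    outs = []
    for i in range(0, len(x), chunk):
        outs.append(est.net.forward(x[i:i + chunk], train=False))
    out = np.concatenate(outs) if outs else np.empty((0, 2) + stack.shape[-2:])
    m0 = out[:, 0] * scales[:, None, None].astype(np.float32)
    t2 = out[:, 1].astype(np.float64) * T2STAR_SCALE_MS
    return np.asarray(m0, dtype=np.float64), t2


def predict_stack(est: TrainedEstimator, stack: np.ndarray,
                  t2_bounds=DEFAULT_T2_BOUNDS_MS
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized inference on (n, echo, H, W) slices.

    Returns ``(s0, t2star_ms, valid)`` each shaped (n, H, W).  ``valid``
    marks voxels with appreciable signal (first echo above 2% of the
    slice maximum) whose raw prediction already lay inside the T2* bounds;
    T2* is clipped to the bounds wherever signal is present and 0 elsewhere.
    """
    if stack.ndim != 4 or stack.shape[1] != est.n_echoes_in:
        raise ValueError(f"stack must be (n, {est.n_echoes_in}, H, W)")
    m0, t2 = _predict_batch(est, stack)
    t2_min, t2_max = t2_bounds
    first = stack[:, 0]
    thresh = 0.02 * first.reshape(len(stack), -1).max(axis=1)
    tissue = first > thresh[:, None, None]
    valid = tissue & (t2 > t2_min) & (t2 < t2_max)
    t2c = np.where(tissue, np.clip(t2, t2_min, t2_max), 0.0)
    m0c = np.where(tissue, np.maximum(m0, 0.0), 0.0)
    return m0c, t2c, valid


def predict_t2star(est: TrainedEstimator, img: MultiEchoImage,
                   t2_bounds=DEFAULT_T2_BOUNDS_MS) -> FitResult:
    """Estimate (S0, T2*) for one slice with the trained network."""
    if img.n_echoes != est.n_echoes_in:
        raise ValueError(f"estimator expects {est.n_echoes_in} echoes, got {img.n_echoes}")
    m0, t2, valid = predict_stack(est, img.data[None], t2_bounds)
    m0, t2, valid = m0[0], t2[0], valid[0]
    r2 = np.where(t2 > 0, 1.0 / np.where(t2 > 0, t2, 1.0), 0.0)
    return FitResult(s0=m0, t2star_ms=t2, r2star_per_ms=r2, valid=valid)


def fit_volume_slicewise(est: TrainedEstimator, volume: np.ndarray, te_ms,
                         t2_bounds=DEFAULT_T2_BOUNDS_MS) -> FitResult:
    """Apply the estimator independently to every axial slice of an
    (x, y, slice, echo) multi-echo volume and stack the results."""
    if volume.ndim != 4 or volume.shape[3] != est.n_echoes_in:
        raise ValueError("volume must be (x, y, slice, echo) matching the estimator")
    stack = np.ascontiguousarray(volume.transpose(2, 3, 0, 1))  # (z, e, x, y)
    m0, t2, valid = predict_stack(est, stack, t2_bounds)
    to_vol = lambda a: np.ascontiguousarray(np.moveaxis(a, 0, 2))
    t2v = to_vol(t2)
    r2 = np.where(t2v > 0, 1.0 / np.where(t2v > 0, t2v, 1.0), 0.0)
    return FitResult(s0=to_vol(m0), t2star_ms=t2v, r2star_per_ms=r2,
                     valid=to_vol(valid))
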