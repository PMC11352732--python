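"""Procedural 2D parametric head phantoms (M0, T2*) for synthetic training data.

Each template is an elliptical "head" containing nested tissue classes with
distinct T2* ranges at 3 T — white-matter-like (45–60 ms), grey-matter-like
(60–80 ms), CSF-like (150–250 ms, clipped to 200 ms) and small iron-rich /
vessel-like foci (15–35 ms) — plus smooth within-class variation.  The
templates stand in for anatomy-derived parametric maps: what matters for
training a slice-wise T2* estimator is realistic spatial structure and value
ranges, not anatomical fidelity.

A "subject" is one top-level seed controlling head geometry and tissue
layout; augmented copies of a subject's base map share its ``subject_id`` so
that train/validation splits can be made subject-disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "ParametricMap",
    "TISSUE_T2STAR_MS",
    "generate_template",
    "augment",
    "make_template_bank",
    "split_bank_by_subject",
]

# T2* ranges (ms) per tissue class at 3 T; CSF clipped at the map-wide cap.
TISSUE_T2STAR_MS = {
    "wm": (45.0, 60.0),
    "gm": (60.0, 80.0),
    "csf": (150.0, 250.0),
    "vessel": (15.0, 35.0),
}
T2STAR_CAP_MS = 200.0
T2STAR_MAX_MS = 500.0
MIN_DIM = 16


@dataclass(frozen=True)
class ParametricMap:
    """Paired proton-density (M0) and T2* maps with a tissue mask.

    ``m0`` and ``t2star_ms`` are 0 outside ``mask``; inside the mask
    ``t2star_ms`` lies in (0, 500].
    """

    m0: np.ndarray
    t2star_ms: np.ndarray
    mask: np.ndarray
    subject_id: int = 0

    def __post_init__(self) -> None:
        if not (self.m0.shape == self.t2star_ms.shape == self.mask.shape):
            raise ValueError("m0, t2star_ms and mask must share one shape")
        if self.subject_id < 0:
            raise ValueError("subject_id must be >= 0")
        inside = self.t2star_ms[self.mask]
        if inside.size and (inside.min() <= 0 or inside.max() > T2STAR_MAX_MS):
            raise ValueError("t2star_ms inside mask must lie in (0, 500] ms")
        if (self.m0 < 0).any():
            raise ValueError("m0 must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.m0.shape


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Zero-mean, unit-ish amplitude smooth random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    s = f.std()
    return f / s if s > 0 else f


def _ellipse(shape, center, semi_axes, angle_rad: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr, dc = rr - center[0], cc - center[1]
    ca, sa = np.cos(angle_rad), np.sin(angle_rad)
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    return (u / semi_axes[0]) ** 2 + (v / semi_axes[1]) ** 2 <= 1.0


def generate_template(rows: int, cols: int, subject_seed: int) -> ParametricMap:
    """Generate one 2D (M0, T2*) template, deterministic in ``subject_seed``.

    Parameters
    ----------
    rows, cols
        Matrix size; at least 16 each (64 x 64 matches a typical EPI matrix).
    subject_seed
        Controls head geometry and tissue layout; acts as the subject
        identity for leakage-free data splits.
    """
    if rows < MIN_DIM or cols < MIN_DIM:
        raise ValueError(f"matrix size must be >= {MIN_DIM} x {MIN_DIM}")
    rng = np.random.default_rng(subject_seed)
    shape = (rows, cols)

    center = (rows / 2 + rng.uniform(-rows * 0.03, rows * 0.03),
              cols / 2 + rng.uniform(-cols * 0.03, cols * 0.03))
    head_ax = (rows * rng.uniform(0.36, 0.44), cols * rng.uniform(0.33, 0.41))
    tilt = rng.uniform(-0.3, 0.3)
    head = _ellipse(shape, center, head_ax, tilt)

    # CSF rim just inside the head outline.
    inner = _ellipse(shape, center, (head_ax[0] * 0.90, head_ax[1] * 0.90), tilt)
    rim = head & ~inner

    # White-matter core inside the grey-matter interior.
    wm_center = (center[0] + rng.uniform(-2, 2), center[1] + rng.uniform(-2, 2))
    wm = _ellipse(shape, wm_center, (head_ax[0] * 0.55, head_ax[1] * 0.52),
                  tilt + rng.uniform(-0.2, 0.2)) & inner

    # Ventricle-like CSF blobs near the centre.
    vent = np.zeros(shape, dtype=bool)
    for sgn in (-1.0, 1.0):
        vc = (wm_center[0] + rng.uniform(-1.5, 1.5),
              wm_center[1] + sgn * cols * rng.uniform(0.04, 0.08))
        vent |= _ellipse(shape, vc, (rows * rng.uniform(0.05, 0.09),
                                     cols * rng.uniform(0.02, 0.04)),
                         tilt + sgn * 0.4)
    vent &= inner

    # A few small iron-rich / vessel-like foci.
    vessel = np.zeros(shape, dtype=bool)
    for _ in range(rng.integers(3, 7)):
        vc = (center[0] + rng.uniform(-0.5, 0.5) * head_ax[0],
              center[1] + rng.uniform(-0.5, 0.5) * head_ax[1])
        vessel |= _ellipse(shape, vc, (rng.uniform(1.0, 2.2), rng.uniform(1.0, 2.2)), 0.0)
    vessel &= inner & ~vent

    t2 = np.zeros(shape)
    m0 = np.zeros(shape)

    def fill(region, t2_lo, t2_hi, m0_mean, m0_jit, sig):
        if not region.any():
            return
        mid, half = (t2_lo + t2_hi) / 2, (t2_hi - t2_lo) / 2
        field = _smooth_field(rng, shape, sig)
        t2[region] = np.clip(mid + field[region] * half * 0.6, t2_lo, t2_hi)
        m0f = _smooth_field(rng, shape, sig)
        m0[region] = np.clip(m0_mean * (1 + m0_jit * m0f[region]), 0.05, None)

    gm = inner & ~wm & ~vent & ~vessel
    wm_only = wm & ~vent & ~vessel
    fill(gm, *TISSUE_T2STAR_MS["gm"], m0_mean=0.85, m0_jit=0.08, sig=3.0)
    fill(wm_only, *TISSUE_T2STAR_MS["wm"], m0_mean=0.70, m0_jit=0.06, sig=3.5)
    fill(rim, *TISSUE_T2STAR_MS["csf"], m0_mean=1.0, m0_jit=0.05, sig=2.0)
    fill(vent, *TISSUE_T2STAR_MS["csf"], m0_mean=1.0, m0_jit=0.05, sig=2.0)
    fill(vessel, *TISSUE_T2STAR_MS["vessel"], m0_mean=0.60, m0_jit=0.10, sig=1.5)

    t2 = np.where(head, np.clip(t2, 1.0, T2STAR_CAP_MS), 0.0)
    m0 = np.where(head, m0 * 100.0, 0.0)  # arbitrary units, ~100 peak
    return ParametricMap(m0=m0, t2star_ms=t2, mask=head,
                         subject_id=abs(int(subject_seed)) % (2**31))


def _apply_rigid(pmap: ParametricMap, k90: int, flip_h: bool, flip_v: bool,
                 angle_deg: float = 0.0) -> ParametricMap:
    """Apply a joint rigid transform (90-degree multiples, flips, optional
    small-angle nearest-neighbour rotation) to all channels."""

    def tf(a: np.ndarray) -> np.ndarray:
        out = np.rot90(a, k90)
        if flip_h:
            out = out[:, ::-1]
        if flip_v:
            out = out[::-1, :]
        if angle_deg != 0.0:
            # nearest-neighbour: never interpolates non-physical T2* values
            out = ndimage.rotate(out.astype(float), angle_deg, reshape=False,
                                 order=0, mode="constant", cval=0.0)
        return np.ascontiguousarray(out)

    mask = tf(pmap.mask.astype(np.uint8)) > 0
    t2 = tf(pmap.t2star_ms) * mask
    m0 = tf(pmap.m0) * mask
    return replace(pmap, m0=m0, t2star_ms=t2, mask=mask)


def augment(pmap: ParametricMap, seed: int) -> ParametricMap:
    """Random rotation and flip, sampled from ``seed``; channels transform jointly."""
    rng = np.random.default_rng(seed)
    k90 = int(rng.integers(0, 4))
    flip_h = bool(rng.integers(0, 2))
    flip_v = bool(rng.integers(0, 2))
    angle = float(rng.uniform(-10.0, 10.0)) if rng.random() < 0.5 else 0.0
    return _apply_rigid(pmap, k90, flip_h, flip_v, angle)


def make_template_bank(n_subjects: int, per_subject: int, rows: int, cols: int,
                       seed: int) -> list[ParametricMap]:
    """Build ``n_subjects * per_subject`` maps, one base geometry per subject.

    The first map of each subject is its untransformed base template; the
    remaining ``per_subject - 1`` are random augmentations of it.  All maps of
    a subject carry the same ``subject_id`` (its index), so any subject-level
    split is leakage-free.
    """
    if n_subjects < 2:
        raise ValueError("need >= 2 subjects for a subject-disjoint split")
    if per_subject < 1:
        raise ValueError("per_subject must be >= 1")
    ss = np.random.SeedSequence(seed)
    bank: list[ParametricMap] = []
    for sid, sub_ss in enumerate(ss.spawn(n_subjects)):
        base_seed, aug_seed = (int(s.generate_state(1)[0] % (2**31))
                               for s in sub_ss.spawn(2))
        base = replace(generate_template(rows, cols, base_seed), subject_id=sid)
        bank.append(base)
        aug_rng = np.random.default_rng(aug_seed)
        for _ in range(per_subject - 1):
            bank.append(augment(base, int(aug_rng.integers(0, 2**31))))
    return bank


def split_bank_by_subject(bank: list[ParametricMap], n_val_subjects: int
                          ) -> tuple[list[ParametricMap], list[ParametricMap]]:
    """Subject-disjoint train/validation split; the last subjects validate."""
    sids = sorted({p.subject_id for p in bank})
    if not 1 <= n_val_subjects < len(sids):
        raise ValueError("n_val_subjects must leave at least one training subject")
    val_ids = set(sids[-n_val_subjects:])
    train = [p for p in bank if p.subject_id not in val_ids]
    val = [p for p in bank if p.subject_id in val_ids]
    return train, val
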