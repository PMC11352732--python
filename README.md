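# met2star

Synthetic-data-driven T2\* mapping and BOLD-sensitivity analysis for
multi-echo fMRI.

## The problem

Multi-echo gradient-echo EPI acquires each volume at several echo times,
so the effective transverse relaxation time T2\* can be estimated per voxel
and per volume from the mono-exponential decay

S(TE&#8345;) = S&#8320; · e^(−TE&#8345;/T2\*),  R2\* = 1/T2\*.

T2\* time series are attractive for BOLD analysis — neuronal activity
changes local T2\*, and the quantitative map is comparable across scanners —
but the standard voxelwise log-linear fit (LLF) is noisy with only three
echoes: fitting log-signals voxel by voxel amplifies acquisition noise and
degrades the resulting time series.

This package implements a synthetic-data-driven alternative: a slice-wise
4-level U-net trained purely on simulated multi-echo data.  Parametric
(M0, T2\*) head phantoms are generated procedurally, pushed through the
forward decay model, corrupted with 0–5 % Rician noise, and used as
input/label pairs.  The network learns both the inverse mapping and
denoising, exploiting in-plane spatial context that voxelwise LLF cannot
see.  Everything needed to reproduce the comparison ships in the package:

- `phantom` — procedural (M0, T2\*) templates with subject-disjoint
  splitting and rotation/flip augmentation
- `signal_model` — forward model, Rician noise, LLF, T2\*-weighted echo
  combination (w&#8345; ∝ TE&#8345;·e^(−TE&#8345;/T̂2\*))
- `sddl` — the U-net estimator (pure numpy, CPU) and its training loop
- `fmri_sim` — 4D three-echo task fMRI with known ground truth: block
  design, canonical-HRF BOLD injected as a T2\* excursion, drift, noise
- `analysis` — the six-series evaluation pipeline: T2\* series (LLF /
  network), echo combinations, detrending, smoothing, first-level GLM,
  tSNR, percentage signal change, functional contrast, UFWE masks, paired
  t / Cohen's d
- `io`, `cli` — BIDS-style multi-echo NIfTI I/O, estimator checkpoints,
  an external-tool hook for MEICA-denoised series, and a `met2star`
  command-line front end
- `model` — a Model/Results wrapper: `T2StarModel(data, te_ms).fit()`
  returns a results object with maps, a validity mask and `summary()`

## Worked example

```python
import numpy as np
from met2star import T2StarModel, phantom, signal_model as sm

template = phantom.generate_template(64, 64, subject_seed=7)
img = sm.forward_signal(template, te_ms=(14.0, 28.0, 42.0))
noisy = sm.add_rician_noise(img, sigma_frac=0.02, seed=1)

res = T2StarModel(noisy.data, (14.0, 28.0, 42.0)).fit(method="llf")
print(res.summary())
```

prints

```
T2* fit results
========================================
method:            llf
echo times (ms):   [14.0, 28.0, 42.0]
grid:              (64, 64)
valid voxels:      2917 / 4096
T2* median (ms):   67.64
T2* IQR (ms):      [51.44, 92.84]
S0 median:         74.52
log-residual RMS:  2.174e-01
```

The median T2\* of ~68 ms sits in the grey-matter range of the template
(60–80 ms).  The `valid` count exceeds the ~2100-pixel head because on
magnitude data the surrounding air voxels carry Rayleigh noise that often
fits with a positive decay rate — voxelwise LLF has no notion of tissue,
which is one of its weaknesses; the network estimator's validity mask is
signal-gated instead.  The log-residual RMS of ~0.22 shows how strongly
2 % image noise is amplified in the log domain at the weak late echoes.

Training the network estimator and comparing it with LLF on held-out noisy
slices is a few more lines — see
`tests/test_acceptance.py::test_network_beats_llf_across_noise_levels` —
or one CLI call each:

```sh
met2star --seed 1 train --out est.npz
met2star --seed 1 simulate --out sim/
met2star fit --series-dir sim/ --method sddl --estimator est.npz --out t2.nii
met2star evaluate --series SDDL_T2STAR t2.nii --volumes 210 --out metrics.csv
```

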