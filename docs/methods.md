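# Methods

## Signal model

Multi-echo gradient-echo fMRI magnitude signal is modelled as
mono-exponential decay over echo time,

    S(TE_n) = S0 · exp(−TE_n / T2*) ,   R2* = 1 / T2*,

with `S0` the proton-density-weighted amplitude and `T2*` the effective
transverse relaxation time.  The baseline estimator is the log-linear fit
(LLF): per voxel, `[log S0, R2*]` solves the linear system with design rows
`(1, −TE_n)` applied to log-signals through a pseudo-inverse that is computed
once per TE set (the design is voxel-independent) and applied to all voxels
as one matrix product.  LLF is exact on noiseless data; the package's
round-trip tests hold it to 1e-8 relative error.

Numerical policy for LLF on magnitude data: signals at or below a floor
(default `1e-6 ×` the array maximum) are replaced by the floor before the
log and the voxel is flagged invalid; a non-positive fitted R2* (rising
signal, typical in air voxels) clips T2* to the upper bound and flags the
voxel; T2* is clipped to [1, 500] ms.  The 500 ms ceiling leaves headroom
above CSF while bounding the 1/R2* blow-up; 200 ms is the upper end of the
simulated tissue range.  Voxels where every echo sat at the floor
(background) carry the fill value 0.

T2*-weighted echo combination (EC) uses per-voxel weights

    w_n ∝ TE_n · exp(−TE_n / T̂2*),   normalized to Σ w_n = 1,

with `T̂2*` a static map estimated from the time-averaged series — by LLF
for the conventional EC series, by the network for the network-weighted EC
series.  Weights are static over time by construction.

## Rician noise

Magnitude noise is Rician: `|(S + g1) + i·g2|` with `g1, g2 ~ N(0, σ)`.
The reference amplitude for the fractional noise level is the maximum of
the noiseless first-echo image of the slice (the largest-amplitude echo),
making the fraction a stable per-slice SNR knob; the published range 0–5 %
never states its referent, so this is a package choice.  During training
the fraction is drawn uniformly from [0, 0.05] per slice.

## Procedural parametric phantoms

Templates are 64×64 (M0, T2*) pairs: an elliptical head with a CSF rim,
a white-matter core, ventricle-like CSF blobs, and a few small iron-rich
foci, each class carrying smooth within-class variation from filtered
noise fields.  Tissue T2* ranges at 3 T: WM 45–60 ms, GM 60–80 ms, CSF
150–250 ms clipped at 200 ms, vessels/iron 15–35 ms; M0 is scaled to ~100
at CSF.  Background is exactly zero in both channels so the estimator can
learn masking.  One top-level seed fixes a "subject" (geometry + layout);
augmented copies (90°-multiple rotations, flips, optional ±10° small-angle
rotation with nearest-neighbour resampling so no non-physical interpolated
T2* values appear at tissue borders) share the subject id, and all data
splits are subject-disjoint.

What the phantoms do not emulate: real cortical folding, B0/B1 field
structure, partial-volume mixtures at tissue interfaces, and
between-subject anatomical variability beyond ellipse geometry.  Passing
tests therefore demonstrate correct inference under the stated forward
model and noise, not anatomical generalization to real scans.

## The network estimator

A 4-level U-net (two 3×3 conv+ReLU per level, 2×2 max-pool, nearest ×2
upsampling with a channel-halving conv, skip concatenation, 1×1 output
head) maps an N-echo slice to the two parametric channels (M0, T2*).  It
is implemented directly on numpy: channels-last im2col + BLAS GEMM
convolutions with hand-written backward passes and Adam.  Gradient
correctness is verified against finite differences (exact to ~1e-9 in a
float64 variant of the layers) and the forward convolution against scipy.

No normalization layers are used: the regression must preserve absolute
intensity calibration end to end (the M0 output is tied to the input
scale), and feature normalization measurably degraded both validation loss
and held-out T2* error when tried.

Normalization: inputs are divided by the slice's first-echo maximum; the
M0 label shares that constant so de-normalization at inference needs no
label information; T2* labels are divided by 200 ms.  Loss is MSE over
both channels, equally weighted, matching the evaluation metric.  Training
samples random 32×32 crops (batch 16); one epoch draws 4 crops per slice,
i.e. one expected pixel coverage of a 64×64 slice.  Inference runs full
slices — valid because the network is fully convolutional — and clips T2*
to the fit bounds wherever the first echo exceeds 2 % of the slice
maximum.

Training profiles.  The full-scale protocol follows the published recipe:
Adam at learning rate 1e-4, batch 16, crop 32×32, training until the
lowest validation loss (`TrainingConfig` defaults).  The reduced-scale
profile used by the test suite and the acceptance script — 600 training /
120 validation slices from 12 subjects, split 5:1 by subject, 20 epochs,
base width 16 — doubles the learning rate to 2e-4: at 1e-4 the validation
loss is still falling steeply at epoch 20, whereas 2e-4 reaches the
plateau region of the curve within the epoch budget, honouring the
train-to-convergence stopping rule at reduced compute.  The best-validation
checkpoint is always returned, and the recorded history exposes the whole
curve.

Observed reproducibility: training is bit-reproducible under a fixed seed
on fixed hardware (all randomness flows from `TrainingConfig.seed` through
one generator; the only floating-point nondeterminism would come from BLAS
thread scheduling, and the reference environment is single-threaded).

## Task fMRI simulation

The simulator emulates a three-echo EPI protocol: TR 2 s, TEs 14/28/42 ms,
210 volumes, 64×64 matrix, ON/OFF blocks of 10 volumes starting OFF.  The
BOLD effect is injected as an additive task-locked T2* excursion: inside
the activation mask, T2*(t) = baseline + Δ·h(t), with h the boxcar
convolved with a canonical double-gamma HRF (delay 6 s, undershoot 16 s,
ratio 6, sampled at TR) normalized to peak 1, so Δ is the peak excursion
in ms.  The default Δ of 3 ms (~4–5 % of a GM baseline) is a
literature-informed magnitude for strong sensory/motor activation, not a
measured value.  Scanner drift is a multiplicative polynomial
`1 + a·u + b·u²` (u = normalized run time; defaults a = 1 %, b = −0.5 %
over the run) applied to all echoes of a volume equally — which is why the
true T2* course is drift-free by construction: a common multiplicative
factor shifts log S0 and leaves the log-linear slope untouched.  Rician
noise is drawn independently per volume with σ referenced to the baseline
first-echo maximum.  Motion, physiological noise and EPI artifacts are not
simulated; the pipeline consumes realigned data by contract.

## Evaluation pipeline

- **Derived series.**  4D T2* series by voxelwise LLF (one GEMM per
  series) or by batched slice-wise network inference; EC series with
  static weights from the time-averaged series' T2* map (LLF or network).
  Externally produced MEICA-denoised series enter only through a
  command-line hook that stages echo NIfTIs, runs the external tool, and
  records the exact command in provenance; when the tool is absent the
  pipeline degrades to the four internal series.
- **Detrending** removes the least-squares constant+linear+quadratic fit
  per voxel and restores the temporal mean.
- **Smoothing** is volume-wise Gaussian, σ_vox = FWHM/(2.3548·voxel size),
  default 7 mm on 3.5 mm voxels, reflective boundaries.
- **GLM**: ordinary least squares per voxel on [peak-normalized
  HRF-convolved task regressor | optional nuisance columns | constant];
  t = β_task / √(σ̂²·(XᵀX)⁻¹₁₁); zero-residual fits report a 1e6 sentinel
  so maps stay finite.  Nuisance regressors (e.g. motion or physiological
  recordings) are accepted as an arbitrary matrix.
- **tSNR**: the denominator is the SD of the quadratic-detrend residual;
  the numerator is the intercept of that trend model in raw acquisition
  time (the modelled signal level at run start).  The intercept estimates
  the temporal mean for drift-free data and makes tSNR exactly invariant
  to added `a·t + b·t²` drift, which the raw mean is not; near-zero-
  variance voxels report 0.
- **PSC** = 100 · SF · β_task / β_constant, with SF the maximum of a
  single-block reference response evaluated on a 16× super-sampled design
  grid, expressed on the same scale as the GLM's peak-normalized
  regressor (SF ≈ 1.03 for the 10-volume block at TR 2 s).
- **Functional contrast**: detrend → optional smooth → ROI average →
  mean(ON) − mean(OFF) using the unconvolved condition labels (no
  hemodynamic-lag shift; with a lag shift the contrast would rise
  slightly, but the unshifted convention keeps the measure model-free).
- **UFWE mask**: per series, voxels whose Bonferroni-corrected two-sided
  task p-value is below α (default 0.001); the analysis ROI is the union
  across series.  Bonferroni was chosen over random-field theory because
  it is exactly implementable and conservative.
- **Paired comparisons**: two-tailed paired t-test and Cohen's d =
  mean(diff)/SD(diff) with the n−1 SD; the reported d is positive when the
  second pipeline scores higher.

## Problem sizes in the shipped study

The test suite and acceptance script run the whole study at sizes chosen
to keep a single-CPU run comfortable: 600/120 training/validation slices
from 12 subjects (the full-scale recipe is 4500/900 from more subjects),
base width 16 (default 32), 100 held-out slices per noise level, 10
simulated subjects for the paired comparisons, single-slice 210-volume
task runs, and 10⁵ null voxels for GLM calibration.  These sizes are the
package's reduced study conditions; all of them are plain arguments, so a
larger run only changes numbers, not code paths.

## Known limitations

- The estimator is trained for one fixed TE set; a new protocol needs a
  retrained model (the checkpoint records its TE list and refuses
  mismatched inputs).
- Phantom realism bounds what the simulation study can claim about real
  scans (see above); in particular the network's advantage over LLF is
  demonstrated under matched forward-model assumptions.
- MEICA-based series depend entirely on the external tool; the package
  never reimplements component classification.
- The Rician noise referent and the hemodynamic-lag convention for the
  functional contrast are package choices where the published protocol is
  silent; both are recorded here and adjustable in code.
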