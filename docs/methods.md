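# Methods

This note documents the models, algorithms and numerical choices behind
`pulsebp`, what the synthetic-data generator does and does not emulate, and
the design decisions made where the published constants leave the procedure
under-determined.

## Problem setting

The task is regression from a single-cycle PPG pulse (plus features of its
10 s context) to the cycle's systolic and diastolic arterial pressure in
mmHg. A record is reduced to a set of (feature vector, cycle waveform,
[SBP, DBP]) triples; a model is fit on a random ROI-level 85/15 split and
graded with device-certification statistics (AAMI, BHS, Bland–Altman).

Note the split is at ROI level, not subject level: cycles of one synthetic
record can land on both sides. This mirrors the published protocol but is
optimistic relative to subject-wise generalization; for leakage-free
evaluation, split by `parent_id` (each `DatasetBundle` block is one source
record, so a block-wise split is subject-wise).

## Synthetic PPG + ABP generator

Each cardiac cycle is a two-Gaussian pulse
`p(t) = A1·exp(−(t−μ1)²/2σ1²) + A2·exp(−(t−μ2)²/2σ2²)`: the first hump is
the systolic upstroke and peak, the second the dicrotic (reflected) wave,
giving the waveform a detectable systolic peak, dicrotic notch and
diastolic peak — every landmark the feature extractor uses. Per-record
heart rate is uniform on 60–100 bpm (the adult resting band); per-cycle
latents (amplitude A1 ∈ [0.7, 1.3], dicrotic ratio A2/A1 ∈ [0.2, 0.5],
systolic width σ1 ∈ [0.09, 0.15]·T, dicrotic delay μ2−μ1 ∈ [0.30, 0.45]·T,
decay width σ2 = [1.2, 1.6]·σ1) wander around record-level means with an
AR(1) perturbation (jitter coefficient 0.25), so consecutive cycles are
similar but not identical.

Ground-truth pressures are **linear in the latents**:
`SBP = 10 + 60·A1 + 5.5/σ1[s]`, `DBP = 32 + 170·σ2[s] + 28·(A2/A1)`, plus
optional i.i.d. Gaussian label noise. The coefficients put SBP in roughly
[90, 180] mmHg and DBP in [50, 110] mmHg — the bands device standards
require a test cohort to cover — and keep SBP > DBP by a ≥ 10 mmHg pulse
pressure guard. Linearity makes feature-based recovery provably possible,
so an end-to-end error far above the label-noise floor indicates a pipeline
defect, not an unlearnable target. The ABP channel is a per-cycle affine
rescaling of the pulse, so per-cycle max/min reproduce the stored labels
exactly; ROI labels are the max/min of ABP over the ROI window.

Artifacts are injected separately: sinusoidal baseline drift, white noise
at a configured SNR, and saturation plateaus (runs of ≥ 3 identical
samples, one per 10 s span with a configured probability) — exactly the
defects the QC stage must reject.

**What the generator does not emulate**: arrhythmia and beat-to-beat
morphology pathology, respiratory modulation, motion artifacts with
physiological structure, sensor transfer functions, or the nonlinear and
subject-specific latent→pressure physiology of real patients. Passing
tests on these synthetics demonstrates internal correctness of the
pipeline (detection, feature math, selection, optimization), not clinical
accuracy on real PPG.

## Preprocessing

* **Filter**: fifth-order Butterworth band-pass 0.5–5 Hz, applied
  forward–backward (`sosfiltfilt`) so peak times are not phase-shifted.
* **Segmentation**: non-overlapping 10 s windows; each min–max normalized
  to [0, 1]. Zero-range windows are flagged `degenerate_range`.
* **Flat-run QC**: three consecutive *exactly equal* samples fail the
  segment. The comparison runs on raw, pre-filter values, because
  saturation produces repeated ADC codes that filtering would smear.
* **Peak detection** (two event-related moving averages): the segment is
  mean-centered, clipped below zero and squared, then smoothed with
  uniform kernels of round(w·fs) taps (w₁ = 0.667 s → 42 taps,
  w₂ = 0.111 s → 7 taps at 62.4725 Hz). Candidate blocks are runs where
  the peak average exceeds `PPG_beat + β·z̄` (β = 0.03, z̄ the mean of the
  emphasized series); blocks shorter than the peak-kernel width are
  discarded; each surviving block contributes one peak at its amplitude
  maximum (ties → leftmost). Centering restores the zero level removed by
  the [0, 1] normalization and squaring suppresses the dicrotic wave,
  which otherwise produces a second threshold crossing per cycle.
* **Peak-count QC**: ≥ 8 systolic peaks per 10 s segment.
* **ROIs**: for each interior peak p_i the window [p_{i−1}, p_{i+1}]
  inclusive — one full cycle plus the flanking downstroke and upstroke —
  labelled by ABP max/min over the window, then shaped to exactly 80
  samples (zero-pad tail / truncate; the pre-shaping length is kept so
  landmark analysis ignores padding).

## Feature registry (138 scalars)

The catalogue has 73 items in six groups; family items expand
multiplicatively: the six morphological decile items × 10 levels, the five
sub-band ratios, overall trend × 3 (amplitude/mean/variance), and
short-time energy / zero-crossing rate × 2 (mean + variance over the 20
frames). The frequency group carries the six spectral-peak scalars plus
three STFT-derived scalars (instantaneous-frequency mean and standard
deviation, spectral entropy). Totals: 31 + 60 + 4 + 9 + 19 + 15 = 138.
The registry object is the single source of truth for order, grouping and
the per-target (SBP/DBP) selection annotations, and validates its own
budget at construction.

Numerical conventions worth stating:

* kurtosis is Pearson (normal → 3);
* the pulse K value is (mean − min)/(max − min) over the cycle;
* decile crossing times (SW/DW) use linear interpolation between samples —
  index rounding would quantize at 16 ms steps at 62.47 Hz;
* the dicrotic-notch search runs in (peak, peak + 0.5·t_PI) as a local
  minimum, falling back to the second-derivative maximum, then NaN; the
  diastolic peak is the first local maximum after the notch, falling back
  to the notch;
* derivative landmark times use plateau-tolerant local-extrema detection
  with a global-extremum fallback for monotone traces;
* spectral-peak features use an FFT zero-padded to 16 × nextpow2(N) for a
  fine frequency grid, with the fundamental constrained to 0.5–5 Hz and
  secondary components required to sit ≥ 0.25 Hz from already accepted
  peaks (rejecting leakage sidelobes); magnitude-weighted moments
  (centroid, bandwidth, entropy) instead use the unpadded DFT, because
  zero padding spreads magnitude into sinc sidelobes and biases weighted
  means;
* short-time frames: 20 frames of 80 samples cannot tile a 10 s segment
  at 62.47 Hz (625 samples) disjointly, so frames overlap with hop
  floor((L−80)/19), preserving both constants;
* the zero-crossing rate is computed on mean-removed frames: a strictly
  positive pulse train never crosses zero, so the raw statistic is
  degenerate (the raw variant remains available via `demean=False`);
* undefined features (missing notch, level never crossed, flat
  derivative) become NaN with a mask — a vector is always complete — and
  are median-imputed on the training set before selection/regression.

## SVM-RFE

Blood pressure is continuous, so the linear SVM inside RFE runs in
regression mode (liblinear epsilon-SVR, C = 1, ε = 0.1); the primal
coefficient vector plays the role of the classification weight vector.
Features are median-imputed and z-scored **once** before the loop (so
squared weights are commensurable); the target is z-scored for the
internal fits only (the epsilon tube is scale-sensitive; an affine target
rescaling does not change the elimination ranking beyond solver
tolerance). Each iteration removes the two smallest `w_i²`, ties broken
toward the lower registry index; 138 → 60 takes exactly 39 iterations.
Per-target selections (matching the catalogue's separate SBP/DBP
annotations) are the primary path; the `merged` mode ranks by the mean of
the two elimination ranks to feed a single two-output network.

## Two-branch network

* Feature branch: dense(60 → 64) + batch norm, treated as a 1-channel
  64-step sequence; two residual blocks (Conv1D 64 filters, kernel 3,
  stride 1 → batch norm, shortcut added, ReLU; the first block's shortcut
  is a 1×1 projection to match channels); global average pooling → 64.
* Waveform branch: 80×1 sequence → BiLSTM(100, full sequence) →
  BiLSTM(100, last step) → batch norm → 200.
* Head: concatenation (264) → linear dense → [SBP, DBP].

The dense-64 front and the global-average-pooling reduction are the two
places the architecture is under-determined by its printed constants; this
combination totals 340,354 trainable parameters, within 1.3% of the
≈ 336 K budget the architecture is known to occupy. Forward and backward
passes (including backprop-through-time for the LSTMs and the batch-norm
gradient) are implemented in NumPy in float32 and verified against
numerical differentiation in float64.

Training: joint MSE over both outputs, Adam with initial learning rate
0.001, minibatches of 64, up to 150 epochs, early stopping on a 15%
validation split of the training data (patience 10, best weights
restored). Features are z-scored and targets standardized internally;
predictions are inverse-transformed to mmHg. All stochastic elements
(initialization, shuffling, splits) derive from `random_state`.

## Evaluation

Errors are reference − prediction. SD is taken about the mean difference
with the 1/(n−1) normalization. AAMI comparisons are inclusive
(|ME| ≤ 5, SD ≤ 8 mmHg); BHS thresholds are inclusive on both the error
(≤ 5/10/15 mmHg) and the percentage (≥), following the tabulated grading
thresholds; a grade requires all three cumulative thresholds. Bland–Altman
limits are mean ± 1.96·SD of the differences. Pearson correlation returns
NaN (flagged) for zero-variance inputs.

## Problem sizes used in the tests

The test suite exercises the full pipeline at sizes a single CPU handles
comfortably: peak-detection properties on 60 s records at 60/75/100 bpm;
RFE recovery on 150 × 138 designs over 10 seeds; end-to-end recovery on
~2,500 ROIs (45 records × 60 s) with 3 mmHg label noise, trained for up to
30 epochs with patience 6 — enough for the held-out MAE to fall within
twice the label-noise floor for both targets. The published protocol's
full 150-epoch budget is available through configuration.

## Known limitations

* The NumPy network trains on CPU only and is intentionally compact; it
  is not a deployment implementation (no pruning/quantization, no
  latency accounting).
* Saved models use an `.npz` + JSON format specific to this package and
  are not interchange formats.
* The generator's latent→pressure map is linear by design; model
  comparisons on these synthetics say nothing about ranking on real,
  nonlinear physiology.
* No WFDB reader is included; records enter via HDF5 or CSV.
* The ROI boundary convention (inclusive peak-to-peak window) and the
  label convention (ABP max/min over the window) are one reading of the
  published description; both are isolated behind `extract_rois`.
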