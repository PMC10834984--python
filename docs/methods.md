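# Methods

## Overview

`ecgsift` classifies long single-lead ECG recordings into three diagnostic
classes — arrhythmia (ARR), congestive heart failure (CHF) and normal sinus
rhythm (NSR) — by converting each recording into a set of images and
classifying the images with a compact convolutional network enriched with
scale-invariant keypoint features:

1. **Pre-processing.** Each record is smoothed with a centered moving
   average, min–max normalised to [0, 1] per record, and cut into six
   equal-length contiguous segments (a 65,535-sample record yields six
   segments of 10,922 samples; the 3 trailing samples are discarded).
2. **Rendering.** Each segment is drawn as a black 1-px polyline on a white
   200 × 200 × 3 raster, axis-free, no antialiasing, y autoscaled to the
   segment's own range.
3. **Keypoint features.** A SIFT detector (difference-of-Gaussians extrema,
   Taylor subpixel refinement, contrast and edge rejection, 36-bin
   orientation assignment, 4 × 4 × 8 = 128-d descriptors) runs on each
   raster; detected keypoints are drawn back onto the image as red circles,
   so the classifier input stays an H × W × 3 image. A HOG descriptor is
   available as the comparison extractor.
4. **Balancing.** SMOTE on the flattened image vectors grows each minority
   class to the majority count (576 per class for the default dataset).
5. **Classification.** Three blocks of (3 × 3 valid convolution, 32 filters,
   ReLU, 2 × 2 max-pool stride 2), flatten, dropout 0.5, dense(64, ReLU),
   dense(3, softmax); Adam (lr 10⁻³) on categorical cross-entropy, batch 16,
   30 epochs by default.
6. **Evaluation.** One-vs-rest accuracy/precision/recall/F1/specificity
   (macro-averaged), plain fraction-correct accuracy, the multiclass
   Matthews correlation coefficient computed from the confusion-matrix
   totals (diagonal sum c, grand total s, column totals p_k, row totals
   t_k), Cohen's kappa, one-hot-vs-probability RMSE, stratified hold-out and
   k-fold cross-validation, and one-way ANOVA with Tukey HSD for comparing
   metric groups across models.

## The synthetic-data generator

Public ECG corpora cannot ship with the package, so the generator emulates
the study conditions: 96 ARR + 30 CHF + 36 NSR records of 65,535 samples.
Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) with textbook-ish
amplitudes (R = 1.0, T = 0.3, P = 0.15, Q = −0.10, S = −0.15) placed on an
RR-interval schedule drawn per class:

| class | rr_mean (s) | rr_sd (s) | ectopy | R scale | AM depth |
|-------|------------|-----------|--------|---------|----------|
| NSR   | 0.8        | 0.04      | 0      | 1.0     | 0.25     |
| ARR   | 0.8        | 0.25      | 0.15/beat (inverted, widened QRS) | 1.0 | 0.15 |
| CHF   | 0.7        | 0.01      | 0      | 0.6     | 0.05     |

These choices force the RR-interval coefficient of variation to order
ARR > NSR > CHF — the ordering clinicians expect — and give CHF its
attenuated R waves. Additive white Gaussian noise (SD 0.02 in R-peak units)
is applied last. The default sampling rate is 128 Hz, so a record covers
about 512 s, a few hundred beats.

**Why the amplitude-modulation (AM) envelope exists.** Six-way segmentation
of a 512-s record gives ≈ 85 s per image. At 200 px — let alone the 50-px
benchmark scale — individual beats are sub-pixel, and the per-segment y
autoscaling erases absolute amplitude, so RR statistics and the R-wave
attenuation alone leave NSR and CHF renderings as nearly identical filled
bands. Real recordings carry slow autonomic/respiratory amplitude
modulation that is classically *blunted* in heart failure; the generator
models it as a multiplicative envelope `1 + depth·sin(2π·0.1 Hz·t + φ)`
with depth 0.25 (NSR), 0.15 (ARR) and 0.05 (CHF). This carries class
identity at raster scale (wavy vs. flat band edges; ARR additionally shows
deep ectopic spikes), so the rendered images are separable — a linear model
on the raw 50-px pixels already separates the classes, and the package's
separability property (a linear classifier on RR-CV and mean R amplitude
exceeding 90% accuracy) still holds on the raw signals.

**What the generator does not emulate:** real PQRST morphology variants,
baseline wander, electrode artefacts, atrial fibrillation waveforms,
inter-patient variability, or the actual difficulty of the public corpora.
Passing the end-to-end benchmark therefore shows the pipeline's plumbing
learns planted class structure end to end — not that it reaches any
particular accuracy on clinical data.

## Rendering

Sample index maps linearly to x ∈ [0, width−1]; the segment's own
[min, max] maps to [height−1−pad, pad] with pad = 2 px, larger values
higher. Rasterisation is pure integer span-filling (consecutive samples in
the same or adjacent pixel columns fill vertical runs; sparser polylines
walk the columns), so outputs are bit-identical across platforms, and
rendering is exactly invariant to global amplitude scaling of a segment. A
constant segment draws a single mid-height horizontal run. Line width > 1
dilates the 1-px trace with a square structuring element. Dense multi-beat
segments can ink more than half the raster; the >50%-background property is
meaningful for figure-like traces with a few samples per column. The y
scale is switchable to `global` (a fixed [0, 1] range shared by all
segments of a record) for ablation.

## SIFT implementation notes

* Scale space: `n_intervals + 3` Gaussian levels per octave at
  σ = base_sigma·k^i, k = 2^(1/n_intervals); defaults 4 octaves (fits
  200-px images; 3 at 50 px), 3 intervals, base σ 1.6. Kernels are
  truncated discrete Gaussians renormalised to sum 1, borders reflected.
  No initial 2× upsampling. Each next octave starts from the level at
  2·base σ, downsampled by 2 (floor).
* DoG is the elementwise difference of adjacent Gaussian levels.
* Extrema are voxels strictly above or below all 26 scale-space neighbors;
  borders excluded.
* Localization solves the second-order Taylor system with finite
  differences, re-centers while any offset component reaches 0.5 (max 5
  iterations), and rejects on |D(â)| < 0.03 (contrast, on [0, 1] images)
  or tr(H)²/det(H) ≥ (r+1)²/r with r = 10 (edges). Both thresholds are the
  canonical defaults and sit in the configuration.
* Orientation: 36-bin magnitude-weighted histogram under a Gaussian window
  of 1.5× the keypoint scale, two passes of circular [1,1,1]/3 smoothing,
  one keypoint per peak ≥ 80% of the maximum, parabolic peak interpolation.
* Descriptor: gradients rotated into the keypoint frame, trilinear binning
  into a 4 × 4 × 8 histogram with Gaussian spatial weighting, L2
  normalisation, clamping at 0.2, renormalisation.
* Fusion with the CNN: the stated classifier input is an H × W × 3 image,
  so keypoints are rasterised onto the rendering as red circles of radius
  round(σ) with a 1-px stroke (`fusion: overlay`); descriptors are still
  computed and persisted for inspection, and `fusion: passthrough` feeds
  the raw rendering for ablation. SURF is not implemented.

Everything in the feature module is deterministic.

## CNN

Implemented in numpy (float32) with im2col/BLAS convolutions; training is
exactly reproducible for a fixed seed — there are no nondeterministic
kernels. Padding is `valid`, giving the 200→198→99→97→48→46→23 spatial
trace and a flatten width of 16,928. Dropout (rate 0.5) sits between
flatten and the hidden dense layer; the hidden width 64 is a configuration
default. Adam uses the conventional defaults (lr 0.001, β₁ 0.9, β₂ 0.999).
Training aborts with a diagnostic on a non-finite loss.

## Balancing and leakage control

SMOTE runs in flattened pixel space (the balanced vectors reshape back to
images for training), with k = 5 neighbors (effective k is capped at class
size − 1) and uniform interpolation weights; synthetic rows are flagged
with their parent pair. The file-based `balance` stage balances the whole
image set — mirroring a workflow where balancing precedes training — while
the hold-out and k-fold harnesses re-run SMOTE strictly inside each
training partition, so no synthetic row ever derives from a test row.

## Cross-validation and group comparison

The stratified k-fold splitter keeps per-class fold sizes within one and
round-robins each class's remainder starting where the previous class's
extras ended, so total fold sizes also differ by at most one (972 samples,
k = 5 → 195/195/194/194/194). Hold-out uses per-class rounded stratified
sampling (default test fraction 0.2 → 194 of 972).

ANOVA is the standard fixed-effects decomposition (SS_between/SS_within,
F = MS_between/MS_within, p from the F survival function). Tukey HSD uses
SE = √(MS_within·(1/nᵢ + 1/nⱼ)/2) so q = |Δmean|/SE is on the studentized-
range scale; critical values and p-values come from the exact studentized-
range distribution rather than a printed table.

## Problem sizes and the smoke configuration

`PipelineConfig.smoke()` is the package's reduced-scale study: the default
162-record dataset, 50 × 50 renders (3 SIFT octaves), 10 training epochs.
On the synthetic classes the CNN reaches its training plateau within about
three epochs, so 10 epochs is ample; the native 200 × 200 / 30-epoch
configuration is the default for real use and runs in roughly one to two
hours on one CPU. The acceptance script and the end-to-end tests use the
smoke configuration; structural checks (record/segment/image counts,
descriptor width, flatten width) run at the native scale.

## Numerical choices and degenerate inputs

* Min–max normalisation of a constant signal returns all 0.5.
* Rate metrics return 0 with a warning flag on zero denominators; MCC
  returns 0 when its denominator vanishes (e.g. single-column
  predictions); kappa returns 1 when P_e = P_o = 1 and a flagged 0 when
  P_e = 1 ≠ P_o.
* SMOTE neighbor ties break by row index (stable sort).
* Prediction ties resolve to the lowest class index.
* RR intervals are truncated at 0.3 s so ARR schedules stay causal.

## Known limitations

* The generator is a phenomenological beat model, not a dynamical ECG
  simulator; results on it do not transfer to clinical recordings.
* SMOTE in 7,500-d pixel space is the most literal reading of balancing
  "the dataset of images"; interpolated pixel vectors are blurry image
  mixtures, which is inherent to that reading.
* At the 50-px smoke scale few keypoints survive the contrast/edge tests,
  so the overlay contributes less than at 200 px.
* The ANOVA/Tukey utilities compare arbitrary metric groups; the package
  does not prescribe which model metrics to feed them.
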