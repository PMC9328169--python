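# Methods

This note documents the models, procedures, numerical choices, and known
limitations behind `qrstangle`.

## Conventional angle computation

A signal-averaged VCG beat is a trajectory v(t) = (x(t), y(t), z(t)) in mV.
The QRS and T loops are the segments between their respective onsets and
offsets after subtracting the loop origin v₀, the componentwise median of
the 25 ms window ending at the QRS onset. Windows are inclusive of both
endpoints; with τ₀ = 25 ms this is round(τ₀·fs) + 1 samples (13 at 500 Hz,
using banker's rounding of 12.5). A window that would start before the
first sample is clipped to sample 0 with a warning. The median of an
even-length window is the mean of the two central order statistics,
componentwise.

Each loop's dominant vector is the mean of all loop samples whose magnitude
is at least 70 % of the loop's maximal sample magnitude; the threshold
comparison is inclusive, and argmax ties are broken by the earliest sample
for determinism. The single-sample maximal-magnitude variant is also
provided (`method="max"`) but the averaged variant is the default because
it is more robust when loop morphology is complex. The angle is computed as
atan2(‖u₁ × u₂‖, u₁ · u₂), which covers obtuse angles and avoids the
division-by-zero and sign ambiguity of forming arctan of the ratio
directly. Degenerate loops (e.g., a flat T wave) raise an error rather than
returning a silent 0°.

Fiducial refinement (adjusting loop onsets/offsets before extraction) is
exposed as a pluggable hook defaulting to the identity; the refinement
rules used alongside clinical delineators are not reproduced here.

## Kors transform

Only 8 of the 12 standard leads are independent; III, aVR, aVL, aVF are
fixed linear combinations of I and II and are recomputed from them when
needed, never fed to the matrix. The 3×8 regression coefficients are stored
in `src/qrstangle/data/kors_matrix.tsv` (lead-labeled, transcribed from the
published Kors regression matrix) so they can be audited as data rather
than read from code.

## Preprocessing

- **Filtering.** Zero-phase (forward-backward) Butterworth high-pass at
  0.5 Hz and low-pass at 45 Hz. The orders are not prescribed by the
  procedure this implements; 4th order for both is used as common ECG
  practice. Because the 0.5 Hz filter's impulse response spans roughly two
  seconds, the `sosfiltfilt` edge padding is extended to 3/f_c seconds;
  with the default short padding the boundary transient measurably
  contaminates the first and last beats of a 10 s record, which matters
  once T-wave magnitudes are small.
- **R peaks.** A lightweight derivative-energy detector with an adaptive
  threshold and a 250 ms refractory period runs on lead II when no
  annotations are supplied. It is plumbing: synthetic records carry
  ground-truth peaks, and clinical workflows would use a dedicated
  delineator.
- **Beat quality.** A beat is kept when its Pearson correlation with the
  lead's median-beat template is ≥ 0.9 (configurable). This is a
  template-correlation proxy for published signal-quality criteria whose
  detailed thresholds are not reproduced here.
- **Eligibility.** Records with fibrillation/flutter rhythms are excluded;
  any lead with strictly more than 50 % poor beats makes the record
  unanalyzable; with a bradycardia/tachycardia/sinus-arrhythmia flag the
  record is kept only when at least 70 % of all beats (pooled over leads)
  pass.
- **Averaging.** Good beats are aligned at the R peak and averaged
  samplewise over a fixed window, 300 ms before to 500 ms after the peak
  (configurable; the exact window is not prescribed). Beats truncated by
  the record edges are excluded.
- **Model input.** Averaged beats are polyphase-resampled to 250 Hz and
  zero-padded at the end to exactly 550 samples (trailing padding keeps
  fiducial indices stable). Sex is encoded 0 (male) / 1 (female); age is
  divided by 100 and clipped to [0, 1].
- **Delineation of the averaged beat.** QRS and T windows are found by
  magnitude thresholds on the baseline-corrected vector magnitude (5 % of
  the R magnitude for QRS bounds, 10 % of the T peak for T bounds). This
  is deliberately simple and adequate for averaged beats with distinct
  lobes; it is not a general PQRST delineator.

## Labeling and splitting

Labels are computed from the averaged X, Y, Z beats by the conventional
method above. The morphological class is one of NORM, MI, CD, STTC, HYP,
or LOWM; a record is LOWM when ‖u_T‖/‖u_QRS‖ < 0.1 (strict), and LOWM
overrides the diagnostic class so the six classes are mutually exclusive.
Multi-label diagnostic metadata is resolved to the first listed class.
Classes with fewer than 100 labeled records (configurable, counted after
quality exclusions) are dropped before splitting.

The split is stratified by class × sex × 5° angle bin (bins [i, i+5) with
[175, 180] closed). Within each stratum round(0.8·n) records (ties rounded
up) are drawn uniformly into training — round(0.5·n) for LOWM, which is
more error-prone and deliberately less represented in training. Identical
seeds reproduce the assignment exactly.

## Network and loss

The regressor maps (550 × j leads, sex, age) → 6 outputs interpreted as
û_QRS and û_T; α̂ is the angle between them. Feature extraction uses D
blocks: block 1 is a depthwise convolution (k/j kernels per lead, size 3,
stride 1, 'same' padding) + layer normalization + LeakyReLU(0.1); blocks
2…D−1 hold two conv/LN/LeakyReLU structures with a 1×1-conv residual
connection and end in max pooling (pool 2, stride 2); channel counts are k
in block 2 and double per subsequent residual block; block D repeats the
double structure and ends in global average pooling followed by dropout
(p = 0.25). The head is three dense layers (64 and 32 units by default,
configurable; the exact widths are an open choice), the first receiving the
pooled features concatenated with the two metadata scalars, the first two
followed by LN + LeakyReLU, the last linear with six outputs. No pooling is
applied when D = 2 (no residual blocks exist). The whole network and its
backpropagation are written in NumPy; correctness of every layer's backward
pass is verified against finite differences in the test suite.

**Layer normalization axis.** The normalization is described as balancing
intermediate features to zero mean and unit standard deviation with scale
and shift trainable per feature map. This package computes the statistics
per feature map, i.e., over the time axis of each channel (dense layers
normalize over the feature axis). The alternative reading — normalizing
across channels at each time step — was also implemented and compared: it
forces every time step, including the long isoelectric baseline, to unit
scale, which dilutes the localized QRS/T information that global average
pooling must preserve and slows convergence several-fold at the data scales
this package targets. The per-feature-map reading is therefore the
package's interpretation and default.

The loss is L = w₁(L_d(u_QRS, û_QRS) + L_d(u_T, û_T)) + w₂·L_α. Both
vectors are unit-normalized inside L_d only (raw-magnitude labels are
stored), so L_d ∈ [0, 2] with 2 at antiparallel directions; L_α is the
batch-mean absolute angle difference in radians, putting the two terms on
comparable scales. α̂ is always recomputed from the predicted vectors, so
the loss is zero exactly when both predicted directions match the targets
up to positive scale. Analytic gradients of the loss w.r.t. the predicted
coordinates are implemented in closed form; at angles of exactly 0 or π the
angle-term gradient is clamped (sin α ≥ 1e-8), and a zero distance
contributes a zero subgradient.

Training uses Adam (standard moments; the optimizer is not prescribed and
Adam is the conventional choice for this model family) with batch size 8,
initial learning rate 0.001, halved every 20 epochs, 100 epochs by default.
Runs are reproducible under a seed. Supported lead subsets out of the box:
XYZ, {I, aVF, V2, V6}, {I, II, aVF, V2}, {I, II, aVL, aVR}, plus arbitrary
subsets; the per-subset default architectures are D = 4, k = 8 for XYZ and
D = 3, k = 16 for reduced-lead subsets, with (w₁, w₂) = (0.8, 0.2), the
weighting that performs best.

## Evaluation

Errors are εᵢ = |α̂ᵢ − αᵢ| for the metrics (RMSE, mean ε̄, median ε̃) and
signed α̂ᵢ − αᵢ for Bland-Altman. Confidence intervals use the
nonparametric bootstrap (5000 resamples by default) with the bias-corrected
percentile method. Bland-Altman bias is the **median** difference and the
limits of agreement are bias ± 1.45·iqr; quartiles use linear interpolation
of order statistics (type 7). Spearman ρ uses average ranks for ties and is
flagged undefined for constant input. A Kolmogorov-Smirnov normality check
of the error distribution is reported as a diagnostic only — the bootstrap
is used regardless. Strata: all records, NORM, and pooled cardiac disease
(MI, CD, STTC, HYP, LOWM). The per-bin profile reports ε̄ with a bootstrap
CI per 5° bin of the target angle and flags bins backed by fewer than 200
training records as underrepresented.

## Synthetic data generator

Each beat is a two-dipole model: v(t) = m_QRS·u_QRS·e(t) +
s·m_QRS·u_⊥·e'(t) + m_T·u_T·e_T(t) + noise, with e(·) a compactly
supported Gaussian envelope (the raw Gaussian shifted and rescaled to reach
exactly zero at the 1 % cutoff that defines the phase window) and u_⊥ a
random unit vector orthogonal to u_QRS. The derivative-of-Gaussian spread
term (default s = 0.15) turns the QRS phase into a genuine loop; being
antisymmetric about the QRS center it leaves the dominant mean vector
exactly along u_QRS. Compact support makes the beat strictly isoelectric
outside its QRS/T windows, matching the assumption behind the pre-QRS
origin window; without it the Gaussian tail biases the origin median and
the recovered angle by several tenths of a degree.

Vector pairs at a prescribed angle are drawn with u_QRS uniform on the
sphere and u_T at exactly that angle with uniform azimuth, so repeated
draws cover all octants. Defaults: QRS magnitude uniform 0.8–2.2 mV,
T/QRS magnitude ratio uniform 0.15–0.5 (0.02–0.095 for LOWM records), QRS
Gaussian width 12 ms, T width 50 ms, T center 300 ms after the R peak,
noise 0.02 mV — magnitudes and timings a reader of clinical ECGs would
call ordinary. Records are 10 s at 500 Hz with 10 beats (60 bpm), the
first R peak at 0.4 s so every beat has a complete averaging window.
Projection to the 8 independent leads uses the fixed right pseudo-inverse
of the Kors matrix, so the labeling pipeline's Kors step recovers the
generating VCG exactly (round trip ≤ 1e-9) and ground-truth closure is
testable; physiological realism of the projection is secondary to that
testability and documented as such. White noise is added per independent
lead, so derived limb leads keep their exact linear relations. Dataset
metadata: 48 % female, ages uniform 18–90, six classes with NORM-dominated
mix; class-conditional angle distributions concentrate NORM low (mode
~40°) and give disease classes substantial mass above 90°.

What the generator does **not** emulate: pathology-specific morphology
(Q waves, ST deviation), arrhythmias, electrode motion artifacts, baseline
wander beyond what filtering removes, or inter-beat variability. Passing
tests therefore demonstrate the pipeline's internal consistency and the
learnability of the geometric mapping — not clinical-grade accuracy on
real ECGs.

## Problem sizes and runtimes

The test suite exercises the learning path at a deliberate desk scale:
1000 training / 200 validation synthetic records, 30 epochs, leads
{I, II, aVF, V2}, D = 3, k = 16 — about three minutes of NumPy training on
one CPU, with labeling of the 1320-record pool taking ~25 s. At that scale
the validation median absolute angle error drops from ~30° (untrained or
constant-median prediction) to ~16° with Spearman ρ ≈ 0.72. Larger record
counts and the full 100-epoch schedule continue to improve accuracy but
are outside the default test budget.

## Known limitations

- The WFDB reader/writer covers the PTB-XL-style subset only (format 16,
  single .dat, comment-line metadata).
- The R-peak detector and averaged-beat delineator are simple threshold
  methods; heavily pathological morphologies would need a dedicated
  delineator feeding the pluggable fiducial path.
- The NumPy network trains on CPU only and is intentionally small;
  hyperparameter search beyond the configuration loop is out of scope.
- Bootstrap CIs use the bias-corrected (not accelerated) percentile
  method.
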