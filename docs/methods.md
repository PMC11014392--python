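# Methods

`imuscore` implements a sensor-to-score analysis chain for upper-limb motor
examination in Parkinson's disease: two wrist/hand-mounted 9-axis inertial
measurement units (IMUs) record six standardized movement tasks, and
supervised models map conditioned signal features to the 0–4 clinician
motor score of each task and hand. Because clinical recordings of this kind
are rarely shareable, the package includes a first-class synthetic cohort
generator that reproduces the statistical structure the analysis relies on,
so every downstream stage is testable end to end.

## The signal model

Each simulated trial is a 10 s, 200 Hz, 9-channel recording (accelerometer
in G, gyroscope in °/s, magnetometer in µT). The accelerometer carries a
constant 1 G gravity component along a per-trial random orientation, so the
magnitude signal has a non-zero mean as in real data. On top of this
baseline the generator superimposes the two phenomena the clinical scale
grades:

* **Tremor** (AR, OA, FN tasks): a band-limited sinusoid — 4–6 Hz at rest,
  6–9 Hz during the postural hold — whose acceleration amplitude follows a
  geometric score mapping `a(s) = 0.08 G · 1.9^(s−1)` for s ≥ 1 and 0 at
  score 0. Geometric growth keeps adjacent scores separable but overlapping
  under noise. The oscillation direction is biased toward the gravity axis
  (tremor acts roughly along the limb), which keeps the tremor visible in
  the magnitude signal at its fundamental frequency.
* **Bradykinesia** (HM, PS, FT tasks; FN carries a slow 0.4 Hz reach
  cycle): a repetitive voluntary oscillation at a task-specific base
  frequency (HM 2.0 Hz, PS 1.5 Hz, FT 3.0 Hz) whose envelope decays
  exponentially at `0.05·s` per second, whose excursion shrinks by 12 % per
  score point, and whose cycles are skipped with per-cycle probability
  `0.05·s` (hesitation). Cycle boundaries sit on zero crossings so gating
  leaves the waveform continuous.

Gyroscope channels carry the angular-rate analogue of each component plus a
slow physiological drift; the magnetometer sees a constant ~40 µT earth
field, a slow orientation wobble, and a motion-coupled term. Gaussian noise
(0.02 G, 2 °/s, 1.5 µT) is added per channel, then samples are clipped and
quantized to the sensor's range and bit depth (±8 G/16-bit, ±2000 °/s
/16-bit, ±1200 µT/13-bit), so the generator emits realistic discretized
values.

Cohort scores are drawn per (participant, hand, task) to match a
configurable per-task score histogram; the default profile mirrors an
imbalanced 45-participant clinical distribution. Controls always score 0.
A Gaussian copula with ρ = 0.7 couples one latent severity per patient
across tasks and hands — the per-recording percentile is exactly uniform,
so the target histogram is matched in expectation while scores remain
correlated within a patient, as clinical ratings are. When a task's zero
bin is smaller than the control share (which happens in the default FT
profile), the deficit is clipped from the PD-conditional distribution by
default; `strict_histogram=True` raises instead. Contamination is modelled
as uniformly sampled (participant, hand, task) flags; removal is a
downstream filter, so the dataset always holds the complete
participants × 12 grid.

### What the generator does not emulate

Biomechanically realistic limb kinematics, magnetometer calibration
artifacts, inter-rater disagreement, medication-state fluctuations, and
score noise (a patient's latent severity maps deterministically through the
copula). Separation between score levels is consequently cleaner than in
clinical data: passing recovery tests demonstrates that the pipeline
extracts the encoded severity signal without leakage, not that clinical
AUROCs of any particular magnitude are attainable.

## Conditioning

Fixed order: downsample 200 → 50 Hz, per-sensor Euclidean magnitudes,
lowpass, centre 5 s epoch, equal 2.5 s halves.

* Downsampling uses polyphase FIR decimation (zero-phase, linear edge
  extension) — an anti-alias stage is standard practice, and the subsequent
  20 Hz filter makes the exact choice observationally minor within the
  analysis epoch.
* The conditioning filter is a causal 3-pole Butterworth lowpass at 20 Hz
  (single forward pass; group delay on the order of 10 ms). All 12 series
  (9 axes + 3 magnitudes) are filtered identically; magnitudes are formed
  before filtering so they are non-negative by construction.
* The 5 s epoch is centre-aligned (start = (duration − 5)/2), an automated
  stand-in for manual isolation of the stable mid-portion of a trial.
* Odd-length epochs drop the final sample (≤ 20 ms) before splitting.

The half-split exists because bradykinesia manifests as progressive loss of
amplitude and rate toward the end of a task: features computed on the early
and late halves capture that decrement. Note that on the accelerometer
magnitude the 1 G offset dominates the raw rms, so the decrement appears in
the variance (and in the gravity-free gyroscope-magnitude rms), not in the
raw accelerometer rms.

## Features

13 features per channel per half: six time-domain (rms, range, mean,
variance, skew, kurtosis — bias-uncorrected standardized moments, excess
kurtosis, constant series → 0), six spectral from a Welch PSD restricted to
0–10 Hz (dominant frequency; relative magnitude = band power within
±0.5 Hz of the dominant frequency over total band power; PSD mean, sd,
skew and excess kurtosis treating the normalized density as a probability
mass over the frequency grid; all-zero spectrum → 0), and sample entropy.

* Welch settings: Hann window, 64-sample segments, 50 % overlap on the
  125-sample half-segment — at least two averaged periodograms at ~0.78 Hz
  resolution, adequate for a 0–10 Hz band.
* Sample entropy: m = 2, r = 0.2 × segment SD, Chebyshev distance,
  self-matches excluded, the common-template (N−m) convention. When no
  m+1 template pair matches, the conventional upper bound
  −ln(2/((N−m−1)(N−m))) is returned; a constant series returns 0. The
  implementation is vectorized and verified exactly against a brute-force
  O(n²) template count.

The magnitude variant yields 78 features per recording (13 × 3 sensors ×
2 halves); the axis variant 234. Halves are concatenated into one vector
per recording rather than treated as independent samples. Standardization
is z-scoring with training-partition statistics only; it runs inside every
cross-validation split (first pipeline step), so held-out rows never leak
into the feature scaling. Zero-variance features map to 0.

## Models and evaluation protocol

Four designs on the feature table: six-class task identification; per-task
binary score classification (score 0, pooling patients and controls,
vs non-zero); per-task multiclass classification of non-zero scores; and
per-task regression of the non-zero score. Rare score categories are
excluded per task (2 and 3 for AR, 2 for OA, 4 for HM and FT) so every
retained class can be stratified. Random forests (bootstrapped) are the
primary learner; an RBF-kernel SVM with a small C × γ grid is the
comparator.

The evaluation protocol is repeated stratified k-fold cross-validation,
4 folds × 5 repeats = 20 fold-level metric values, summarized by their mean
and a 95 % percentile interval (a normal-approximation interval is
available). Folds are not grouped by participant by default — both hands of
one patient may span folds, matching common practice for this design — but
a `by_participant` grouped protocol is available because the ungrouped
design risks optimism when within-patient correlation is strong. A fold
whose class would have fewer members than folds fails loudly rather than
silently re-binning; regression folds stratify on the integer score when
every score is frequent enough and fall back to unstratified shuffling
otherwise.

The hyperparameter grid (trees 10:5:150, depth {5,16,28,40}, min-split
{2,5,10}, min-leaf {1,2,4}; 1044 points) is searched exhaustively when
requested, ties broken by enumeration order. The pipeline default uses
fixed mid-grid values (100 trees, depth 16, min-split 2, min-leaf 1):
on the synthetic cohorts the search surface is flat near the optimum and
the full search over 20 folds per point adds nothing but runtime.

Metrics: binary AUROC equals the normalized Mann–Whitney concordance count
(ties ½) and is computed by threshold sweep; multiclass AUROC is the
unweighted one-vs-rest macro average. The confusion-matrix suite (per-class
TPR/PPV/specificity, accuracy, macro sensitivity/specificity/precision/F1,
multiclass Matthews correlation in covariance form, Cohen's kappa with
marginal-product expected agreement) is computed directly from a count
matrix so published matrices can be re-analysed without the underlying
predictions; a class with a zero marginal contributes 0 to the affected
macro term.

## Numerical conventions and degenerate inputs

Determinism throughout: every stochastic step takes a seed, and identical
arguments give bit-identical outputs (recordings, fold assignments, forest
fits, reports). Sub-seeds for per-recording simulation derive from the
cohort generator stream. Constant series yield 0 skew/kurtosis/sample
entropy; all-zero spectra yield zero spectral features; zero-variance
features standardize to 0; empty post-policy tables and single-class
targets raise.

## Problem sizes

The test suite and the acceptance script use the full reference cohort
dimensions — 45 participants (33 patients, 12 controls) × 6 tasks × 2
hands = 540 recordings, 32 flagged contaminated → 508 analysis rows — with
10 s recordings at 200 Hz. Property suites use 50–100 seeded replicates
per check.

## Known limitations

Scores are conditionally independent of everything but the latent severity;
no per-trial rater noise. The magnetometer model is phenomenological (no
soft-iron/hard-iron effects). The SVM comparator's settings are a small
conventional grid, not a tuned reference. Multiclass separation on the
default synthetic cohort is higher than clinical reality; use the severity
presets (or custom `SeverityParams`) to study degradation, down to the
`fully_overlapping` preset where every classifier performs at chance.
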