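# Methods

This note documents the generative model, the decoding algorithms, the
evaluation machinery and the design choices behind `vsabci`, in the spirit
of a model description for a simulation-backed analysis package.

## 1. Paradigm model

A session consists of stimulation *blocks*, one per (VSA condition, cued
target) pair. Defaults follow the Hex-o-Spell oddball protocol: 6 circular
targets (4.15° visual angle, intensified to 5.50°) at the vertices of a
hexagon of radius 12.28°, flashes of 100 ms, stimulus-onset asynchrony
200 ms with uniform ±50 ms jitter, and per-target intensification counts
drawn uniformly from 10–15. With the default three conditions this yields
6 × 3 = 18 blocks, presented in randomized order with 2 s pauses.

*ISI semantics.* "Inter-stimulus interval of 200 ms" is interpreted as
onset-to-onset (SOA): at the minimum gap of 150 ms the 100 ms flash still
ends before the next begins. This is configurable.

*Randomization.* Intensification order is round-structured: each round is a
permutation of the targets that still have flashes left, so the first 10
rounds each contain every target exactly once. A target does not open a
round it just closed whenever ≥ 2 targets remain in the new round; in tail
rounds with a single remaining target the repeat is unavoidable and
permitted. Round structure guarantees that consecutive groups of six
stimuli form valid selections (six unique targets).

## 2. EEG model

Each stimulus evokes a sum of named components; a component is the outer
product of a spatial topography (Gaussian in electrode space on an
18-channel 10–20 montage) and a Gaussian temporal kernel. Defaults:

| component | modulation | latency | kernel SD | amplitude | topography |
|---|---|---|---|---|---|
| P1 | visual | 110 ms | 18 ms | +3 µV | occipital |
| N1 | visual | 175 ms | 25 ms | −4 µV | occipito-temporal |
| P3 | attention | 380 ms | 60 ms | +6 µV | centro-parietal |

*Attention* components appear only on target stimuli; their amplitude scale
and latency-jitter SD come from the per-condition profile. *Visual*
components appear on every stimulus, scaled by `exp(−gaze_offset / 6°)`
where the offset is the angular distance from the fixation point to the
flashed stimulus — under overt fixation the attended target's flashes land
on the fovea and evoke large early components; under central fixation all
six stimuli are equidistant (12.28°) and the early response is small and
non-discriminative.

Condition profiles (defaults):

| condition | P3 scale | P3 jitter SD | gaze strategy |
|---|---|---|---|
| overt | 1.0 | 20 ms | fixate target |
| covert | 0.7 | 60 ms | fixate center |
| free | 0.9 | 35 ms | mixture, P(target fixation) = 0.7 |

These encode the two empirical contrasts the analysis rests on: the P3 is
larger under overt attention, and its latency jitter grows substantially
under covert attention. The free-VSA mixture reflects users who mostly fall
back on residual gaze control when uninstructed.

Background noise is spatially correlated (distance-decay covariance,
length 0.6 head radii), temporally AR(1) (coefficient 0.97) Gaussian noise
scaled to 2.5 µV RMS per channel. This RMS was chosen once so that default
sessions land in the realistic single-trial accuracy range for healthy
Hex-o-Spell operation (overt ≈ 0.8–0.9, covert ≈ 0.3, free in between);
the value is a scenario parameter, not a fitted quantity. Optional Poisson
eye-blink artifacts (vertical-EOG deflections with frontal leakage) are off
by default and exist to exercise the EOG-regression stage.

Gaze traces are sampled at 60 Hz around the strategy's fixation point with
1° Gaussian noise, a ±0.3° per-eye vergence offset, and independent 5%
per-eye sample dropout.

All randomness flows from one master seed through per-block child seeds
(`numpy` `SeedSequence`), making sessions byte-identical across runs.

### What the generator does *not* emulate

Non-stationary noise and drifts, alpha rhythm, muscle/movement artifacts,
electrode pops, inter-subject topography differences, ERP habituation over
the session, and eye-tracker systematic calibration error. Consequently,
passing tests demonstrate correctness of the *analysis machinery* and the
direction of condition effects under the stated model — not clinical
performance on real recordings.

## 3. Preprocessing

Zero-phase (forward–backward) 4th-order Butterworth band-pass 0.5–16 Hz
(filter family/order is our choice; only the band is prescribed by the
protocol). RANSAC-style bad-channel detection predicts each channel from
random 25% subsets of the others by least squares in 5 s windows (50
resamples; bad if the median prediction correlation is below 0.75 in more
than 40% of windows); flagged channels are *excluded* from decoding rather
than interpolated, keeping the feature space honest. Re-referencing
subtracts the TP9/TP10 average from every EEG channel. Ocular-artifact
cleaning by visual-inspection ICA is not automatable; an optional
EOG-regression stage (least-squares projection on the EOG channels) stands
in for it and is off by default. Decoding epochs span [−0.1, 0.9) s
(half-open, 0-based, onset sample included) with no baseline correction;
visualization ERPs use [−0.2, 1.0) s with pre-stimulus baseline. Only the
first 10 intensifications per target per block are kept.

## 4. Decoders

**tLDA.** Features are the epoch cropped to [0, 800) ms and decimated by 20
(50 Hz; the 16 Hz band-pass makes stride decimation alias-free), flattened
lag-major. The pooled within-class covariance (ML divisor, which makes the
fit invariant under epoch duplication) is averaged over equal-lag
channel-blocks to enforce block-Toeplitz structure, then shrunk toward a
scaled identity with the Ledoit–Wolf analytic intensity computed on the
class-centered data. Weights solve `Σ w = μ_T − μ_NT`; the bias centers
scores at the class-mean midpoint. With a single retained lag the structure
is vacuous and tLDA coincides with unstructured shrinkage LDA (tested to
1e−6).

**xDAWN + tangent space.** Four xDAWN filters from the generalized
eigendecomposition of (target-evoked covariance, noise covariance). Each
epoch is augmented with the filtered target and non-target prototypes
(12 × 40 matrix), its covariance regularized by eigenvalue flooring at
1e−10 × trace, projected to the tangent space at the affine-invariant
Riemannian mean (fixed-point iteration, tolerance 1e−8, ≤ 50 iterations;
vectors of length d(d+1)/2 = 78 with √2-scaled off-diagonals), and
classified with Ledoit–Wolf-shrinkage LDA.

**WCBLE.** Wide epochs [−0.1, 0.9) s leave exactly ±100 ms of slack around
the nominal [0, 800) ms window. Iteration 0 fits tLDA at the nominal
window. Each Woody iteration slides the classifier template across every
*target* training epoch in 5 ms steps, takes the per-epoch latency at the
score maximum inside the ±100 ms search window (ties → earliest), re-cuts
those epochs at their aligned windows (non-targets stay nominal — they
carry no P3 to align) and refits; iterations stop after 3 or when the mean
absolute latency change falls below 5 ms. At test time every epoch is
scored by its maximum sliding score, and the argmax latency is reported for
diagnostics.

*Regularized peak picking.* At single-trial SNR the raw score-versus-lag
curve is noise-dominated; naive argmax alignment recovers little of the
oracle benefit of perfect alignment. Two regularizations address this, and
both are part of this package's methodology rather than the published
description of the algorithm:

1. the score curve is smoothed over lags with a Gaussian kernel (SD 30 ms)
   before peak picking, which roughly doubles the correlation between
   estimated and true latencies in simulation;
2. at test time a Gaussian log-prior penalty on the latency excursion
   (SD 150 ms, scaled by the SD of the nominal-lag training scores)
   discounts large shifts that are not strongly supported by the data.
   Training-time estimation stays unpenalized so alignment is not biased
   toward the nominal latency.

The penalty vanishes at the nominal lag, so a zero-width search window
reduces WCBLE exactly to tLDA; with smoothing and prior disabled the plain
convolve-and-maximize rule is recovered. The prior SD was fixed at a weakly
informative value where simulations show the decoder neither gains nor
loses measurably on jitter-free sessions (the no-harm calibration) while
retaining the jitter benefit.

## 5. Evaluation

A *selection* is six consecutive stimuli covering all six targets once;
after truncation each block yields 10 single-trial selections. The decision
is the argmax of per-target scores (ties → lowest index). Accuracy is
estimated by 6-fold block-wise cross-validation (train 5 blocks, test 1;
folds never share a block) pooled over folds, with 95% percentile-bootstrap
CIs over 10,000 resampled selections (resampling unit: the selection).
k-averaged selections average the first k repetitions per target, one
selection per block. Cross-condition cells train on the 5 blocks of
condition A whose fold index differs from the B test block's index,
keeping the training size at 5 and using all data symmetrically; diagonal
cells are ordinary within-condition CV. Repetitions-to-threshold reports
the smallest k whose accuracy reaches 80% (inclusive), rendered "–" when
never reached.

## 6. Experiment sizes

The simulation experiments shipped in the test suite and acceptance script
use: 40 sessions per arm for the covert-jitter contrast (covert-only
sessions, jitter SD 60 vs 0 ms), 120 sessions for the overt-calibration
transfer contrast in the tests (60 in the reporting script), 1000 replicate
experiments for bootstrap coverage, and single sessions for structural
checks. These sizes give the paired contrasts ≥ ~90% power at their
observed effect sizes (≈ +3–5 percentage points against a per-session
sampling SD of ≈ 7–10 points) while keeping a full run in the minutes
range on one CPU. The transfer experiment uses matched covert profiles with
a 2× overt-only P3 amplitude boost, isolating the amplitude mechanism from
gaze- and jitter-related confounds; with the smaller default amplitude
contrast the effect exists but sits below the sampling noise floor of a
60-selection session, so the constructed contrast is what the experiment
tests.

## 7. Numerical and degenerate-input conventions

Half-open epoch windows, 0-based indexing, onset sample included; epoch
length is `round((tmax − tmin) · sfreq)`. Argmax ties resolve to the
earliest latency / lowest target index. Covariances are regularized by
shrinkage (tLDA) or eigenvalue flooring (xDAWN); the Riemannian mean clips
eigenvalues away from zero before logarithms. Empty component lists produce
zero waveforms; an epoch of zeros scores exactly the classifier bias.
Sessions round-trip through HDF5 float32 (or EDF-style 16-bit physical
quantization, error ≤ half a step) plus TSV tables validated line-by-line
with offending line numbers in errors.

## 8. Known limitations

- The ERP model is stationary within a session; real covert-VSA data show
  time-varying strategy drift that WCBLE's global alignment cannot capture.
- RANSAC parameters follow common conventions but were not tuned against
  real recordings.
- The bootstrap treats selections as exchangeable within a condition;
  block-level dependence is ignored (the resampling unit is a choice, and
  per-fold counts are reported so block effects remain visible).
- Cross-condition fold rotation is one of several defensible pairings; it
  was chosen for symmetry, not validated against an external reference.
- Gaze "strategy labels" (overt-like / covert-like / mixed) operationalize
  what heatmap inspection reads qualitatively; thresholds (0.5 dwell, 3°
  landmark radius) are configurable and reported alongside raw fractions.
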