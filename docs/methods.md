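# Methods

## Model and fitting

The core model is a sparse delay differential form with two linear delayed
terms and one quadratic delayed term,

    u̇(t) = a1·u(t−τ1) + a2·u(t−τ2) + a3·u(t−τ1)²,

fitted per window by linear least squares.  Conventions:

- **Time step.** Δt = 1 sample; delays are integers in samples.
  Coefficients are therefore in per-sample units, and — because every
  window is standardized before fitting — the features are invariant to
  the sampling rate, signal scale and offset.
- **Derivative.** 3-point center difference, u̇[n] = (u[n+1] − u[n−1])/2.
  Endpoints are excluded; the regression uses rows n = max(τ) … N−2, so a
  window of N samples yields N−1−max(τ) rows.
- **Solver.** Batched QR decomposition of the (rows × 3) design; an
  independent brute-force normal-equations solve is used as the oracle in
  the test suite (agreement to 1e−8).  Rank-deficient designs fall back to
  the minimum-norm pseudo-inverse and the condition number is logged.
- **Residual.** ρ is the RMS residual of the regression (the root of the
  mean squared residual over the window's rows; for pooled CT fits, over
  all pooled rows).
- **Degenerate windows.** A window with (numerically) zero variance cannot
  be standardized; it is NaN-flagged and its fits are excluded from
  aggregation, never imputed.  The zero-variance test uses a relative
  tolerance (SD ≤ 1e−12·max(1, |mean|)) because a constant level like 4.2
  leaves rounding-level variance after the mean subtraction.

ST fits treat each window of each channel separately.  CT fits stack the
regression rows of a window group (the three channels of a triple, at the
same window position) and solve once; since the pooled fit is a
constrained version of the per-window fits, ρ_CT² ≥ mean(ρ_ST²) always
holds and the ergodicity score E = ρ_CT − mean(ρ_ST) is nonnegative up to
rounding.  Small E means the group is dynamically similar.

## Windowing and features

Sliding windows of 700 ms with 50% overlap (defaults; configurable).
Sample counts come from round-half-away-from-zero on the ms→samples
conversion, the step is round(win·(1−overlap)), and an incomplete trailing
window is dropped rather than padded — e.g. a 4 s trial at 1024 Hz gives
10 windows of 717 samples stepped by 359.  Windows are half-open [start,
stop) with 0-based indexing throughout.

Per trial and channel triple the feature vector concatenates, in order:
per-channel mean and population SD across windows of (a1, a2, a3, ρ)
(8 features × 3 channels), the same 8 statistics for the CT fit, and
mean/SD of E — 34 features per triple.  In single-window mode there is
nothing to aggregate over, so the 4 raw per-channel values, 4 CT values
and 1 E value are emitted instead (17 per triple); the SD of a single
window is undefined and deliberately omitted.

## Delay search and classification

All ordered pairs (τ1, τ2), τi ∈ 1…τ_max, τ1 ≠ τ2, are scored; the pair is
ordered because only the τ1 term is squared.  Each candidate is scored by
stratified k-fold cross-validation (default 5) of a standardize+SVM
pipeline on its features — accuracy for balanced multiclass problems,
macro one-vs-all AUC for binary or unbalanced ones.  Per scoring unit
(subject × triple) the pairs are ranked (rank 1 = worst), ranks are
averaged across units, and the mean ranks are min-max scaled to [0, 1];
the grid diagonal is missing-coded.  The best pair is the scaled-rank
maximum, with exact ties broken by smaller τ1+τ2 and then
lexicographically, so reruns are reproducible.  If every pair scores
identically the scaling is degenerate and the grid is filled with 0.5.

Classifiers are Gaussian-kernel SVMs with K(x, y) = exp(−‖x−y‖²/s²) and
kernel scale s = 2 (gamma = 1/4), one-vs-one coding.  Class-membership
scores are Platt-calibrated pairwise-coupled probabilities
(`CalibratedClassifierCV(SVC(...), ensemble=False)`).  Features are
z-scored per feature with training-set statistics only.  Scores from all
triples are fused by their arithmetic mean and the prediction is the
fused argmax (ties to the first class in class order).

**SD scheme.** Per subject, pseudo-trials drive structure selection and
training: within each class, all (trial, window) slots form a pool, a
seeded global permutation of the pool is chunked into pseudo-trials
(defaults: as many pseudo-trials as real trials, as many windows each as a
real trial has), so every window is used at most once and channel
alignment is preserved.  Delay search and the final classifier fits use
only these pseudo-trials; evaluation uses the original time-connected
trials.  **SI scheme.** Leave-one-subject-out on time-connected trials:
search and training pool all other subjects, evaluation is on the held-out
subject.

## Evaluation

Accuracy; one-vs-all ROC per class with trapezoidal AUC; a macro curve by
vertical averaging of TPR on a fixed 101-point FPR grid and macro AUC as
the mean of per-class AUCs (a class absent from the labels is NaN-coded
and excluded); PPV/recall/F1 for binary problems with NaN for
zero-denominator cases; confusion matrices; and two-sided one-sample
t-tests of per-subject metrics against chance 1/K with Bonferroni
per-test alpha fwer/m (default family m = 4, so alpha = 0.0125).
Sidedness is a package choice (two-sided); AUC is checked in the tests
against the Mann–Whitney U statistic as an independent oracle.

## Synthetic data generator

Trials are realizations of a discrete two-delay map,

    u[n] = u[n−1] + b1·v1[n] + b2·v2[n] + b3·v1[n]² + ε[n],
    vk[n] = (u[n−tk] + u[n−1−tk]) / 2,      ε ~ N(0, noise_sd²),

with i.i.d. N(0, 0.1²) initial history, a burn-in of 10·max(t) samples
discarded, an amplitude guard at |u| > 1e6 (divergent runs are resampled
with a perturbed seed up to 10 times, then raise), and per-(subject,
class, trial, source) seeding so identical specs reproduce bit-identical
trial sets.  Channels are independent sources per class dynamics by
default, optionally mixed by a dense matrix, with optional white
observation noise.

The delayed terms are evaluated at the trapezoidal midpoint rather than at
a single lag.  This is deliberate: under the fitter's center-difference
derivative, a plain one-lag Euler map has an effective delay of t − 0.5
samples, which biases coefficient recovery and systematically pulls delay
selection toward t − 1; the midpoint form is delay-symmetric, so fits at
the generating delays recover (b1, b2) with median absolute error well
below 0.02, and with b = 0 the map still reduces to a pure random walk
(the degenerate control case).  Note that a3 estimates on standardized
windows scale with the window SD, and at very low drive noise the
quadratic regressor carries too little variance for b3 to be identifiable;
round-trip tests of a3 therefore run at noise_sd = 0.1.

Null sets share one dynamics across all classes (labels carry no signal);
a scrambling option permutes the class↔dynamics assignment independently
per subject, producing data that are decodable within subjects but not
across them.

**What the generator does not emulate:** 1/f background spectra,
nonstationarity, volume conduction beyond linear mixing, artifacts
(blinks, EMG), or any physiological forward model.  Passing tests
demonstrate the pipeline's correctness and its behaviour under known
dynamics, not performance on real EEG.

## Study conditions used by the tests and the acceptance script

- Null benchmark: 10 virtual subjects, 5 or 6 balanced classes, 20
  trials/class, 3 channels, fs = 256 Hz, 2 s trials, shared dynamics
  (t = (3, 7), b = (−0.1, 0.05), noise 1.0), τ_max = 10.
- SD/SI contrast: 6 subjects, 3 classes with distinct generating delays
  ((3, 7), (4, 9), (2, 5); b = (−0.3, −0.1)), 8 trials/class, 6 channels
  (two fused triples), τ_max = 6; the scrambled variant permutes the
  class↔dynamics map per subject.
- Delay-recovery study: two classes sharing delays (3, 7) and linear
  coefficients (−0.3, −0.1), differing only in the sign of b3 (±0.05,
  noise 0.3) — a contrast with matched second-order structure — 12
  trials/class at fs = 128, τ_max = 8.

These sizes keep a full test run in minutes on one CPU while leaving each
statistical check adequately powered.

## Known limitations

- **Window reuse in the SD protocol.** The non-connected/connected scheme
  trains on pseudo-trials assembled from the same windows that compose the
  time-connected test trials.  With kernel scale 2 on ~34 standardized
  features, exp(−d²/4) is vanishingly small at typical inter-point
  distances and the SVM behaves nearly as a nearest-neighbour rule; a test
  trial's nearest training point is then usually a pseudo-trial that
  contains one of its own windows and carries its label.  On synthetic
  *null* data this memorization yields ~30% accuracy against a 20% chance
  level (5 classes), while the same models evaluated on freshly generated
  null data score at chance — the inflation is a property of the protocol,
  not of the features.  The null benchmark reports this honestly rather
  than masking it; analyses that need leakage-free SD estimates should
  evaluate on held-out recordings.
- **Delay selection is discriminative, not generative.** The exhaustive
  search maximizes cross-validated class separation, which identifies the
  most discriminative delay pair; that pair generally need not equal the
  generating one.  In the recovery study τ1 (the nonlinear term's delay)
  is pinned reliably, but τ2 — entering only linearly — confers an
  expected-score advantage of well under 0.01 at its true value, so exact
  pair recovery by classification score is not resolvable at realistic
  sample sizes.  This mirrors the broad, smooth delay-ranking grids
  observed on real EEG.
- LOO subject-independent evaluation shows the usual pessimistic bias when
  label↔dynamics assignments anti-correlate between training majority and
  held-out subject (scrambled data can score below chance).
- The generator's delay maps must be linearly stable; strong positive
  quadratic terms can diverge, which the amplitude guard converts into
  retries/errors rather than silent garbage.
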