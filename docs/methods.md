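# Methods

`eegdecode` implements an intersubject EEG decoding workflow for the binary
animate/inanimate classification of visually evoked responses, together with
a synthetic paradigm simulator that makes every stage testable without any
recorded data.  This note documents the models, the simulator, the numerical
conventions, and the deliberate design choices.

## The decoding problem

Observations are epoched multichannel EEG responses: one epoch spans
[-100, 500) ms around stimulus onset, sampled at 100 Hz (60 samples) on a
32-channel montage, giving a 32 x 60 = 1920-dimensional feature vector per
trial.  Each trial carries a semantic category label (23 categories, 30
trials each, 690 trials per subject) and a binary animacy superclass label
y in {-1, +1} (+1 animate; 10 animate categories -> 300 animate vs 390
inanimate trials, majority baseline 390/690 = 0.565).  Decoding is
evaluated across subjects: leave-one-subject-out (LOSO), never within
subject, so accuracies measure intersubject generalization.

Every observation entering a classifier is z-scored as a unit: the
channel x time block of a trial (or pseudotrial) is shifted and scaled to
mean 0, standard deviation 1 across all 1920 entries.  The population
standard deviation (divide by n) is used; the z-scoring invariant holds
either way, but one convention must be fixed.

## Classifiers

Both classifiers are soft-margin SVMs with the RBF kernel
k(x_n, x) = exp(-gamma ||x_n - x||^2), discriminant

    f(x) = sum_n alpha_n k(x_n, x) + b,

with signed dual coefficients |alpha_n| <= c.  The quadratic program is
solved by scikit-learn's libsvm wrapper; the package owns the model
contract: the full-length dual-coefficient vector with zeros retained, the
retained training rows, and an analytic decision function (needed for the
sensitivity map below).

* **Single-trial classifier** — trained on all z-scored single trials of
  the training subjects (14 subjects -> 9660 rows).
* **Pseudotrial classifier** — trains on category averages: the ~30 trials
  of each (subject, category) cell are averaged sample-wise, then z-scored
  as units (23 pseudotrials per subject).  Averaging before z-scoring is
  the default; the reverse order is exposed via `zscore_order` because
  either reading is defensible and the choice is not empirically pinned
  down.

Determinism: training rows are sorted canonically by (subject, trial
index) before the solve, so row order never affects the fitted model.
Prediction ties (decision value exactly 0) go to the inanimate majority
class.

### Hyperparameter search and cross-validation

Grids are 10 x 10 log-spaced (endpoints included) over
c in [0.05, 10], gamma in [2.5e-7, 5e-3] (single-trial preset) or
c in [0.25, 15], gamma in [5e-7, 2.5e-2] (pseudotrial and debiased
presets).  Log spacing is used because the reported optima of such
analyses sit on decade ladders; grid-search ties break toward the smaller
c, then the smaller gamma (prefer stronger regularization,
deterministic).  No class weighting is applied despite the 300/390
imbalance — the 0.565 majority baseline is the reference.

Three LOSO evaluation schemes:

1. **Nested LOSO** — inner LOSO over the training subjects selects
   (c, gamma) by mean validation accuracy; the held-out subject is scored
   once.  Because the training set of inner fold (outer s, validation v)
   depends only on the unordered pair {s, v}, each pair is fit once and
   evaluated on both members.
2. **Debiased double holdout** — each of n iterations leaves out one
   validation and one test subject (training on n-2).  Per-half mean
   optimal parameters (arithmetic mean of c, geometric mean of gamma —
   gamma spans four decades where arithmetic means are dominated by the
   top decade — snapped to the nearest grid point) are transferred to
   score the other half's test subjects; exactly two transferred sets
   result.  With 15 subjects the halves are 7/8 and one subject is tested
   twice (accuracies averaged).
3. **Oracle** — parameters maximize the held-out subject's own accuracy;
   an optimistically biased upper bound, flagged in the result metadata.

Significance of a held-out subject's accuracy uses a label-permutation
test (default 1000 shuffles of the true labels against fixed predictions)
with the add-one convention p = (1 + #{perm >= obs}) / (n_perm + 1), which
never returns 0.  The standard error of the mean LOSO accuracy is
reported both naively (sd/sqrt(K)) and with a dependence correction
sd * sqrt(1/K + n_test/n_train), since LOSO folds share most training
data; the correction is a documented convention, and both numbers are
always co-reported.

## Sensitivity maps

The RBF discriminant is differentiated analytically,

    df/dx_j = sum_n alpha_n 2 gamma (x_{n,j} - x_j) exp(-gamma ||x_n - x||^2),

and the gradient is aggregated over evaluation points (default: the
model's training rows, which are always available).  The default
aggregation is the mean squared derivative, giving a nonnegative
channels x time importance map; the signed mean is exposed to inspect
effect direction.  The aggregation normalization (mean over points) is a
documented convention isolated behind the `aggregation` flag.

## NPAIRS effect sizes

A full-cohort map M_full (ERP difference map or sensitivity map) is scaled
into an effect size by split-half resampling: in each of S = 100 splits,
two disjoint partitions of 7 subjects are drawn without replacement (one
random subject left out per split with 15 subjects), the map is computed
on each partition, and

    sigma^2 = 1/(S*T*N) sum over splits and map elements of (M1 - M2)^2,
    M_hat = M_full / sigma.

The element sum runs over all channels x time cells.  Partition maps are
not normalized per split before differencing.  Sensitivity map functions
inside NPAIRS use fixed hyperparameters (inputs, not re-optimized per
split), mirroring how transferred/mean validation parameters are used for
the full-data maps.

## ERP statistics

ERPs are subject-level class means; grand averages weight subjects equally
(subject means are the analysis unit, whatever the trial counts).  The
difference map is grand animate minus grand inanimate.  Significance is a
paired t-test across subjects per cell, Bonferroni-corrected either over
the 60 time samples of a posterior channel-averaged trace
(O1, O2, Oz, PO3, PO4; alpha/60) or — the conservative default — over the
full 60 x 32 map (alpha/1920).  Zero-variance cells get t = +/-inf and
count as significant iff the mean difference is nonzero; this degenerate
case cannot occur with continuous noise but is pinned down for
deterministic behaviour.

## The synthetic paradigm simulator

The simulator emulates the structure of the target paradigm — 15 subjects,
23 categories x 30 images in randomized category blocks, 32 channels,
60-sample epochs — and its timing arithmetic (5 s category probes, 1 s
stimuli, ISIs drawn with replacement from the 7-value grid
1.85..2.15 s averaging 2.0 s, five 35 s breaks; the default paradigm lasts
2360 s = 39.33 min).

Each trial is built as

    common template * subject gain, latency-shifted
    + class effect (animate only) * subject gain, latency-shifted
    + iid Gaussian noise (optional AR(1) smoothing in time).

* The **common template** is a sum of Gaussian-windowed deflections
  (posterior negativity ~90 ms, positivity ~140 ms, P3a/P3b-like bumps at
  250/300 ms) weighted toward posterior channels.  Morphology is a free
  modelling choice exposed through the config.
* The **class effect** is a Hann-windowed bump confined to the effect
  channels (default O1, O2, P7, P8) and window (default 200-330 ms),
  where posterior animacy differences concentrate.
* **Subject variability** is a multiplicative lognormal gain
  (sigma = 0.25) and a uniform latency shift (default +/-20 ms), modelling
  intersubject amplitude/latency diversity without quantifying it from
  data.
* **Noise** is iid Gaussian per sample and channel (sd 1.0).  No spatial
  covariance is simulated by default; an AR(1) temporal-smoothing
  coefficient is available as a config extension.

Calibration: the paradigm gives no quantitative single-trial SNR.  The
default `effect_amplitude = 0.22` (relative to `noise_sd = 1.0` and
`common_erp_amplitude = 1.0`) is calibrated once so that intersubject
single-trial decoding accuracy lands in the 0.55-0.65 band typical of
scalp-EEG animacy decoding, and is documented as a calibration, not a
measured value.

What the simulator does **not** emulate: spatially correlated sensor
noise, volume-conduction channel covariance, artifacts (blinks, muscle,
electrode drift), sampling drift, oscillatory background activity, or
image-level stimulus variability.  Passing tests on synthetic data
therefore demonstrate correctness of the pipeline and recoverability of a
planted effect under realistic SNR — not performance claims about any real
recording.

## Problem sizes used in tests and the acceptance script

The structural quantities (trial counts, 10350/345 dual-coefficient vector
lengths, timing arithmetic) are computed at the full default scale.
Statistical properties are checked at reduced problem sizes chosen as the
package's own test design: null-calibration runs use 10 trials per
category and reduced 3 x 3 grids; the classifier-parity check uses 8
subjects x 12 trials per category; sensitivity-recovery checks subsample
trials per subject.  Reduced sizes trade statistical resolution for
runtime and are stated inline in each test.

## Known limitations

* The debiased scheme's pairing of validation/test subjects for odd
  cohorts is one of several defensible conventions; results for the
  twice-tested subject are averaged.
* The NPAIRS sigma pools all map elements; no per-element or per-split
  normalization variants are provided.
* Only binary animacy decoding is implemented (no 23-way decoding, no
  non-RBF kernels, no probability calibration).
* The HDF5/CSV container stores rectangular (equal trials per subject)
  datasets only.
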