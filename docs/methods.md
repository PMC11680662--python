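# Methods

`wordform` reconstructs, end to end, a transfer-learning decoding study of
spoken-word recognition in source-space MEG/EEG, together with a synthetic
generator of its data, so that the complete analysis chain — design,
preprocessing, decoding, cluster inference, effective connectivity — runs
and can be validated on a single CPU without any recordings.

## The experimental design

Six CVC hub words (*pig, toad, cab, bike, dupe, gut*) each anchor a
phonological neighborhood of six one-phoneme neighbors: three real words
and three nonwords, with the changed position (onset, vowel, coda)
counterbalanced within each lexicality. A neighbor's unchanged material
defines its overlap class with the hub: coda change → shared initial CV-,
vowel change → shared C_C frame, onset change → shared final -VC.
Participants (20 in the reference design) perform lexical decision on
these items, presented in 16 blocks of 48 trials (each hub twice, each
neighbor once per block), two non-consecutive blocks per each of 8
resynthesized "virtual talkers", in pseudo-random order with the
constraint that a hub's second presentation never directly follows its
first. `design.make_schedule` enforces both constraints by rejection
sampling with a retry cap (1,000), which fails loudly only for degenerate
configurations.

## The synthetic generative model

The analysis consumes per-trial source activations of 39 ROIs × 8
subdivisions over epochs of −100…1000 ms at 1 kHz (1,101 samples, onset at
index 100). The generator (`synth`) produces these as a sum of:

* **Segmental structure.** Each (ROI, neighborhood) has three unit
  8-vectors, one per phoneme slot. An item's segmental pattern is the
  normalized slot sum; a changed slot is replaced by an item-specific
  vector. Shared phonology therefore literally means shared pattern
  components, which is the premise of transfer decoding. Active during the
  stimulus window (0–350 ms by default).
* **Lexical structure.** Each (ROI, neighborhood) has one unit pattern
  carried by the hub and its *word* neighbors only, in a post-offset
  window (400–600 ms by default) — the consolidated-wordform signature
  that only word-trained classifiers can exploit at test. Nonword
  neighbors never receive it.
* **Amplitude modulation and coupling.** Each (subject, ROI) has one slow
  AR(1) gain latent (`amp_mod_sd`, correlation `amp_mod_rho`) multiplying
  its signal envelope, shared across trials. A coupling edge
  (source → target, lag, gain) adds the source's lagged envelope to the
  amplitude of the target's lexical pattern. The latent is deliberately
  trial-shared: trial-independent modulation would average out of both the
  event-related fields and the decoding-accuracy time course, leaving the
  connectivity stage nothing to detect.
* **Nuisances.** I.i.d. Gaussian channel noise (`noise_sd`, optional AR(1)
  smoothing), a per-subject random rotation of all pattern vectors
  (`subject_jitter_sd`, preserving unit norm — patterns are
  subject-specific as in within-subject decoding), and a small
  talker-specific additive offset during the stimulus window
  (`talker_offset_sd`).

Behavioral errors are independent per-trial draws at lexicality-specific
rates (defaults 0.08 words / 0.14 nonwords, matching the reference
accuracies of 92%/86%); only correct trials enter analysis. Everything is
reproducible bit-for-bit from `(schedule, truth, config)` seeds.

What the generator does **not** emulate: forward/inverse modeling and
crosstalk between ROIs, realistic evoked-response morphology (envelopes
are rectangular), 1/f sensor noise, eye blinks or other artifacts, and
reaction-time structure. Passing tests therefore show that the analysis
chain is correct and calibrated under its stated assumptions, not that it
would behave identically on real recordings.

## Preprocessing

Per epoch and channel the mean over the 100-ms pre-stimulus baseline is
subtracted; then, at every timepoint, the 8-subdivision vector of each ROI
is scaled to unit norm (exact zeros stay zero). Normalization scope is a
config switch (`roi` default, `global` available) because the reference
description is ambiguous; within-ROI makes each ROI's evidence purely
pattern-directional. State flags block double application. Correct trials
are then grouped into random disjoint bins of 8 and averaged
("pseudo-trials"), independently 100 times; leftover trials are dropped
per assignment rather than forming a short bin, keeping bin SNR
homogeneous. Binning applies to both training (neighbor) and test (hub)
conditions.

## Transfer decoding

For each ROI, neighborhood pair (A, B), training condition, timepoint and
bin assignment, a linear soft-margin SVM (C = 1) is trained on the
bin-averaged neighbor trials of A vs. B selected by the condition
(`words_only`, `nonwords_only`, `cv_overlap`, `vc_overlap`) and tested on
the bin-averaged hub trials — items never seen in training. Features are
the 8 normalized subdivision values at that single timepoint. Accuracy is
averaged over the 100 assignments, then over the 15 neighborhood pairs;
chance is 0.5. Training/test trial sets are asserted disjoint on every
fold. Decision-boundary ties go to the first class of the pair,
deterministically.

The SVM is solved by the libsvm algorithm (SMO with maximal-violating-pair
working-set selection and libsvm's clipping and intercept rules),
implemented in numba because the workload is millions of 12-sample ×
8-feature problems and generic wrappers spend ~250× the solver time in
validation overhead. The test suite holds this solver to exact agreement
with scikit-learn's libsvm-backed `SVC` (decision signs on randomized
problems, dual objective, weight vectors).

## Cluster-based sign-flip permutation inference

Group-level inference treats each ROI's accuracy time course across
subjects. The cluster-forming test is a one-tailed one-sample t-test
against chance (alpha 0.05); clusters are maximal runs of consecutive
significant timepoints, and the cluster statistic is the run length. The
null flips each subject's deviation from chance by an independent ±1 per
permutation (1,000 by default) and records the largest cluster; the
cluster p-value is (k+1)/(n_perm+1). Family-wise control across ROIs is
Bonferroni — 0.05/39 = 0.00128 under the full ROI family; analyses on a
simulated subset gate over that subset's size. Because squared deviations
are flip-invariant, all permuted t statistics are computed in closed form
at once.

The between-condition test requires a timepoint to be above chance
(uncorrected 0.05) *and* paired-different from the comparator (uncorrected
0.05, two-tailed, mean difference in the favored direction). Its null
flips, independently per subject, the deviation of the within-subject
condition mean from chance and the A−B difference (two Rademacher
variables); each permutation's statistic is the largest cluster over both
directions, giving one null for the two-direction family. Alternative
readings of the published flipping sentence (joint flips, label swaps)
exist; independent flips are the package's documented choice.

A known property of sign-flip nulls worth keeping in mind when choosing
simulation amplitudes: for a homogeneous effect much larger than
between-subject noise, majority-sign flip patterns reproduce the full
cluster, so the attainable p saturates near the binomial sign-pattern tail
(≈0.02–0.07 regardless of effect size); near-minimal p-values require
effects comparable to the noise, where partial-flip clusters fragment.
The recovery simulations are parameterized in that regime.

## Decoding-informed Granger causality

For a directed pair (source → target) among the word-trained decoding
ROIs, the target node is its scalar within-subject word-trained decoding
accuracy time course; every other ROI contributes its 8 subdivision
event-related time courses (mean over correct trials); the target ROI's
own activations are excluded (substituted by the accuracy channel), giving
(R−1)×8+1 channels, z-scored over the 250–550 ms analysis window and
downsampled to 250 Hz (76 samples). To keep the full-ROI conditioning set
estimable over a short window, non-source predictor ROIs are compressed to
their leading principal component by default (config flag); the tested
source keeps all 8 channels.

An adaptive AR model of the target channel is estimated with a Kalman
filter whose state is the coefficient vector (intercept + `order` = 5 lags
of every channel, ≈20 ms of history at 250 Hz), evolving as a random walk
with state-noise variance `adapt_const²` (adapt_const = 0.02). The
innovation variance is tracked with a separate exponentially weighted
estimator (`err_smooth` = 0.5, time constant ≈2 samples). The GC index is
ln(reduced/full innovation variance), floored at 0, where the reduced
model omits the source channels; it is computed per subject and averaged.
`err_smooth` deliberately differs from `adapt_const`: with a long-memory
variance track the whole window behaves as a single random draw and the
per-timepoint significance counts become bimodal; a short memory makes
exceedances local and the downstream binomial test meaningful.

Per-timepoint significance compares the observed subject-mean GC with the
(1−alpha) quantile of ≥100 surrogate ensembles built by circularly
time-shifting the source channels per subject (autocorrelation preserved,
cross-dependence destroyed). The floored log-ratio has a positive
finite-sample bias (the full model has more parameters); the bias is
common to observed and surrogate statistics and cancels in this
comparison. A pair's strength is its count of significant timepoints
(timepoints before `order` carry no estimate and are excluded from the
window length). The count is tested against a baseline rate estimated from
a non-decoding control ROI pair — pooled over both directions of that
pair and floored at 1/window_len — with a one-tailed exact binomial test,
then Benjamini–Hochberg FDR over the k(k−1) candidate directed pairs;
mutually significant pairs are flagged reciprocal.

At the 76-sample window the per-timepoint count statistic separates
coupled from uncoupled pairs cleanly in node-signal simulations with the
default gain; pushed through the complete epochs→decoding pipeline the
separation narrows (the accuracy channel quantizes and saturates), so
end-to-end runs demonstrate direction recovery by the mean-GC ranking
while count-based calibration and FDR properties are validated at the
node-signal level.

## Problem sizes used in validation

The suite and the acceptance script run reduced-but-faithful problem
sizes chosen as the package's own desk-scale defaults: calibration runs
use 8 subjects and 5 ROIs with 3–5 bin assignments on 25–50-sample time
grids; recovery runs use 12 subjects, 8 blocks (4 talkers), a 2-ROI family
(one signal, one null ROI), 3 assignments, a 20-ms grid and 1,000
permutations; connectivity validity runs use 8 subjects, 76-sample
windows, 120–200 surrogates and 10–12 Monte-Carlo repetitions; the
end-to-end demo uses 12 subjects, 5 ROIs, 6 assignments and an 8-ms grid.
Full-design values (100 assignments, 1-ms grid, 1,000 permutations, 200
surrogates) remain the library defaults.

## Numerical choices and degenerate inputs

Zero subdivision vectors normalize to zero, not NaN. Zero-variance
t-tests resolve by the sign of the mean (significant only if positive).
Permutation p-values are smoothed, (k+1)/(n_perm+1), never zero. SVM ties
at the decision boundary go to class A. The Kalman covariance is
symmetrized each step; `gc_index` is floored at 0; `alpha ≥ 1` in the
surrogate test returns an all-true mask. Binomial control rates are
floored at 1/window_len. Schedules, tensors, bins, permutations and
surrogates all derive from explicit seeds; identical seeds give
bit-identical outputs.

## Known limitations

* The generator's rectangular envelopes and white noise make cluster
  inference slightly conservative relative to temporally smooth real data;
  the optional AR(1) noise switch exists to stress this.
* The binomial count test inherits serial dependence of GC exceedances
  from the data; the control-pair baseline absorbs the common part, but
  strongly autocorrelated GC tracks (small `err_smooth`) would break it.
* With few subjects the sign-flip null's resolution (≈2^−n) bounds
  attainable cluster p-values; Bonferroni over 39 ROIs is only meaningful
  with ≳11 subjects.
* The per-timepoint GC significance rule and the exact binomial
  formulation are package choices behind documented defaults; the
  reference analysis does not specify them.
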