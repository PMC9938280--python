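# Methods

`cognistack` implements a discovery–validation workflow for binary
case-control classification on tabular cognitive and socio-cognitive
feature batteries: repeated, double-cycle nested cross-validation of
linear support-vector classifiers with fold-safe preprocessing and
greedy wrapper feature selection; stacked fusion of the unimodal
classifiers; permutation significance of the out-of-training balanced
accuracy; frozen-model application to external cohorts (OOCV); and
decision-score staging of unlabeled intermediate groups.  This note
records the model, its assumptions, the numerical choices, and what
the synthetic cohorts do and do not establish.

## The classification model

Each base learner is a soft-margin linear SVM minimizing

    (1/2)‖w‖² + C Σᵢ cᵢ max(0, 1 − yᵢ(w·xᵢ + b)),

with per-class weights `cᵢ` proportional to inverse class frequency,
because the pipeline optimizes balanced accuracy (BAC) on imbalanced
cohorts (roughly 2:1 controls:cases).  The dual is solved exactly
(libsvm, tolerance 1e−6), so training is deterministic.  A subject's
*decision score* is the geometric signed distance from the hyperplane,
(w·x + b)/‖w‖, with patients on the positive side; the predicted label
is the score's sign.  Geometric normalization makes scores comparable
across base models with different weight norms, which matters because
scores are averaged across an ensemble and reused as stacking inputs.
If a solution has ‖w‖ = 0 (pathologically small C) the raw margin is
returned instead of dividing by zero.

## Nested cross-validation geometry

The outer cycle (CV2) exists solely to estimate generalization: by
default 10 stratified folds × 5 repetitions, with subjects reshuffled
within their diagnostic groups between repetitions.  Inside each outer
training partition an inner cycle (CV1), by default also 10 folds × 5
repetitions, drives *all* fitting: preprocessing parameters,
regularization tuning, and feature selection.  Each CV1 partition
contributes one base model, so a full-geometry run carries the
canonical 50 base models per CV2 partition.  Outer-test subjects are
predicted by majority vote over the partition ensemble; the reported
per-subject score is the arithmetic mean of the geometric decision
values over all votes the subject received (one ensemble per outer
repetition, i.e. `outer_repetitions × inner_folds × inner_repetitions`
votes in total).  Vote ties resolve to the sign of the mean score, and
a zero mean falls to the control label (a conservative tie-break: no
subject is called a patient on a coin flip).

Fold assignment uses stratified K-fold on the labels only, so per-fold
class counts are within one subject of perfect stratification; a class
smaller than the fold count is a configuration error.

## Fold-safe preprocessing

Three steps, estimated on a CV1-training partition and applied frozen
everywhere else, in this order:

1. **Feature-wise min–max scaling** to [0, 1] on observed training
   values.  Constant training features map to 0 (the map stays total),
   and out-of-range test values are *not* clamped — clamping would
   silently distort external cohorts that drift from the training
   distribution.
2. **k-nearest-neighbour median imputation** (k = 7).  A missing cell
   is filled with the median of that feature over the k nearest
   training subjects that observe it.  Distance is Euclidean over
   coordinates observed in both rows, normalized by the number of
   shared coordinates (so rows with different missingness patterns are
   comparable); neighbour ties break on the lower training-row index,
   making imputation deterministic.  A query sharing no observed
   coordinate with any eligible neighbour receives the feature's
   training median.  Observed values are never altered.
3. **Covariate residualization.**  Per-feature least-squares betas on
   [intercept, age, gender] are estimated on the scaled-and-imputed
   training matrix and subtracted using each subject's own covariates.
   This is the standard linear confound-removal reading of
   "regressing out" age and gender; nonlinear confound models are out
   of scope.

Whether residualization should precede or follow imputation is not
dictated by the workflow itself; this implementation follows the
enumerated order scale → impute → residualize.

## Hyperparameter tuning and feature selection

C is tuned once per outer partition by maximizing mean CV1-validation
BAC over a default grid of 11 powers of two, 2⁻⁶…2⁴ (spanning heavily
under- to over-regularized fits); ties go to the smaller C (more
regularization).  The greedy forward wrapper then runs per base model
with the tuned C: starting from the empty set it adds, at each step,
the feature maximizing validation BAC of a retrained SVM, and stops
when no candidate strictly improves the score or a feature budget is
reached.  The first feature is always accepted so every base model is
trainable; candidate ties break to the lower feature index.  Per-step
re-tuning of C inside the wrapper would multiply cost by the grid size
for little benefit and is deliberately not done.

Selection probabilities are the fraction of base models (across all
outer partitions) whose final mask contains a feature; figure-style
reports filter at probability > 0.5.

## Stacking

The multimodal classifier learns from meta-features, one per modality:
each subject's *out-of-training* mean decision score from the
corresponding unimodal run.  In-training scores are never used — they
are optimistically biased and would leak label information into the
meta level.  The meta table then goes through the identical nested-CV
machinery (same preprocessing chain, same SVM, selection trivially
small with two meta-features).  The aggregated per-subject score (not
the per-partition score vectors) is the default meta-feature; this is
the simplest representation consistent with one score per participant.

External application of a stacked model first scores the external
cohort with the frozen unimodal ensembles, builds the external meta
table from those scores, and applies the frozen stack — no quantity is
ever re-estimated on external data.

## Permutation significance

Labels are permuted freely across the cohort (1000 permutations by
default).  For each permutation every linear SVM is retrained on the
permuted labels while the fold assignments, preprocessing parameters,
tuned C, and wrapper-selected feature subsets of the observed-label
run stay frozen, and the permuted out-of-training BAC is assembled
exactly as in the observed run.  Freezing the subsets follows the
retrain-with-observed-subsets design; preprocessing is label-free, so
reusing it is exact, not an approximation.  The p-value is
`#{permuted BAC ≥ observed}/n`, with the conservative `(k+1)/(n+1)`
variant reported alongside (the plain estimator can return 0, which is
convenient for reporting but not a valid probability statement).  A
permutation that leaves a CV1-training fold single-classed yields a
constant vote for that class.

## Group statistics

Out-of-training decision scores of staging cohorts (e.g. clinical
high-risk, first-episode) are compared with the discovery groups by
one-way ANOVA with Tukey-HSD post-hoc contrasts by default; plain
uncorrected pairwise t-tests are available because the original
pairwise p-values' correction procedure is not documented, and neither
mode is asserted as "the" original.  Demographic contrasts use the
pooled-variance two-sample t for continuous variables and the
Yates-corrected Pearson χ² for 2×2 gender splits — exactly these two
dialects reproduce the published demographic statistics (t = 10.3 for
current IQ, χ² = 26.24 and 1.99 for the gender ratios) from the
printed summaries.  AUC is the rank-based probability that a random
case outscores a random control, ties counting one half.

## Synthetic cohorts

The generator emulates the *structure* the pipeline assumes, not any
particular instrument.  Within each feature block, subjects are drawn
from an exchangeable-correlation Gaussian (shared factor + independent
noise), with a sparse subset of features mean-shifted in the case
group by a specified Cohen's d relative to the nominal within-group
SD.  Age is drawn from group-specific normals and gender from
group-specific Bernoullis (defaults mirror the published
demographics: e.g. controls ~26.6 ± 7.6 y vs bipolar patients
~38.1 ± 13.7 y), and both load linearly onto every feature, so the
between-group covariate differences create genuine confounding that
residualization must remove.  Missingness is MCAR on feature cells
only; labels and covariates are always complete.  Identical spec +
seed reproduces a byte-identical table.

Default conditions, fixed once: 5 informative features per block at
d = 1.2, block correlation 0.2, covariate loadings 0.15 (age, gender),
5% missingness — values a practitioner would call realistic for
neuropsychological batteries, since no per-feature distributional
summaries were available to calibrate against.  With nonzero loadings
the realized standardized effect is computed against the
loading-inflated nominal SD, so planted d values remain interpretable;
the clean-recovery tests (d within ±0.02 at n = 50 000/group) use zero
loadings.

What passing synthetic tests do **not** show about real data: the
generator has no item-level psychometrics, no nonlinear covariate
effects, no informative missingness, no site or battery-version
effects, and exchangeable correlation is far simpler than real test
intercorrelation structure.  Results on these cohorts validate the
*machinery* (no leakage, correct aggregation, recoverable signal), not
clinical performance.

## Problem sizes used in the shipped tests

The full 10 × 5 / 10 × 5 geometry with 1000 permutations is the
configured default but is computationally heavy; the test suite runs
scaled-down geometries chosen to keep the statistical claims intact:

* null calibration: 20 signal-free cohorts of 77 + 77 subjects,
  16 features, outer 5 × 1 / inner 5 × 1, 100 permutations each —
  mean out-of-training BAC must sit in [43, 57]% and permutation
  p-values must be approximately uniform;
* signal recovery: 20 cohorts of 150 + 150 subjects with the default
  planted effects, outer 5 × 1 / inner 5 × 2 — the inner geometry
  keeps the canonical 50 base models per outer partition, which the
  selection-probability aggregation needs for reasonable granularity
  (with 25 models the probability grid is too coarse to rank 52
  features stably);
* unit tests: 70-subject cohorts with 8 + 6 features, 3 × 1 / 3 × 2
  folds.

## Known limitations

* The wrapper is O(steps × features) SVM retrains per base model;
  full-geometry runs on 50+ features are minutes-to-hours, not
  seconds.  Thread-level parallelism is not implemented.
* Only two-group classification; multi-class staging is handled by
  score comparison, not by multi-class models.
* The preprocessing chain imputes features only; subjects with missing
  age/gender are rejected, not imputed.
* Decision-score aggregation (arithmetic mean of geometric scores) is
  one reasonable combiner among several; rank-based aggregation is not
  implemented.
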