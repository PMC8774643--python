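# Methods

This note records the models, conventions and design choices behind the
package, in the spirit of a statistical-software methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Feature representation

A subject is a vector over the canonical column universe: 68
Desikan–Killiany parcels (34 labels × 2 hemispheres) × 4 morphological
measures × 2 robust bounds = 544 columns.  Canonical ordering is
hemisphere (left before right), then parcel label in alphabetical
registry order, then measure (`Sa`, `V`, `Th`, `c`), then bound (lower
before upper).  Column tokens follow
`<hemi>_<label>_<measure>_<bound>` with `hemi ∈ {lh, rh}`,
`measure ∈ {area, vol, thick, curv}`, `bound ∈ {lo, hi}`.  The parcel
order is a package convention — any fixed order works; alphabetical is
reproducible without reference data.

The robust bounds are `median ± IQR` of the within-parcel vertex values.
Quartiles use linear interpolation between order statistics (the common
"type 7" rule); other quartile conventions differ by `O(1/n_vertices)`
and change nothing downstream.  Bounds are *not* clipped to physically
admissible ranges: they are a statistical envelope, and a negative lower
bound for thickness simply records a wide, skewed vertex distribution.
Aggregation accepts any non-empty vertex set and logs a warning below 10
vertices.

## Cohort assembly

Exclusion always runs subjects first, sites second (the order is
observable: dropping incomplete subjects can tip a site's balance).  A
subject is dropped iff any of its feature entries is missing.  A site is
dropped iff its majority-class count divided by its total *exceeds* 0.6
(strict; exactly 0.6 is retained).  The balance rule is deliberately
phrased on the majority-class fraction rather than on the raw ASD:TD
ratio — a ratio bound of 0.6 would discard every nearly balanced site
(19 ASD : 18 TD gives a ratio of 1.06), which cannot be the intent of a
balance filter.  The threshold is configurable.

Demographic diagnostics (diagnosis chi-square, Welch age t-test,
within-group sex chi-square against a uniform split) are descriptive
only and never gate the pipeline.  Degenerate cases (a single-sex group;
zero age variance in both groups) are flagged rather than raised.

## Age/sex harmonization

`Vs(a)` is a per-sex piecewise-linear normative trajectory of mean
cortical grey volume: steep rise in childhood, adolescent peak, slow
decline, with the male curve above the female.  Volumes are replaced by
`V/Vs(a)`; surface areas by `S/Vs(a)^(2/3)` (areas scale as the 2/3
power of volumes under isotropic growth); thickness and curvature are
not adjusted, as no normative formula is defined for them here.  The
packaged curve table is a documented stand-in with the canonical shape
and plausible magnitudes (peak ≈ 585 000 mm³ male, ≈ 520 000 mm³
female); studies with access to population-specific normative curves
should substitute them via `load_growth_curves(path)` or the
`--growth-curves` CLI option.  Because the adjustment is a positive
per-subject scalar, it commutes with the median/IQR aggregation, so
adjusting aggregated bounds equals adjusting vertex values first (the
property suite verifies this).

Min–max normalization maps each column to [0, 1].  The default
(`mode="paper"`) fits min/max on the full matrix before any
cross-validation, replicating the original protocol of the study design
this pipeline operationalizes; `mode="leakage_safe"` fits on training
rows only and clips held-out values into [0, 1].  Constant columns map
to all zeros rather than raising, so degenerate synthetic inputs cannot
abort a run.

## RFECV

Per stratified fold: fit the backend on the training rows, score the
validation rows by balanced accuracy, remove the least important
feature, repeat until one feature remains — recording a score at every
feature count.  Scores are averaged over folds per count; the optimum
`Nf` is the argmax, with ties resolved toward fewer features
(parsimony).  The final atlas comes from one more elimination pass over
all rows, stopped at `Nf` survivors.  One feature is removed per step
(no step acceleration) so the elimination order is exactly the
ascending-importance order a brute-force oracle predicts.

Backends and importances: `lg1`/`lg2` are L1/L2-penalized logistic
classifiers (the classification forms of LASSO/ridge), `lsvm` a linear
SVM — importance is `|coefficient|` — and `rf` a random forest with
impurity importances.  Regularization strengths are fixed documented
defaults (`C = 1.0`; 50 trees) and are not tuned inside the elimination
loop, which performs no nested search.  Importance ties break toward
the lowest canonical column index.  Folds are stratified by diagnosis
with a recorded seed; if the smaller class has fewer members than the
requested 10 folds, the fold count is reduced to that size with a
logged warning, so small sites keep both classes in every training
fold.  Balanced accuracy `½(TP/Pos + TN/Neg)` is undefined (hard error)
when either class is absent from the evaluated rows.

## Classifier selection

Eight families, stratified 5-fold CV, balanced accuracy, exhaustive
grid enumeration; the best mean wins, with ties broken toward the grid
point with fewer hyper-parameters and then the earlier family in the
canonical order.  The default grids are package constants: logistic and
linear-SVM `C ∈ {0.01, 0.1, 1, 10}`; passive–aggressive aggressiveness
`∈ {0.01, 0.1, 1}` (implemented as hinge-loss SGD with the `pa1`
learning rate, the documented equivalent form); random forest
`{100, 300}` trees; RBF SVM `C ∈ {1, 10} × gamma ∈ {scale, 0.01, 0.1}`;
gradient-boosted trees (xgboost) `{100, 300}` rounds at depth 3;
Gaussian naive Bayes (single point); neural network with one hidden
layer `(32,)` ("shallow") or two `(64, 32)` ("deep"), tanh activation,
SGD with adaptive learning rate and L2 penalty `1e-4`.  "Shallow and
deep" is one family with depth as a grid axis, keeping eight families.
A `small_classifier_specs()` variant with single-point grids exists for
smoke and determinism runs.

## Atlases, markers, explanations

For each scope the backend whose downstream best classifier scores
highest defines the atlas (ties → backend order `lg1 < lg2 < lsvm <
rf`); all four backends' outcomes are retained in the run report.  A
column is a candidate marker when the global atlas and ≥ `min_local`
(default 3) local atlases select it; the marker table also records the
per-site mutual counts `|global ∩ local|`.  The region-level rollup
lists a region once per selected (measure, bound) column, preserving —
and flagging — duplicates.

Explanations perturb the subject in the normalized feature space
(Gaussian per column, sd from the training matrix), weight samples by
`exp(−d²/w²)` on standardized Euclidean distance with default kernel
width `w = 0.75·√p`, and fit a weighted ridge surrogate to the
classifier's continuous score (`P(ASD)` when available, else the
decision margin).  Contribution of column j is
`coef_j · (x_j − mean_j)`; positive pushes toward ASD.  Region scores
are signed sums of their columns' contributions, so the rollup is
exactly complete.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not any real
dataset: per-site ASD/TD counts and age ranges fixed by the
configuration (the default 12-site layout totals 664 subjects, 328
ASD/336 TD, with site UM contributing 134); lognormal per-vertex
distributions for area (`exp N(log 0.6, 0.35²)` mm²) and volume
(`exp N(log 2.0, 0.35²)` mm³) — right-skewed, which is what motivates
the median/IQR representation — and Gaussian thickness
(`N(2.5, 0.5²)` mm) and curvature (`N(0.12, 0.05²)` 1/mm); volumes
multiplied by `Vs(age)/V_ref` and areas by its 2/3 power, coupling raw
features to age; per-site multiplicative scanner scales in [0.9, 1.1]
plus small additive offsets; 4:1 male:female imbalance in both groups
by default; optional missing-feature injection that always removes both
bounds of a (parcel, measure) pair.

Between-subject variation is a multiplicative subject factor per
(parcel, measure) with sd `subject_sd = 0.08`.  A planted effect of
standardized size `d` multiplies ASD subjects' values by
`1 + direction·d·subject_sd`, so group separation on the aggregated
column is approximately `d` subject-level standard deviations (slightly
less once vertex-sampling noise and site effects are added).  All draws
flow from a single `numpy` Generator seeded by the configuration, so a
cohort is a pure function of its config.

What the generator does *not* emulate: spatial correlation between
neighbouring parcels, realistic covariance between measures,
heavy-tailed site failure modes, or any image-level artifact.  Passing
tests therefore demonstrate the pipeline's statistical machinery —
exclusion logic, harmonization, selection, scoring, explanation — under
controlled conditions, not performance on real MRI.

## Benchmark experiments and problem sizes

The experiments in `neuromark.experiments` (run by the acceptance
script and `tests/test_acceptance.py`) use the reduced 64-column
universe (4 registry labels × 2 hemispheres × 4 measures × 2 bounds)
and n = 200 single-site cohorts for the selection experiments, and a
0.1-scale 12-site layout over 32 columns for the end-to-end determinism
check — sizes chosen so the full set completes in minutes on one CPU
while leaving the statistical questions intact.  The cohort-bookkeeping
experiment generates the full 12-site layout (664 subjects) at the
reduced universe.

Two calibration experiments (null cohort, strong d = 3 plants) score
the selected-and-tuned model on an *independently generated held-out
cohort* with leakage-safe normalization rather than by in-sample CV:
feature selection performed on all rows followed by cross-validation
over those same rows is optimistically biased by construction, and a
chance-level calibration check is only meaningful on data the selection
has never seen.  The pipeline's default reporting mode remains the
in-sample protocol (with `leakage_safe` available throughout); the
hold-out design is specific to these two experiments, whose purpose is
calibration.

## Numerical and degenerate-input conventions

- Seeds: every stochastic component takes an explicit seed; experiment
  sub-seeds derive from SHA-256 of `(seed, tag)` reduced below 2³¹.
- JSON artifacts are written with sorted keys; equal objects produce
  byte-identical files.
- Ties: argmax ties in `Nf` → smallest count; importance ties → lowest
  column index; grid ties → fewer hyper-parameters, then family order;
  backend ties → backend order.
- Hard errors: empty vertex sets, duplicate (parcel, measure) sample
  sets, non-positive ages, single-class training folds, balanced
  accuracy without both classes, atlases referencing absent columns,
  models without a score function, cohorts of fewer than 4 subjects.

## Known limitations

- The growth-curve table is a shape-faithful stand-in, not fitted
  normative data; absolute adjusted magnitudes are only meaningful
  relative to it.
- The in-sample selection protocol inflates CV scores on small sites
  (an effect the held-out calibration experiments quantify at the null);
  per-site accuracies from tiny cohorts should be read accordingly.
- The surrogate explainer assumes local linearity of the classifier
  score; its weighted R² is reported so unfaithful fits are visible.
- Reduced fold counts at very small sites (down to 2) make those local
  atlases noisy; the marker criterion (global ∧ ≥3 locals) is the
  guard against over-reading any single site.
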