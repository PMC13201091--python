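# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `msprofiler`, stage by stage.

## Severity normalization

Each clinical measure is transformed to a 0–1 severity within the
analysis cohort by its empirical cumulative distribution. Measures where
higher raw scores mean better performance (SDMT, BVMT-R) are negated
first, so severity is always worseness-oriented. The rank convention is
the midrank transform `s = (r − 1)/(n − 1)` with ties sharing the
average rank: both endpoints are attained (a strictly best score maps to
exactly 0, a strictly worst score to exactly 1), which the textbook
`r/n` ECDF cannot do. Severity is computed within the cohort, not
against an external norm; `ECDFNormalizer.transform` on new subjects
interpolates into the fitted cohort's distribution, clipping outside the
observed range. Missing values are rejected by name; at least two
subjects per measure are required.

Consequence worth knowing: an ordinal measure (EDSS, half-point grid)
passes through the ECDF as tie groups — many subjects share one severity
value. Downstream models must treat such point masses sensibly (see the
variance floor below).

## Latent profile analysis

Profiles are latent classes of a finite Gaussian mixture over the five
severities, fit by EM. Two diagonal covariance structures are available:

* `equal` (default) — one variance per measure, shared across profiles
  (the common LPA default);
* `varying` — a separate diagonal variance vector per profile.

Which variant the motivating analysis used is not stated; both are
selectable and tested. EM details: `n_starts = 20` k-means++-seeded
restarts (best likelihood kept), convergence at ΔLL < 1e-6, at most 500
iterations; the observed-data log-likelihood is asserted non-decreasing
at every step. EDSS is treated as continuous after normalization.
Posterior ties are assigned to the lowest-index profile and flagged.

**Quantization variance floor.** The M-step clamps each dimension's
variance at `(largest tie-group mass)² / 12`. Rationale: a tie group of
mass *m* on the severity scale is a quantization bin of width ~*m*, so
variance below *m*²/12 resolves measurement granularity, not structure;
without the floor, EM either collapses onto EDSS point masses (varying
model) or spends extra components on them (equal model). Clamping is the
exact maximizer of the EM Q-function under the constraint, so
monotonicity is preserved. For continuous measures the floor is
~(1/n)²/12 and never binds.

**Selecting the number of profiles.** Models with K = 1..10 are fit and
BIC/AIC recorded (`BIC = −2LL + p ln n`, lower better). The default
selection rule is the point of diminishing returns: scanning K upward,
stop at the first K whose BIC improvement when moving to K+1 falls below
τ = 0.25 of the K=1→2 improvement (or is non-positive). The rationale is
structural: after ECDF normalization each latent class is only
piecewise-Gaussian (a well-separated class's severities are near-uniform
on a sub-interval), so beyond the true class count the BIC keeps
creeping down in small steps as components subdivide non-Gaussian shape;
the argmin chases those crumbs while the diminishing-returns point
tracks the class count. On default synthetic cohorts the improvement
ratio drops from ≥ 0.38 (K=2→3) to ≤ 0.19 (K=3→4) under both covariance
models, so the rule is insensitive to τ over a wide band; plain
argmin-BIC remains available (`selection="min_bic"`) and is always
reported alongside. A single tight cluster yields a non-positive first
improvement and selects K = 1.

Ten-fold cross-validation assesses generalisability (held-out mean
log-likelihood per fold) and stability (adjusted Rand index between
held-out hard labels from the fold model and the full-data model; ARI is
label-permutation invariant, so no explicit component matching is
needed).

## Lesion disconnectomes

The reference tractogram is a set of ordered voxel paths with endpoints
in labelled regions. HC counts all streamlines by unordered endpoint
pair (symmetric N×N); a streamline is *affected* iff at least one voxel
of its path is lesioned (path-based, not endpoint-based); AC counts
affected streamlines the same way. Disconnection is
`D = 1 − (HC − AC)/HC = AC/HC` where HC > 0; entries with HC = 0 are
defined as 0 and carried in a defined-entry mask so 0/0 never
propagates and undefined pairs can be excluded from feature tables.
Self-connections stay on the diagonal and enter regional sums once.
Regional disconnection is `r_i = Σ_j AC_ij / Σ_j HC_ij`; the whole-brain
value is total affected / total streamlines (each streamline counted
once). The whole-brain statistic has no published formula; the
total-ratio definition is this package's choice. Inputs with AC > HC
anywhere are rejected as inconsistent. Lesion-superset monotonicity (a
larger mask never decreases any disconnection value) holds exactly and
is property-tested, as is equivalence with per-streamline brute-force
enumeration.

## ICA covariance patterns

FastICA (fixed-point, symmetric/parallel mode, logcosh contrast with
α = 1, tol 1e-4, ≤ 200 iterations — convergence flagged) is applied to
column-centered subjects × regions matrices after whitening onto the
top-k principal subspace. The implementation delegates the fixed-point
iteration to scikit-learn's FastICA behind this module's surface.
Because ICA signs and order are arbitrary, components are oriented so
the largest-|loading| region is positive, loadings are reported
row-unit-norm, and `match_components` aligns estimated with reference
sets by maximum-|correlation| assignment (Hungarian algorithm).
Variance explained is defined on the whitening (PCA) subspace — the
fraction of total centered variance captured by the top-k principal
directions — because independent components do not individually
partition variance. The disconnection input to ICA is the regional
vector r_i, not the N×N matrix.

## Statistics

Per-feature comparisons fit a linear model with profile indicators plus
age, sex and disease duration; for MRI-derived features a random
intercept per scanner is added (REML via MixedLM), falling back to fixed
scanner effects — flagged in the result — when fewer than 3 scanners
are present or the variance component degenerates. All three pairwise
profile contrasts (difference of adjusted means, SE, p) are extracted
from one fit via the coefficient covariance. BH-FDR is applied across
all contrasts of one call, and each result carries its family label;
one family per analysis table is the convention. Constant outcomes
return β = 0, p = 1 by construction. Chi-square tests are Pearson
without continuity correction. Propensity matching fits a logistic
model of group membership on EDSS and disease duration, takes the
caliper as 0.2 × SD of the pooled propensity scores (probability scale,
as worded in the motivating description; a logit-scale option would be
a one-line change), and matches greedily 1:1 without replacement with
treated units processed in seeded-random order — order changes greedy
results, so determinism comes from the seed.

## Profile drivers

For each profile, a one-vs-all XGBoost classifier is trained in nested
stratified CV: 10 outer folds give out-of-fold predictions covering
every subject exactly once; within each outer training fold, a small
hyperparameter grid (depth {2,3,4} × learning rate {0.05, 0.1} ×
subsample {0.8, 1.0}, ≤ 500 rounds with early stopping after 20
stagnant rounds) is scored by 5-fold inner-CV validation AUC, and the
winning configuration is refit on the full outer-training fold at the
median early-stopped round count. Class imbalance is handled by
positive-class scale weighting. SHAP values use the exact TreeSHAP
algorithm (xgboost's `pred_contribs`) computed only on held-out data
with the fold's own model, so no subject's attribution comes from a
model that saw them — additivity (SHAP values + base value = margin) is
asserted per held-out sample. Features are ranked by mean |SHAP| with
alphabetical tie-break. The LASSO sensitivity analysis fits one-vs-rest
L1 logistic regression on standardized features with the penalty chosen
by cross-validated deviance under the one-standard-error rule (the
sparsest model within one SE of the best mean CV score).

## Synthetic cohorts

The generator plants known structure so recovery can be measured:

* **Clinical.** Each subject draws a profile (motor / cognitive /
  global disability, default proportions 138:181:261 of 580) and then
  each measure from that profile's truncated normal on its legal range
  (EDSS snapped to the 0–10 half-point grid, times > 0.5 s, SDMT ≥ 0,
  BVMT-R in [0, 36]). Default profile means follow the published
  cohort summaries (e.g. SDMT 56.5 / 36.8 / 39.2; EDSS 4.0 / 4.5 / 6.0).
  Per-measure SDs are the published marginal SDs scaled by a single
  factor 0.45: the printed marginals describe a strongly correlated
  real cohort, and drawing measures *independently* at those SDs
  overlaps the profiles far more than the published model's posterior
  certainty (mean assigned posteriors 0.89–0.99) indicates; the 0.45
  calibration restores that separation level (generated mean assigned
  posteriors ≈ 0.94–0.99). Covariates: age, disease duration, sex and
  PPMS/SPMS mixing per profile at published values (SPMS-enriched in
  the global profile), subjects spread over 5 scanners.
* **Imaging.** A parcellation of compact BFS-grown regions (default 12
  regions of 40 voxels on a 32³ grid; a 123-region mode mirrors
  full-atlas dimensionality) with background "white matter";
  streamlines are 3-D digital lines (Bresenham-style voxel traversal)
  between random voxels of each region pair, optionally jittered.
  Lesion masks draw their voxel count from the profile's truncated
  normal (published ml burdens 10.799 / 21.628 / 18.013 scaled by 8
  voxels/ml) and place voxels by a Gaussian field mixed with a uniform
  floor, centered centrally for the cognitive profile, mid-way for
  global, peripherally for motor — so both lesion volume and
  whole-brain disconnection order cognitive > global > motor by
  default. Regional volumes are baseline + planted unit-norm component
  loadings × profile-shifted subject scores + Gaussian noise
  (amplitude 0.6, noise SD 0.2), clipped positive.

What the generator does **not** emulate: within-profile correlation
between measures, realistic neuroanatomy or lesion morphology,
continuous-coordinate tractography, scanner effects on imaging values,
missing data. Passing tests therefore demonstrate correctness of the
algorithms and recoverability of planted structure under idealized
sampling — not performance on real MRI.

## Problem sizes and numerics

Tests run at desk scale by design: cohorts of 40–600 subjects (580 for
recovery checks, matching the published cohort size), 4–12 regions,
16³–32³ grids, toy tractograms up to ~1000 streamlines for brute-force
equivalence. Degenerate inputs are handled explicitly: empty cohorts
and tractograms, constant severity columns (midrank 0.5), HC = 0 pairs
(defined-entry mask), constant outcomes in contrasts, zero-caliper
matching. All generators and fits are bit-reproducible for a fixed
seed; every random draw in the pipeline descends from a single
top-level seed via spawned seed sequences.

## Known limitations

* The equal/varying covariance dichotomy does not cover mixtures with
  within-profile correlations; real severity data are correlated.
* The elbow threshold τ = 0.25 is a convention, defensible here because
  the improvement-ratio gap is wide; on data with genuinely ambiguous
  class counts the BIC curve should be inspected directly
  (`SelectionReport.as_frame()`).
* Whole-brain disconnection as total-affected/total is one of several
  defensible definitions (e.g. mean pairwise D would weight sparse
  pairs differently).
* The propensity caliper is applied on the probability scale; matching
  on the linear predictor can differ near 0/1.
* TreeSHAP attributions are with respect to the fitted model's margin;
  they rank associations, not causes.
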