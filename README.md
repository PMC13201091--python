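# msprofiler

Disability profiling of progressive multiple sclerosis: a tested,
reusable implementation of the full analysis pipeline that turns
clinical test batteries and lesion imaging into data-driven disability
profiles and their structural substrates.

Progressive MS is clinically heterogeneous: two patients with the same
EDSS can differ sharply in walking speed, hand function, processing
speed and memory. This package implements the pipeline used to dissect
that heterogeneity:

1. **Severity normalization** — each clinical measure (EDSS, timed
   25-foot walk, 9-hole peg test, SDMT, BVMT-R) is mapped onto a common
   0–1 scale by its empirical cumulative distribution within the cohort
   (midrank convention, `s = (r − 1)/(n − 1)`), with 0 the best and 1
   the worst observed performance.
2. **Latent profile analysis** — finite diagonal-Gaussian mixtures are
   fit to the severity matrix by EM for K = 1..10 profiles; the profile
   count is selected from the BIC curve at the point of diminishing
   returns, and subjects are classified by maximum posterior
   probability.
3. **Lesion disconnectomes** — a reference tractogram is intersected
   with each subject's binary lesion mask; with HC the healthy
   streamline-count connectome and AC the counts of lesion-affected
   streamlines, pairwise disconnection is `D = 1 − (HC − AC)/HC`
   (0 = preserved, 1 = fully disconnected), plus regional and
   whole-brain proportions.
4. **ICA covariance patterns** — FastICA (logcosh contrast, symmetric
   mode, tol 1e-4, ≤ 200 iterations) extracts covarying spatial
   components from subjects × regions matrices of grey-matter volume
   and of regional disconnection.
5. **Statistics** — covariate-adjusted pairwise profile contrasts (age,
   sex, disease duration; scanner as a random intercept for MRI
   features) with Benjamini–Hochberg FDR, chi-square tests, and 1:1
   nearest-neighbour propensity matching (logistic propensity on EDSS
   and disease duration, 0.2-SD caliper, without replacement).
6. **Profile drivers** — one-vs-all XGBoost classifiers in nested
   stratified cross-validation (10 outer / 5 inner folds with early
   stopping), with out-of-fold TreeSHAP attribution and mean-|SHAP|
   feature ranking; L1-penalized logistic selection as a sensitivity
   analysis.

Because the motivating trial data are not publicly deposited, the
package ships a first-class synthetic-cohort module (`msprofiler.synth`)
that generates every pipeline input — clinical tables with a planted
3-profile structure calibrated to published cohort summaries, a
parcellation volume, a voxel-path tractogram, profile-dependent lesion
masks, and regional volumes with planted covarying components — so every
stage is testable against known ground truth.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from msprofiler import CohortConfig, ecdf_normalize, select_profiles, assign_profiles
from msprofiler.synth import generate_clinical

clinical, truth = generate_clinical(CohortConfig(seed=1))   # n = 580
severity = ecdf_normalize(clinical)
report = select_profiles(severity.to_numpy(), k_max=10, seed=1)
assign = assign_profiles(report.models[report.chosen_k], severity.to_numpy())

print(f"profiles selected: {report.chosen_k}")
print(f"subjects per profile: {np.bincount(assign.labels).tolist()}")
print(f"mean assigned posterior: {np.round(assign.mean_assigned_posterior, 3).tolist()}")
print(f"ARI vs planted profiles: {adjusted_rand_score(truth.true_profile, assign.labels):.3f}")
```

prints

```
profiles selected: 3
subjects per profile: [147, 246, 187]
mean assigned posterior: [0.97, 0.99, 0.94]
ARI vs planted profiles: 0.935
```

Three disability profiles are recovered from the severity matrix; each
subject's posterior for their assigned profile is near 1 (unambiguous
classification), and the recovered partition agrees closely with the
planted one (adjusted Rand index 0.935).

The same stages are scriptable from the shell:

```bash
msprofiler run-all --out demo_run --seed 0        # full pipeline, n = 200 demo
msprofiler normalize --in clinical.csv --out severity.csv
msprofiler lpa --severity severity.csv --kmax 10 --seed 0 \
    --out-report lpa.json --out-assignments profiles.csv
```

`run-all` writes every intermediate (severity matrix, profile
assignments, connectomes, disconnection tables, ICA loadings/scores,
adjusted contrasts, SHAP rankings) as CSV/JSON plus a manifest with
per-stage seeds and wall times; reruns with the same config are
byte-identical.

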