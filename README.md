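# phenoface

Quantitative facial phenotyping for the differential diagnosis of two
clinically overlapping dysmorphic syndromes — a Noonan-like class (`NS`)
and a Williams–Beuren-like class (`WBS`) — from frontal face photographs
with annotated landmarks. The package is aimed at researchers in
computational dysmorphology who need an objective, reproducible pipeline
from landmarks and pixels to discriminative facial metrics, classifier
accuracies stratified by ethnic background, and population-average
reference images, without access to large clinical imaging cohorts: a
built-in synthetic cohort generator with planted, calibrated class
structure makes every stage testable end to end.

## What it computes

**Geometry.** From 44 named landmarks per subject, metrics are evaluated
in an intrinsic face frame (origin mid-tragion, x-axis along the
inter-tragion line). Horizontal distances are normalized by the
ear-to-ear distance, vertical distances by the commissure-midpoint-to-
nasion distance, angles are in degrees. Paired metrics yield a symmetric
feature, mean(L, R)/ref, and an asymmetry feature, |L − R|/mean(L, R);
the resulting vector is invariant under translation, rotation, and
uniform scaling. The default catalog holds 23 metrics (34 features).

**Texture.** Around each of 33 inner landmarks, a multi-scale block
local binary pattern compares the landmark-centered patch mean against
its eight neighbors at three block sizes (b ∈ {3, 5, 9} px for a 200-px
inter-tragion face, scaled per subject): bit_i = 1 iff mean_i ≥
mean_center, code = Σ bit_i 2^(7−i), giving 33 × 3 × 8 = 792 features
sensitive to lines, shadows, and local contrast but invariant to
positive affine intensity changes.

**Selection and evaluation.** A linear SVM with per-sample weights
N/(2 N_c) (both classes contribute equal total weight) drives recursive
feature elimination; leave-one-out cross-validation scores every subject
for increasing feature counts k, and the operating point k\* is the
smallest k whose held-out ROC AUC is within ε = 0.005 of the maximum.
Individual features are screened with the Mann–Whitney U test; competing
models (global vs. ethnicity-specific) are compared per stratum and
overall with two-sided Fisher exact tests and relative improvements
100(a_s − a_g)/a_g.

**Atlases.** Generalized Procrustes alignment (similarity transforms)
builds a consensus shape; each image is piecewise-affinely warped onto
it and averaged, producing population-based appearance images per
diagnosis × ethnicity selection.

## Worked example

Generate a small synthetic cohort with the default planted effects
(e.g. wider inner-canthal spacing for NS, wider mouth and thicker lower
lip for WBS, plus two local texture stamps), extract features, and run
the nested selection protocol:

```python
from phenoface.synthetic import SyntheticCohortConfig, generate_cohort
from phenoface.io import feature_table_from_cohort, split_feature_table
from phenoface.selection import SelectionConfig, loocv_curve, feature_screening

cfg = SyntheticCohortConfig(
    group_sizes={("NS", "Caucasian"): 30, ("WBS", "Caucasian"): 50},
    seed=7,
)
cohort = generate_cohort(cfg)
table = feature_table_from_cohort(cohort)
X, y, _ = split_feature_table(table)

res = loocv_curve(X, y, SelectionConfig(protocol="nested", k_grid=(1, 2, 4, 8, 16, 32)))
print(res.k_star, res.accuracy)
```

Output (abridged):

```
cohort: 80 subjects, 826 features (34 geometric, 792 texture)
optimal feature count k* = 16
LOOCV accuracy = 92.5%  (NS 100.0%, WBS 88.0%), AUC = 0.980
top-ranked features (Mann-Whitney p):
  geom.ear_canthus_angle.sym               p = 1.78e-11
  geom.lower_lip_thickness.sym             p = 4.14e-09
  geom.mouth_width.sym                     p = 1.20e-08
planted Bayes accuracy: 99.5%
```

Reading this: with 16 of 826 features the held-out accuracy reaches
92.5% against a planted-model ceiling of 99.5%; the top-ranked metrics
are exactly the planted mouth/lip/eye-region differences (the
ear–canthus angle is a geometric echo of the planted fissure-slant
effect through the shared canthus landmark). Per-class accuracies show
the balanced weighting at work despite the 30/50 imbalance.

A command-line workflow covering the same ground plus stratified
evaluation and atlases:

```bash
phenoface simulate --out cohort/ --seed 1
phenoface extract  --images cohort/images --landmarks cohort/landmarks \
                   --metadata cohort/metadata.csv --out features.csv
phenoface evaluate --features features.csv --out report.json --protocol flat
phenoface stats    --features features.csv --out screening.csv
phenoface atlas    --images cohort/images --landmarks cohort/landmarks \
                   --metadata cohort/metadata.csv \
                   --filter diagnosis=WBS --out atlas_WBS
```

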