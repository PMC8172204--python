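# Methods

`phenoface` quantifies frontal-face photographs of patients with two
clinically overlapping dysmorphic syndromes — a Noonan-like class (`NS`)
and a Williams–Beuren-like class (`WBS`) — and asks which facial metrics
discriminate them, globally and within four ethnicity strata (African
descent, Asian, Caucasian, Latin American). This note describes the
models, the numeric choices, and what the synthetic validation does and
does not establish.

## Landmark scheme and geometric metrics

Analysis starts from 44 named 2-D landmarks per subject: 33 *inner*
landmarks (14 periocular/eyebrow, 9 nasal, 10 perioral) and 11 *outer*
reference landmarks (tragions, ear attachments, zygions, gonions,
menton). Coordinates are 0-based pixels, origin top-left, y downward;
`_L`/`_R` denote the image side. The full table is the
`LANDMARK_NAMES` constant; landmark files are validated against it.

All measurements are evaluated in an intrinsic face frame: origin at the
mid-tragion point, x-axis along the inter-tragion line, y-axis rotated
90° toward the chin. This removes head roll, which photograph inclusion
criteria otherwise have to control. Horizontal distances are normalized
by the inter-tragion (ear-to-ear) distance, vertical distances by the
distance from the oral-commissure midpoint to the nasion ("nose root" is
taken to be the nasion landmark), and angles are interior angles in
degrees, unnormalized. For bilaterally paired metrics,

* symmetric feature: `geom.<m>.sym = mean(L, R) / reference`,
* asymmetry feature: `geom.<m>.asym = |L − R| / mean(L, R)`,

with a degeneracy guard that raises when `mean(L, R)` falls below
10⁻⁶ × the inter-tragion distance. Every feature so defined is invariant
under translation, rotation, and uniform scaling (property-tested to
10⁻⁹), and a mirror-symmetric landmark set has all asymmetries exactly 0.

The default catalog holds 23 metrics (11 paired → 34 features): the
inter-outer- and inter-inner-canthal distances, palpebral fissure
length/height/slant, eyebrow-to-eyelid ("orbital rim") height, eyebrow
length and separation, nasal-bridge offset, nose length/width, ala
length/height, philtrum length, cupid's-bow width/depth, mouth width,
upper/lower lip thickness, lateral lower-lip height, ear–canthus angle,
and midface/jaw widths. The catalog is a reconstruction of a standard
frontal anthropometric set, not a certified copy of any particular
instrument; it is fully overridable via a YAML catalog file, and the
slant/ear angles are defined through three-landmark interior angles
(vertex listed second) because the metric language supports exactly
horizontal distances, vertical distances, and angles.

## Multi-scale block LBP texture

Local appearance around each of the 33 inner landmarks is encoded with a
multi-scale block local binary pattern: at three nested block sizes
R1 < R2 < R3 (default 3, 5, 9 px for a 200-px inter-tragion face, scaled
to each subject's face and rounded to odd integers ≥ 3), the mean
intensity of the landmark-centered patch is compared against its eight
neighboring patches, clockwise from top-left; bit *i* contributes
2^(7−i). Intensity is luminance (0.299 R + 0.587 G + 0.114 B), borders
are edge-replicated, and the tie rule defaults to `≥` (classical
convention; `>` available). The default representation keeps the raw
8 bits per landmark and scale (33 × 3 × 8 = 792 features); a normalized
256-bin code histogram over a (3·block)² window is available as an
alternative.

Because patch *means* are compared, the descriptor is exactly invariant
to positive affine intensity maps and only approximately invariant to
general monotone maps (averaging does not commute with a nonlinear map;
measured: ≤ 1% of bits change under square/log maps on the synthetic
template). Pixels farther than 1.5 × (3 · R3) from every inner landmark
can never influence the descriptor.

## Selection and evaluation protocol

Classification uses a linear SVM (C = 1, squared hinge, primal solver)
on z-scored features with per-sample weights `N / (2 N_c)` so both
diagnostic classes contribute equal total weight. Recursive feature
elimination discards the features with smallest |coefficient| —
10% of the remaining set per round down to 64 features, then one at a
time — with ties broken lexicographically, making the ranking
deterministic. Leave-one-out cross-validation scores every subject with
models trained on the others, over a feature-count grid (default
1..min(40, p) plus powers of two and p itself); the operating count k*
is the smallest whose held-out ROC AUC is within ε = 0.005 of the
grid maximum. Per-feature screening uses the two-sided Mann–Whitney U
test (exact for tie-free samples up to n = 20, otherwise normal
approximation with tie and continuity corrections; Benjamini–Hochberg
q-values are reported alongside the raw p-values used for
interpretation). Model comparisons use the two-sided Fisher exact test
on correct/incorrect counts, plus the relative improvement
100 (a_s − a_g)/a_g.

Two protocols are provided. `nested` (default) recomputes the RFE
ranking inside every training fold, so selection never sees the held-out
subject; it is the honest accuracy estimate. `flat` ranks once on the
full data and only refits per fold; it replicates designs that report a
single optimal feature list and is used for the cohort-scale runs, where
a nested ranking at ~830 features × ~450 folds is an order of magnitude
more fits for the same headline quantities. The reported feature list is
in both cases the full-data ranking truncated at k*.

`stratified_evaluation` runs the protocol once pooled (global model) and
once per ethnicity stratum (specific models), compares the global
model's per-stratum accuracy with each specific model (Fisher, relative
improvement), pools specific-model correct counts into an overall
accuracy, and additionally emits the same overall figures recombined
from the rounded per-stratum accuracies — the accounting needed to check
published stratified tables, where per-class and per-stratum
recombinations can legitimately differ by rounding.

A caution on reading LOOCV curves: the accuracy/AUC *at k** is the
maximum over the evaluated grid, so even a leakage-free protocol shows a
winner's-curse offset under a label-permutation null (≈ +0.11 AUC at
n = 40 with a 6-point grid). The permutation-null tests therefore judge
chance-level behavior on the full-model point and the curve median,
which measured 0.49 both over null cohorts.

## Population mean-appearance images

Atlas images are built by generalized Procrustes alignment under
similarity transforms (no reflection; iterated to 10⁻⁸ or 100
iterations; consensus canonicalized to centroid 0, unit centroid size,
inter-tragion axis horizontal, making it order-independent), followed by
a piecewise-affine warp of every image onto the consensus over a
Delaunay triangulation of the 44 landmarks plus 8 canvas-border anchors,
bilinear sampling, and a pixel-wise mean. Similarity (not affine)
alignment preserves the shape differences the classifier uses;
piecewise-affine warping was preferred over thin-plate splines for
determinism and speed. The canvas is 256×256 px with the face scaled to
a 160-px inter-tragion distance. Atlases meant to be compared (e.g. the
two diagnostic classes) should be built on a shared consensus; note that
warping normalizes landmark geometry away, so class atlases differ where
*appearance* differs at corresponding anatomy, not where landmarks
moved.

## Synthetic cohort generator

Because the study photographs are not programmatically available, the
generator emulates the study conditions end to end and is itself
first-class, tested code. Defaults: 286 WBS + 161 NS subjects split
28/26/121/111 and 35/40/40/46 across the four strata; age-group and sex
marginals matching the cohort description; landmark jitter SD 1.5 px;
random similarity transform (rotation ±10°, scale 0.9–1.1, translation
±10 px); intensity noise SD 4 gray levels on a 256×256 rendering with a
160-px inter-tragion template face. The rendering is schematic —
ellipsoidal shading, drawn brows/eyes/nose/lips, Gaussian blur — but
entirely landmark-driven, so planted displacements are visible in the
image. Strata are signal-modulation groups only; no attempt is made to
render ethnic appearance.

Geometric class structure is planted in landmark space so the whole
extraction path is exercised. Each effect names a catalog metric and a
standardized effect size (class-mean difference of `geom.<m>.sym` in
units of its jitter-induced SD); default ±1.5 for six effects
qualitatively mirroring the reported clinical pattern (NS: wider
inner-canthal spacing, higher brow; WBS: wider mouth, thicker lower lip,
shorter nose, more down-slanted fissures), with some effects zeroed per
stratum to emulate stratum-specific feature lists. The displacement that
realizes an effect is calibrated numerically per template: a
symmetric-difference slope (feature per pixel of displacement) and a
3000-sample Monte-Carlo estimate of the jitter-induced feature SD; the
calibration uses a fixed internal seed, so ground truth is identical
across cohort seeds. Validated: the realized standardized effect of a
planted metric is within 10% of the configured value at n = 400/class.
Appliers for different metrics move disjoint landmarks where possible,
but cross-talk through shared landmarks and normalization references is
unavoidable and is handled by the ground-truth carrier accounting below.

Texture structure is planted by stamping a high-frequency pattern
(stripe bands of 8-px period, or a 3×3 spot grid) near a designated
inner landmark of one class, with incidence 0.75 — the stamp appears in
a random 75% of the target class and never in the other class. Both
choices are load-bearing: the stripe period must be about twice the
descriptor block size to register in block means at all (a 4-px period
aliases away), the contrast (default 60 gray levels) must exceed the
face's own local block contrast at the stamped site (15–30 gray
levels), and incidence below 1 — consistent with published
feature-incidence ranges for these syndromes — prevents single
descriptor bits from becoming one-sided deterministic class detectors,
which would collapse the evaluation to a trivial 100%.

The ground truth emitted with every cohort lists (i) one *primary*
feature per planted signal with per-stratum standardized effects, (ii)
*carriers* — every other feature whose measured standardized class
difference reaches 0.5 in a 150-per-class calibration run of the full
generative model (echoes through shared landmarks, references, and
rendering), (iii) a *signal → attributed features* map built
mechanically from which landmarks each applier displaces or each stamp
marks, and (iv) the planted Bayes accuracy: a Gaussian discriminant
over primaries and carriers jointly with a Ledoit–Wolf shrinkage
covariance and equal class priors. Recovery of planted structure is
judged per signal — a signal counts as found when any feature
attributable to it ranks in the top 2p — because an
redundancy-eliminating ranker such as RFE deliberately keeps only one
representative of a correlated group, and feature-level recovery over
all echoes would measure that elimination rather than detection.

What passing synthetic tests shows: the extraction path is
similarity-invariant end to end, the protocol is leakage-free, planted
effect sizes are realized faithfully, and the selection finds planted
structure at the emulated cohort scale (seed 1: LOOCV 96.2% vs planted
Bayes 97.4%, all 8 signals recovered, k* = 8). What it does not show:
performance on real photographs — the renderer has none of the
illumination, pose, occlusion, age, or identity variation of clinical
images, its class differences are planted rather than biological, and
its texture differences are far more stereotyped than real
dysmorphology.

## Problem sizes and runtime choices

Cohort-scale runs (tests and the acceptance script) use the flat
protocol with the k-grid capped at 1..40 plus 48 and 64: the planted
model's AUC converges far below 64 features, while SVM fits at k ≳ 500
near-collinear features dominate runtime without moving k*. The
permutation-null and null-cohort checks run on landmark-only cohorts
(34 geometric features) with a coarse RFE step of 0.3, where the nested
protocol is affordable. Reported figures in this note were produced by
the test suite and `scripts/acceptance.py` on these problem sizes.

## Known limitations

* Figure-level specifics of the original instrument (exact metric list,
  LBP variant, patch sizes) are not recoverable; catalog and descriptor
  are configurable reconstructions.
* Age and sex are carried as metadata but not used for normalization.
* The Latin-American row of the published stratified table is internally
  inconsistent (its improvement and p-value do not follow from its
  accuracy pair); the implementation always reports values computed from
  the accuracy pair.
* `flat` protocol leaks ranking information by construction; use
  `nested` when the accuracy estimate matters more than runtime.
* Histogram-mode texture (256 bins × 3 scales × 33 landmarks) is
  supported but untested at cohort scale; the 59-bin uniform-pattern
  mapping is not implemented.
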