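# Methods

This note documents the models, conventions and numerical choices behind
`spinepath`, and what the synthetic cohorts do and do not establish.

## Data model and coordinate conventions

A spine is the ordered 3D centroids of the 17 vertebrae T1–L5.  The
package fixes a right-handed anatomical frame: x lateral (positive toward
the patient's left), y sagittal (positive anterior), z vertical (positive
cranial), all in millimetres.  Source data rarely document their global
frame, so this is declared as a package convention and enforced only
through the invariants that matter downstream: exactly 17 vertebrae in
anatomical order, z strictly decreasing from T1 to L5, finite coordinates.
Non-monotone z (conceivable in extreme deformity) is rejected rather than
re-ordered, because linear resampling along z is undefined for it.

## Two-step normalization

**Step 1 — isotropic scaling.**  "Spinal height" is the vertical chord
z(T1) − z(L5), not arc length.  All three coordinates are divided by it
and z is shifted so z(L5) = 0.  Because the factor is shared across axes,
every inter-landmark ratio is preserved.  The (x, y) coordinates are *not*
re-centred: lateral trunk shift and sagittal offset are clinically
meaningful shape signal (they distinguish "balanced" from "unbalanced"
curve types), so removing them would discard information the clustering
should see.

**Step 2 — resampling at the control template.**  The per-vertebra mean of
the scaled control spines' z-levels defines a common grid (endpoints
exactly 1 and 0); each patient's x(z), y(z) are evaluated there by
piecewise-linear interpolation between adjacent centroids — no spline
smoothing, so curves linear in z are reproduced to machine precision and a
spine whose z-levels already match the template passes through unchanged.
After this step z carries no information and clustering uses only the
34-vector (x₁…x₁₇, y₁…y₁₇).

Two invariances are guaranteed (and property-tested): multiplying all
input coordinates by any c > 0 changes nothing (≤1e−10), and rigid
translation along z changes nothing.

## Clustering and choice of k

K-means is written in-package: k-means++ seeding, Lloyd iterations run
batched across restarts, convergence when assignments repeat, and a
per-iteration assertion that the within-cluster sum of squares (SSE) never
increases.  Defaults: 100 restarts, seed 20181102, candidate k ∈ {2,…,6}.
The restart with minimal SSE wins; on instances small enough to enumerate
every partition (n ≤ 8) the best-of-50-restarts solution matches the
global optimum in all randomized trials, and scikit-learn's KMeans is used
as an independent cross-check on easy instances.

Mean silhouette (Euclidean) selects k: s = (b − a)/max(a, b) per point,
with members of singleton clusters scored 0 (the standard convention);
ties in the mean go to the smaller k.  Cluster labels from k-means are
arbitrary, so results are canonicalized — clusters numbered 1..k by
descending size, ties broken by lexicographic center comparison — making
the whole fit bit-reproducible for a fixed seed.  Each timepoint is
clustered fully independently.

## Fusion groups and treatment paths

Every distinct (UIV, LIV) pair is a fusion group, numbered 1..G by
anatomical order of the pair (this deterministic rule, not any published
numbering, defines in-package group ids; the fixture tables retain the
publication's own numbers).  Groups with fewer than 3 patients (default)
are excluded and the survivors renumbered contiguously.  A patient's
treatment path is the triple PO_i-EP_j-F_m; path construction is a pure
function of the label maps, and errors name the patient missing a
component.

Where different fusion groups inside one (PO, EP) stratum lead to the same
outcome, they may be merged: the implemented rule unions paths whose
*modal* 2Y cluster coincides (ties toward the lower cluster index),
summing counts.  The published compound groups are consistent with a
same-outcome merge but the exact criterion is not stated; the modal rule
is this package's formalization.  One transcribed row of the packaged
path-outcome table (PO1-EP2-F3,4: counts 1/1/4) has majority fraction 67%,
below the "at least 70%" summary the source text gives for qualifying
paths; the table is kept as printed rather than reconciled.

## Outcome analytics

The empirical route cross-tabulates paths against 2Y clusters.  A path
with n ≥ 3 patients (the "more than two" threshold) qualifies for
reporting; its concordance is the modal-outcome fraction (reported rounded
to integer percent), and coverage is the share of included patients on
qualifying paths.  Prediction for a path is its modal outcome; unseen
paths return an explicit no-data result and modal ties are flagged
ambiguous (resolved toward the lower cluster index).

The model route fits a multinomial logit of the 2Y cluster on the path,
by default with PO, EP and F as nominal main-effect factors (mirroring
f(PO, EP, F) → 2Y), optionally with the full path as one saturated
factor.  The likelihood-ratio statistic is 2(ℓ_full − ℓ_null) with
df = (non-intercept coefficients) × (K−1) and a χ² reference.  For the
saturated encoding this statistic is identical to the contingency
G-statistic of the path-by-outcome table, which the tests verify against
an independent G-test.  Under complete or quasi-complete separation (any
empty cell in the saturated table) the MLE lies on the boundary; the
package then reports the likelihood supremum (empirical cell proportions,
0·ln 0 = 0) with `separation=True` instead of failing, and a ridge-penalized
alternative estimator is available but clearly flagged as such.  The
published cohort's printed regression statistic implies a model
specification (df) that matches neither encoding, so no attempt is made to
reproduce it numerically.

## Clinical-measure surrogates

True Cobb angles, apical rotations and pelvic parameters require endplate
and pelvis landmarks that centroid curves lack.  The package therefore
computes *surrogates* from the centroid polyline: the tangent-direction
spread (central differences along z, second-order one-sided at span ends)
of the curve projected onto the frontal or sagittal plane over standard
spans (proximal thoracic T1–T5, main thoracic T5–T12, lumbar T12–L5,
kyphosis T1–T12 and T4–T12, lordosis L1–L5 — L1–S1 is impossible without a
sacrum landmark), and T1-minus-L5 balance offsets.  These are invariant to
rigid translation and isotropic scaling.  On a circular arc the
finite-difference tangents recover the subtended angle to within ~0.25° at
17 landmarks; surrogate values are *not* comparable to published
radiographic means and are never asserted against them.  Image-only
quantities are accepted as pass-through columns so the comparison pipeline
can exercise them.

Between-cluster comparison follows a fixed decision rule per variable:
Shapiro–Wilk within every cluster at α = 0.05; if all clusters pass,
one-way ANOVA with Tukey HSD, otherwise Kruskal–Wallis with Dunn's
rank-based post-hoc (tie-corrected; uncorrected p-values by default, since
that matches the source analysis, with a Bonferroni option).  Judging
normality per cluster (rather than pooled) is this package's choice.
Monte-Carlo tests confirm the omnibus false-positive rate is ≈5% under the
null.

## Synthetic cohorts

Cluster templates are sums of Gaussian lobes in the unit-height z
coordinate — a main thoracic frontal lobe with optional proximal/lumbar
counter-lobes and a constant lateral shift, plus kyphosis/lordosis lobes
sagittally — expressing the qualitative morphologies reported for the
clinical clusters (closed-V vs. S-shaped frontal patterns, lateral shift,
hypo-/hyper-kyphosis, proximal kyphosis; EP and 2Y templates have strongly
reduced frontal amplitude, as after correction).  Defaults: 67 patients
and 20 controls; 3 PO / 2 EP / 3 2Y templates with pairwise center
separation ≥ 0.15 in the 34-D feature space (actual minima ≈ 0.36–0.43);
within-cluster Gaussian noise SD 0.02 (unit-height scale) on x and y;
spinal heights uniform on 380–480 mm; fusion-level frequencies matching
the published cohort (8/10/14/12/8/12/2/1), apportioned exactly by largest
remainder with randomized assignment, as are the PO (24/21/19) and EP
(41/23) weights.

The 2Y cluster is planted: a deterministic path→outcome map is followed
with probability φ (default 0.8, in line with the published per-path
concordances), otherwise a different cluster is drawn uniformly.  The
default map buckets the additive score po + ep + f into three intervals;
an additive rule was chosen deliberately so the planted association has
main-effect structure a multinomial logit can represent (a modular rule
would be a parity problem, invisible to additive log-odds).  Noise is
applied to x and y only; z stays equally spaced and strictly decreasing by
construction, which is harmless because normalization discards z
variation.

**What passing tests show — and don't.**  Recovery tests (planted k found
and adjusted Rand index ≥ 0.9 in ≥95/100 seeds; planted concordance inside
its binomial band) demonstrate the pipeline is correct and well-behaved
under the stated generating conditions.  Real cohorts differ in ways the
generator does not emulate: non-Gaussian within-cluster variation,
borderline patients between clusters, correlation between PO shape and
chosen fusion level, measurement error from 3D reconstruction, and cluster
separations that need not be as clean.  Synthetic success is therefore a
software/identifiability statement, not a clinical validation.

## Numerical choices and degenerate inputs

* Lloyd convergence: assignments unchanged (equivalently SSE improvement
  < 1e−10); empty clusters re-seeded at the costliest point.
* All-identical feature vectors: clustering refuses (no meaningful k ≥ 2).
* Zero or negative spinal height: rejected.
* CSV round-trips are bit-exact: floats written with `%.17g` and parsed
  with round-trip precision.
* Percentages are reported rounded to the nearest integer, matching the
  conventions of the source tables.
* Problem sizes in the test-suite simulations (e.g. 100 seeds for
  recovery, 200 enumeration instances, 1000 null datasets) were chosen to
  make Monte-Carlo error small relative to the asserted margins while
  keeping the default run quick.

## Known limitations

* The fusion-group numbering cannot reproduce the publication's G-numbers
  (their rule is unstated); only counts are comparable.
* Surrogate angles are not Cobb angles; no numeric comparison with
  published clinical means is possible or attempted.
* The merge rule for outcome-equivalent fusion groups is a formalization
  of an ambiguous description.
* No modelling of instrumentation mechanics, vertebral rotation geometry,
  or image synthesis; fuzzy/probabilistic clustering is out of scope.
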