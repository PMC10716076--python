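# Methods

This note documents the models implemented in `craniomorph`, the
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that make
results reproducible.

## Landmark sets and templates

Five landmark sets are bundled: craniofacial (37 landmarks, 9 midline +
14 bilateral pairs), facial (22, a strict subset of the craniofacial
set), neurocranial (9), temporalis region (6, one-sided), and a
bite-force set. The bite-force set carries 12 true landmarks and 14
semilandmarks delimiting the temporalis (landmarks 2–4, 9–12;
semilandmarks 16–26) and masseter (landmark 1, 5–8; semilandmarks
13–15), plus the TMJ and the M2 bite point appended as reference
points (ordinals 27 and 28): the published muscle roles exhaust
ordinals 1–26, so the two lever endpoints need ordinals of their own.
Anatomical membership beyond the named landmarks is configurable —
`LandmarkSetSpec` is plain data — and the bundled template skull
supplies deterministic, mutually well-separated (≥ 5 mm) coordinates
for every named landmark. Bilateral partnering is a symmetric
involution; sided landmarks in subset configurations may lack a partner
within the set, in which case they are usable for shape analysis but
not for mirror imputation.

Semilandmarks are never slid and never enter shape analyses; they
contribute only to muscle centroid sizes in the bite-force model.

## Midline plane and mirror imputation

The midline is fitted per specimen from its own present landmarks. The
objective is least-squares symmetry: present midline landmarks and the
midpoints of complete bilateral pairs should lie on the plane, and each
pair's difference vector should be parallel to the plane normal. For a
fixed normal **n** the optimal plane passes through the mean of the
on-plane constraint points, which reduces the fit to minimising
**n**ᵀ(A − D)**n** over unit **n**, where A is the scatter of on-plane
points about their mean and D the sum of pair-difference outer
products; the normal is the eigenvector of the smallest eigenvalue,
with its sign fixed so the first non-negligible component is positive.
Estimation requires at least one complete bilateral pair or three
non-collinear midline landmarks.

A missing landmark whose partner is present is replaced by the
partner's reflection through this plane and flagged imputed; imputed
points are treated as ordinary data downstream. Specimens missing more
than `max_missing` landmarks (default 3 — imputation only where fewer
than four are missing) are passed through untouched and flagged
excluded. Missing midline landmarks and pairs missing on both sides are
never imputed; they simply leave the specimen incomplete for any
landmark set that needs them.

The least-squares plane is a documented choice: symmetry-plane fitting
conventions differ between packages, and this one is deterministic,
exact on symmetric inputs, and equivariant under rigid motion and
scaling (verified by test).

## Superimposition and tangent space

Generalized Procrustes analysis: centre each configuration, scale to
unit centroid size, rotate to the running consensus with the proper
(det +1) Kabsch rotation, re-average, and iterate until the consensus
changes by less than 1e-10 (Frobenius norm; cap 200 iterations —
convergence is linear and dispersed samples need over 100). Reflection
to one anatomical side is preprocessing; GPA itself never reflects.
After convergence the consensus is rotated to its principal axes with a
frame-independent sign convention (an index-weighted first moment of
the canonical coordinates orients the first two axes; properness fixes
the third), so the output does not depend on input ordering.

Tangent coordinates are the orthogonal projection of the aligned unit
pre-shapes onto the plane tangent at the consensus; the consensus maps
to zero and tangent vectors sum to zero. Procrustes distance is the
full Procrustes distance (optimal rotation *and* scaling between unit
pre-shapes), computed as an explicit residual rather than via
√(1 − s²), which loses half the significant digits near zero. Pairwise
tables are labelled full-Procrustes accordingly.

## Permutation shape statistics

With tens of specimens and ~3k shape variables, classical MANOVA
statistics are singular, so group and regression tests are Goodall-type
ratios of summed squared tangent deviations:

* **shape ~ ln CS**: r² = SS_model/SS_total pooled over all shape
  variables; F = SS_model/(SS_res/(n−2)); p by permuting the predictor.
* **group tests**: F = (SSB/(g−1))/(SSW/(n−g)); p by permuting labels.
  Groups need ≥ 2 members; offenders are named in the error.
* **pairwise group distances**: full Procrustes distance between group
  mean shapes (means taken in tangent coordinates and mapped back
  through the consensus), per-pair label permutation with the
  (b+1)/(m+1) p-estimator; single-member groups get a distance and a
  flagged (NaN) p.
* **CVA**: tangent data are first reduced to the smallest PCA subspace
  reaching 95% of variance, capped at n − g axes (the within-group
  covariance must be invertible); canonical axes solve the generalized
  symmetric eigenproblem B v = λ W v, and the eigenvalues give each
  axis's percentage of among-group differentiation. Axis orientation is
  sign-fixed deterministically.

Defaults: 10,000 permutations for library calls (the pipeline default
is 999 to keep full runs fast), α = 0.05, one seeded generator per
call. Statistics are invariant under global rotation of the tangent
coordinates and under consistent relabelling of specimens (tested).

## Bite force

`BF = (TCS·t + MCS·m)/Mo`, all quantities in raw millimetres: muscle
centroid sizes must keep size information for BF to be meaningful. All
lever and moment arms are landmark-to-landmark (or centroid-to-
landmark) 3D Euclidean distances; no surface meshes are used, but the
endpoints are the same anatomical points. BF is a relative score (mm²
scale), degree-1 homogeneous in specimen scale and invariant to rigid
motion; no conversion to Newtons is attempted. Group comparison: drop
groups with < 2 members (recorded), Shapiro–Wilk per group (n ≥ 3),
Brown–Forsythe Levene, then Welch's ANOVA if Levene p < 0.05 else the
classical one-way F, and Tukey HSD post-hoc. The report is
deterministic; `posthoc=False` skips the Tukey table, whose
studentized-range quadrature dominates runtime in simulation loops.

## Spatial correlograms

Great-circle distances use the haversine formula on a sphere of radius
6371.0088 km; at site-to-site scales the ellipsoidal correction
(< 0.3%) is irrelevant. The published 16×16 between-site distance
matrix ships as a fixture (site coordinates are not published);
100-km binning of it yields seventeen half-open classes [0, 100),
[100, 200), …, matching the published class count, with ten class-1
pairs averaging 24.52 km. The published table reports a class-1 mean of
22.49 km — not reproducible from the rounded printed matrix, implying
the original tool binned unrounded coordinate-derived distances; the
fixture-based value is reported as-is.

Moran's I uses binary class-membership weights (not row-standardised)
and the maximum-likelihood variance (division by n) with plain-mean
deviations. Two-site systems give I = −1 identically; the permutation
null mean is −1/(n−1), and p-values are two-sided around that
expectation, with one set of value permutations shared across all
classes of a correlogram. Sites without data are excluded pairwise;
classes whose pairs all involve excluded sites (or with no pairs at
all) are flagged undefined (NaN I and p), mirroring the dash cells of
published correlogram tables. The exact conditions under which the
original R tooling declined to print p-values are unpublished and are
not imitated beyond this rule.

## Synthetic data

The generator emulates the study conditions: 16 sites along a ~1700-km
arc with the published per-site sample sizes (85 crania) and five diet
groups; fragmentary preservation as MCAR landmark deletion; allometry;
per-group shape offsets; an optional geographic shape cline; and
isotropic Gaussian landmark noise. Per specimen, in a fixed draw order
(size, noise, rotation, translation, missing mask) from one seeded
generator: ln CS ~ Normal(ln CS₀, 0.05), shape = template ⊕ group
vector ⊕ allometry·(ln CS − ln CS₀) ⊕ cline·(site arc position) ⊕
noise (default 1 mm — digitising error plus individual variation,
giving within-group Procrustes spreads of a few hundredths, the order
seen in human cranial samples), then a uniform random rotation,
translation in ±100 mm, and the drawn scale. Effect vectors are drawn
orthogonal to the similarity directions (translations, scaling,
rotations) at the template, so their stated norms are tangent-space
norms. Defaults: group-effect norm 0.03 (the order of the published
between-group Procrustes distances), allometry off unless set;
`allometry_norm_for_r2` solves |a| from the designed variance share via
r² = |a|²·Var(lnCS) / (|a|²·Var(lnCS) + (3k−7)·(σ/CS₀)²), which
recovery tests confirm is accurate to ~1 point at the 20% design point.

What the generator does **not** emulate: non-random preservation
(missingness in real crania correlates with fragile regions),
measurement error that varies by landmark type, asymmetry, and
non-linear allometry. Passing recovery tests therefore demonstrate the
statistical machinery, not the biology of any real sample.

## Problem sizes in the test and acceptance suites

Recovery experiments use the 9-landmark neurocranial analogue (GPA on
9 × 3 coordinates is fast and the statistics are dimension-generic):
allometry recovery with n = 60 over 200 seeds; group-distance recovery
with 15 + 15 specimens over 100 seeds (99 permutations per test);
cline detection on an 8-site, 665-km transect over 100 seeds; null
calibration with 200 replicates × 999 permutations on the published
16-site distance matrix. The imputation noise study runs 500
replicates against a true-plane oracle on the 37-landmark set.

## Known limitations

* TPS support covers the LM/LM3, ID, SCALE, IMAGE line types; exotic
  dialect extensions are out of scope, as are mesh/CT formats.
* The midline objective is a documented convention, not a reconstruction
  of any specific legacy tool's algorithm.
* CVA percentages depend on the PCA retention rule when group structure
  is weak; the 95% default and the n − g cap are deterministic but not
  canonical across packages.
* Mahalanobis-based CVA significance, allometry-corrected CVA, sliding
  semilandmarks, Mantel tests, and sea-route/least-cost distances are
  deliberately not implemented.
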