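# craniomorph

Landmark-based geometric morphometrics for cranial samples: generalized
Procrustes superimposition, permutation shape statistics, mirror
imputation of missing bilateral landmarks, lever-model bite-force
estimation, and Moran's *I* spatial correlograms — with a synthetic-data
generator that reproduces the statistical structure of a fragmentary,
multi-site archaeological skeletal sample.

## Who this is for

Biological anthropologists and morphometricians analysing 3D cranial
landmark data from fragmentary samples organised into sites and a priori
groups (e.g. dietary or regional categories), who want a scripted,
reproducible version of the classic workflow: impute → superimpose →
test allometry and dimorphism → ordinate and test group differences →
estimate bite force → test isolation by distance.

## The methods

**Superimposition.** Configurations are centred, scaled to unit
centroid size CS = √Σᵢ‖xᵢ − x̄‖², and iteratively rotated (proper
rotations only) onto a consensus, then projected orthogonally into the
tangent space at the consensus, where Euclidean multivariate statistics
apply.

**Missing landmarks.** A landmark whose bilateral partner is present is
estimated by reflecting the partner through the specimen's own
least-squares midline plane; specimens are imputed only when fewer than
four landmarks are missing.

**Shape statistics.** Because specimens are far fewer than shape
variables, all tests are Goodall-type variance ratios with permutation
nulls: shape-on-ln(CS) regression, group "permutation MANOVA", per-pair
Procrustes distances between group mean shapes, plus PCA and canonical
variates analysis (CVA, PCA-regularised) for ordination.

**Bite force.** A relative lever score
`BF = (TCS·t + MCS·m) / Mo`, with TCS/MCS the centroid sizes of the
landmarks delimiting the temporalis and masseter, *t*/*m* their lever
arms to the temporomandibular joint, and *Mo* the moment arm from the
TMJ to the M2 bite point. Group comparison uses Shapiro–Wilk, Levene,
Welch/classical ANOVA, and Tukey HSD.

**Spatial autocorrelation.** Between-site great-circle distances are
binned into 100-km classes; per class, Moran's
*I* = (n/W)·Σᵢⱼ wᵢⱼ(xᵢ−x̄)(xⱼ−x̄) / Σᵢ(xᵢ−x̄)² (maximum-likelihood
variance, binary weights) with a two-sided permutation test around the
null expectation −1/(n−1).

## Worked example

```python
import numpy as np
import craniomorph as cm
from craniomorph.synthetic import (paper_like_simulation, generate_dataset,
                                   allometry_norm_for_r2)

# a study-condition synthetic sample: 16 sites, 5 diet groups, 85 crania
sim = paper_like_simulation("neurocranial", seed=1, missing_rate=0.05)
sim.allometry_norm = allometry_norm_for_r2(sim.template, sim.noise_sd,
                                           sim.ln_size_sd, 0.05)
dataset, truth = generate_dataset(sim)

imputed, report = cm.impute_dataset(dataset)          # mirror imputation
complete = cm.subset_complete(imputed, dataset.spec)  # complete cases only
result = cm.gpa(complete.coords_array())              # superimposition

reg = cm.shape_on_size_regression(result.tangent, np.log(result.csize),
                                  n_perm=9999, seed=1)
test = cm.procrustes_group_anova(result.tangent, complete.diet_groups(),
                                 n_perm=9999, seed=2)
cv = cm.cva(result.tangent, complete.diet_groups())
```

Output:

```
specimens: 85, complete after imputation: 66
shape ~ ln(CS): F(1, 64) = 1.88, r2 = 0.028 (2.85%), p = 0.0573
diet permutation MANOVA: F(4, 61) = 19.05, p = 0.0001
CVA % differentiation: [42.7  29.78 22.14  5.37]
```

Reading it: of the 85 simulated crania, 66 are complete for the
9-landmark neurocranial set once mirror imputation has filled what it
can. Size explains 2.85% of tangent shape variance (the generator was
asked for ~5%; with n = 66 the estimate is noisy and here misses the
0.05 permutation threshold). The diet effect built into the generator is
detected decisively (p = 0.0001, the smallest value 9999 permutations
can produce), and CV1 carries 42.7% of the among-group differentiation.

The same sequence runs from the shell:

```sh
craniomorph run --seed 1 --n-perm 999 --out results/
craniomorph simulate --seed 1 --set-id craniofacial --out data/
```

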