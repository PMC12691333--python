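# habikit

Habitat radiomics on 3D tumor volumes: partition a segmented tumor into
imaging *habitats* — subregions with distinct imaging phenotypes — extract
radiomics feature panels from the whole tumor and each habitat, build sparse
logistic *radscore* models, and compare them with paired ROC statistics.

The motivating use case is predicting brain metastasis (BM) in non-small
cell lung cancer from arterial-phase chest CT: heterogeneous primary tumors
harbor subregions (hypoxic cores, enhancing rims) whose composition carries
prognostic signal that whole-tumor averages dilute. `habikit` implements the
full analysis as a tested, reusable library, and ships a seeded 3D phantom
generator so every stage can be validated against planted ground truth
without patient data.

## The method

1. **Isotropic grid.** Volumes and masks are resampled to 1 mm isotropic
   spacing (image trilinear, mask nearest-neighbour).
2. **Habitat partition.** For every tumor voxel two features are computed:
   its HU intensity and the local Shannon entropy
   `H = -Σᵢ pᵢ log₂(pᵢ + ε)` of the gray-level histogram over its
   mask-restricted neighbourhood. Voxels from all training patients are
   pooled, z-standardized, and clustered with Euclidean k-means at the
   population level; the habitat count k is chosen by the Calinski–Harabasz
   index `CH = [B/(k−1)] / [W/(n−k)]`, and habitat ids are canonicalized by
   ascending centroid intensity (Sub1 = lowest HU). Held-out patients are
   assigned to frozen training centroids.
3. **Features.** Per region (whole tumor and each habitat) the default
   manifest extracts exactly **1218** features: 14 shape features plus
   14 filter images — `original`, Laplacian-of-Gaussian at σ = 1…5 mm,
   and 8 stationary-wavelet subbands (`LLL`…`HHH`, coif1) — × 86
   first-order/GLCM/GLRLM/GLSZM/GLDM/NGTDM features, all implemented here
   and tested against brute-force oracles. Names follow the
   `{filter}_{family}_{feature}` convention (`Sub{j}_` prefix for habitats)
   so published radscore formulas evaluate verbatim.
4. **Selection + radscore.** Optional ICC ≥ 0.70 stability filtering across
   repeated segmentations, greedy elimination of pairwise |r| > 0.75, mRMR
   ranking (MID scheme), then an L1-penalized logistic path with
   cross-validated λ. The surviving coefficients define
   `radscore(x) = β₀ + Σ β_f x_f` on the raw feature scale.
5. **Evaluation.** Logistic models (clinical covariates, whole-tumor
   radscore, habitat radscore) are compared by AUC with DeLong variance,
   Youden operating points, paired DeLong tests, calibration and decision
   curves.

Two published radscore models ship as fixtures (`paper_voi`, `paper_sub`)
loadable by name.

## Worked example

`examples/` holds one short script per capability. Running
`python examples/02_habitat_clustering.py` prints:

```
CH index by candidate k (higher = better separated):
  k=2: CH =       106387
  k=3: CH =       133790  <-- selected
  k=4: CH =       119265
  k=5: CH =       116025
  k=6: CH =       109268

planted habitat count: 3; recovered k* = 3
per-voxel habitat recovery accuracy: 0.945
```

The CH index peaks at the planted habitat count and the recovered habitat
maps agree with the planted labels for 94.5% of voxels. The end-to-end
contrast (`examples/05_model_comparison.py`, an 80-patient phantom cohort)
prints the Table-style evaluation grid:

```
model    cohort         AUC          95% CI  sens  spec
clin     training     0.575     (0.41-0.74)  0.47  0.73
clin     validation   0.461     (0.20-0.72)  1.00  0.12
voi      training     0.858     (0.76-0.95)  0.74  0.86
voi      validation   0.805     (0.60-1.00)  0.75  0.88
sub      training     0.926     (0.86-1.00)  0.89  0.86
sub      validation   0.820     (0.61-1.00)  0.88  0.81
```

The habitat (sub) model dominates the whole-tumor (voi) model, which
dominates the clinical baseline — the expected ordering, since the synthetic
outcome depends on habitat composition.

A thin CLI mirrors the library:
`habikit simulate | resample | habitats | extract | select | radscore | run | ingest`.

## Layout

```
src/habikit/        io, synthetic, habitats, texture/, selection, stats,
                    pipeline, experiments, cli
examples/           one narrative script per capability
docs/methods.md     modeling and numerical choices, in detail
tests/              unit, property and acceptance suites
```
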