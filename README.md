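# musclemorph

Bilateral 3D muscle shape similarity and regional morphometry from
segmented MRI.

After hamstring-tendon harvest for ACL reconstruction, the semitendinosus
shortens, atrophies and changes shape — but discrete measures (length,
cross-sectional area, volume) miss where on the muscle the shape changes
happen. This package quantifies *between-limb* shape difference directly:
one limb's segmented surface is mirrored, scaled to the contralateral
muscle length, rigidly aligned on six musculotendinous-junction (MTJ)
landmarks, and compared with three metrics plus a spatial localization of
the worst deviation. It is aimed at musculoskeletal imaging researchers
with per-muscle label volumes (NIfTI) or surface meshes (STL/PLY).

## What it computes

**Shape similarity** on the aligned pair (A = mirrored/scaled limb, B =
reference limb):

- Jaccard index `J = |A ∩ B| / |A ∪ B|` on voxelized interiors (1 =
  perfect overlap);
- surface RMSE `sqrt(mean d²)` over unsigned point-to-surface distances,
  pooled symmetrically over uniform-area samples of both surfaces (mm);
- symmetric Hausdorff distance `H = max(sup_a inf_b d, sup_b inf_a d)`
  (mm) with the coordinates of the attaining point, assigned to the
  proximal/middle/distal third of the muscle;
- a per-vertex signed-distance heatmap (PLY export) in the usual
  −10 mm (inside) to +25 mm (outside) rendering convention.

**Discrete regional morphometry** on the *unscaled* limbs: the
intercentroid pathway (per-slice cross-section centroids, re-sliced
orthogonal to the local tangent) gives muscle length; cross-sectional
areas on planes orthogonal to the pathway give peak CSA; volume comes from
the closed mesh. Regions split the pathway at 33% and 66% of arc length
(distal = 0). Length is normalized by limb length (cm·m⁻¹), peak CSA and
volume by body mass × limb length (cm²·kg⁻¹·m⁻¹, cm³·kg⁻¹·m⁻¹).

**Group statistics**: Student pooled-variance t-tests (summaries or raw
samples), 95% CIs, Cohen's *d* (pooled SD for independent groups, SD of
paired differences within subjects), a group-by-limb mixed-design ANOVA
interaction per outcome with the post-hoc contrast set, and
tendon-regeneration subgroup comparisons.

**Synthetic phantoms**: bilateral fusiform muscles
`r(z) = r_max · sin(π z / L)^q` with controllable retraction, regional
atrophy and distal tip deviation — every downstream stage is testable
against closed forms and generator ground truth without imaging data.

## Worked example

Group tables of a bilateral study report mean ± SD with n = 18 per group;
those summaries fully determine the effect sizes:

```python
from musclemorph.stats import GroupSummary, cohens_d, ttest_independent

healthy = GroupSummary(mean=9.60, sd=2.47, n=18)   # Hausdorff, mm
aclr    = GroupSummary(mean=23.1, sd=8.68, n=18)

print(round(cohens_d(healthy, aclr), 2))
res = ttest_independent(healthy, aclr)
print(round(res.mean_difference, 1), (round(res.ci95_low, 2), round(res.ci95_high, 2)))
```

prints

```
-2.12
-13.5 (-17.82, -9.18)
```

a large effect: the reconstructed group's bilateral shape deviation is
about 2.1 pooled SDs above the healthy controls', with the mean
between-group difference of −13.5 mm Hausdorff distance bounded away from
zero. The same path on a simulated phantom cohort
(`analysis/01…03`, seed 20260, 6 per group) prints

```
aclr     jaccard 0.65 ± 0.12  hausdorff 12.8 ± 4.4 mm
control  jaccard 0.97 ± 0.00  hausdorff 1.4 ± 0.1 mm
max-deviation region (reconstructed): {'distal': 6}
```

— every simulated post-surgical muscle localizes its maximal deviation to
the distal third, where the generator put it.

## Command line

```bash
musclemorph simulate --n-per-group 6 --seed 1 --out data/      # phantom cohort
musclemorph extract muscle.nii.gz muscle.stl --label-id 2      # label -> surface
musclemorph run-cohort data/manifest.csv --out results/ --heatmaps
musclemorph report results/
```

## Repository layout

- `src/musclemorph/` — the library: `synthgen` (phantoms), `meshio`
  (formats + wrap/smooth surface extraction), `register` (mirror, scale,
  landmark rigid fit), `similarity`, `morphometry`, `stats`, `pipeline`.
- `analysis/01…04_*.py` — numbered drivers: simulate the cohort, run the
  pipeline, compute the group statistics, and recompute the published
  worked-example statistics; tables land in `results/`.
- `tests/` — analytic-geometry oracles, brute-force cross-checks,
  property and calibration tests.

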