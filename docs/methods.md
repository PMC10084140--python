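# Methods

## The measurement problem

The pipeline quantifies how different the two sides of a bilateral muscle
pair are in shape, and where. The two limbs of one subject are segmented
independently (label volumes or surfaces); one limb is mirrored across a
sagittal-proxy plane, uniformly scaled so its centerline length matches the
contralateral side — removing gross size so that the similarity metrics
respond to *shape* — and rigidly aligned by least squares on six labelled
musculotendinous-junction (MTJ) landmarks, three proximal and three distal.
Discrete morphometry (length, peak CSA, volume; totals and thirds) is
always computed on the original unmirrored, unscaled geometry, so reported
sizes are physical.

## Surface extraction from label volumes

Labels are binarized and closed morphologically with a ball of radius
`gap_closing_mm` (default 1.3 mm), connected components smaller than a
sphere of diameter `smallest_detail_mm` (default 0.82 mm) are dropped, the
isosurface is extracted by marching cubes at level 0.5 (half-voxel surface
placement) in voxel coordinates and mapped to world millimetres through
the NIfTI affine, and the mesh is smoothed with Taubin's non-shrinking
filter, `smoothing_factor × 50` iterations at λ/ν = 0.5/0.53. The factor
maps linearly to iterations so smoothing is bounded and monotone; the
filter is volume-stable (<1% change on convex shapes, tested). The affine
is taken as authoritative — no interslice interpolation is added. All
outputs are watertight and outward-oriented (enclosed volume > 0), which
the inside/outside and volume computations require.

## Similarity metrics

*Jaccard* is computed on voxelized interiors: both meshes are rasterized
on one shared isotropic lattice (default 1 mm, the in-plane scale of the
source MRI; the grid covers the joint bounding box with a ≥2-voxel pad).
A voxel is occupied iff its centre is inside the closed surface, decided
per z-slice by point-in-polygon tests against the surface cross-section
(holes respected). Convergence in the voxel size is part of the test
suite; at 1 mm vs 0.5 mm the index moves by <0.01 on smooth phantom pairs.

*Surface RMSE* and *Hausdorff distance* are computed on surface geometry,
not on the grid, so sub-voxel values are meaningful. Distances are exact
point-to-triangle queries: candidate triangles come from a k-d tree over
triangle centroids (k = 32), and the candidate set is widened by a ball
query whenever the best distance found does not provably dominate the
excluded triangles (best > k-th centroid distance − max centroid-vertex
radius). The implementation is validated against an all-pairs brute-force
oracle. RMSE pools unsigned distances from uniform-area samples of both
surfaces (default 50 000 per surface, seeded), making it symmetric by
construction; the Hausdorff scan additionally includes every mesh vertex,
because extremes live at vertices. The argmax sample, its direction, and
its region label (by projection onto the reference centerline) are
reported. Signed heatmap distances take their sign from the face normal at
the closest point — adequate away from sharp creases, which closed muscle
surfaces do not have.

## Morphometry

The intercentroid pathway is fit in two passes: parallel slices along the
principal axis give per-slice area-weighted cross-section centroids
(largest loop on disconnected sections, with a warning); a second pass
re-slices once orthogonal to the local pass-1 tangent, which removes the
obliquity bias (a cylinder tilted 45° still measures its axis length, not
length/cos 45°). Both ends are extended along the end tangents to the
furthest surface point so tapered tips contribute their full length.
Default slice and CSA-station spacing is 1 mm — finer than the source
slice pitch, with convergence headroom (halving changes peak CSA <0.5% on
phantoms).

Peak CSA scans planes orthogonal to the pathway at every station; ties
within 1e-9 relative resolve to the proximal-most station so uniform
shapes report deterministically. Regions split arc length at exactly 33%
and 66% (distal anchored at arc length 0); stations on a boundary belong
to the more proximal region. Regional volumes cut the mesh with the two
boundary planes: triangles are clipped analytically against each
half-space and the planar cuts are closed by their cap flux
(−(origin·n̂)·A/3 per cap, divergence theorem), exact as long as the two
planes do not intersect inside the muscle — true for muscle-like aspect
ratios; a conservation check (regions sum to total within 1%) warns
otherwise. Regional peak CSA restricts the station scan rather than
re-meshing, which is equivalent on the pathway. Normalization divides
length by limb length (m) and peak CSA/volume by mass × limb length
(kg·m).

## Registration

The landmark fit is the SVD (Kabsch) solution with determinant correction:
rotation plus translation only, no scaling, no reflection; correspondence
is by label. Mirroring reflects across the plane through the mesh centroid
perpendicular to a named axis and restores outward face winding; scaling
is uniform isotropic about the centroid by the centerline-length ratio (an
axis-only mode exists for sensitivity checks), applied before the rigid
fit, i.e. mirror → scale → align.

One behaviour worth knowing: when a deformation displaces the distal MTJ
itself (as a deviated tip does), the landmarks move with the tissue and
the least-squares fit partially *reabsorbs* the deviation — a 20 mm tip
offset survives the full pipeline as ~14 mm of residual deviation near the
33% boundary rather than 20 mm at the tip (the fit tilts the muscle to
split the landmark misfit along its length). This is a property of
N-point landmark registration itself, not an implementation artifact; the
package's parameter-recovery checks therefore measure deformations by
comparing deformed and intact shapes in their shared frame, where the
geometric magnitudes are recovered exactly.

## Statistics

Between-group comparisons use the Student pooled-variance t-test
(df = n₁+n₂−2) with the 95% CI on the mean difference from the pooled
standard error; the summary-statistic path is primary (published tables
are mean ± SD), and the raw-sample path reduces to it exactly. Cohen's d
is pooled-SD for independent contrasts and mean difference over the SD of
paired differences for within-subject contrasts, labelled negligible
(<0.20), small (0.20–0.49), medium (0.50–0.79), large (≥0.80). The
group-by-limb interaction of each morphology outcome uses the exact
split-plot identity F = t², with t the pooled t-test on per-subject limb
differences between groups — equal to the classical sum-of-squares
decomposition when balanced (tested against a brute-force SS oracle and
pingouin) and still well-defined with (1, N−2) df after failed cases are
quarantined. A significant interaction (α = 0.05) triggers the post-hoc
set: paired injured-vs-uninjured within the surgical arm, and each
surgical limb against the healthy bilateral average; the average is used
only when the healthy limbs do not differ in a paired test. No
multiple-testing correction is applied by default (a Holm option exists
behind a flag). Degenerate inputs are defined, not NaN: zero pooled
variance with equal means gives t = 0, p = 1; with unequal means t = ±∞,
p = 0; a noise-free additive design gives interaction F = 0.

Calibration is part of the suite: the t-test's type-I error over 10⁴ null
replicates at the study's group size stays within [0.03, 0.07] at
α = 0.05, its p-values agree with a 10⁵-resample permutation oracle within
0.01, and the interaction p-value is uniform under the null (KS test).

## Synthetic cohort: what it emulates and what it does not

Phantoms are surfaces of revolution `r(z) = r_max sin(π z/L)^q` with
elliptical cross-sections — fusiform, MTJ-like tapering tips, and a
closed-form volume at q = 1 (π r² L/2) used as an oracle. Cohort defaults:
length 300 ± 25 mm, peak radius 20 ± 1.5 mm, ellipse ratio 0.8, taper
exponent 0.6 (so volume/(peak CSA × length) ≈ 0.61, matching muscle-like
shape factors); subject mass 69 ± 15.4 / 82 ± 15.6 kg and limb length
0.81 ± 0.05 / 0.83 ± 0.07 m for the control and surgical arms; tendon
regeneration is Bernoulli(0.39). The surgical limb draws retraction
0.32 ± 0.04, regional radial scales (0.78, 0.72, 0.88) ± 0.05
(proximal, middle, distal), and a 14 ± 4 mm distal tip deviation; when the
tendon regenerated, severities are multiplied by 0.45. These defaults make
the simulated injured limb lose roughly half its volume and a third of its
length relative to the contralateral side — the magnitude regime of the
motivating clinical cohort — and they are configuration, not claims about
any particular patient population.

Deformations are C¹: radial scales blend across the 33%/66% boundaries
with smoothstep windows, the tip deviation decays smoothly to zero at 33%
arc length (so its magnitude is a known Hausdorff target), retraction
collapses everything distal to the cut station onto a rebuilt tip (length
scales by exactly 1 − f up to station spacing), and surface noise is
Gaussian along vertex normals, seeded. Landmarks ride the same coordinate
map; noise is not applied to them (MTJ picks are user selections, not
surface jitter), and under retraction, landmarks distal to the cut
coincide at the rebuilt tip — the least-squares fit remains well-posed.
The deformation map assumes the phantom convention (straight axis along z,
distal end at minimal z).

What the generator does **not** emulate: real anatomical bilateral
asymmetry and limb-positioning differences (simulated controls reach
Jaccard ≈ 0.97 where real healthy controls sit near 0.70), segmentation
and rater variability, fatty infiltration, digastric internal structure,
and MRI intensities (label geometry only). Passing tests therefore
demonstrate correctness of the measurement chain and recovery of known
geometric effects, not field accuracy on clinical images.

## Problem sizes

Tests and the acceptance script run phantoms at reduced resolution
(typically 60–120 axial stations × 20–48 circumferential vertices, 2–4 mm
slice/station spacing, 1.5–2 mm voxels, 4 000–20 000 surface samples) and
a 6 + 6 simulated cohort — sizes at which every analytic check holds at
its stated tolerance while a full run stays in the minutes range on one
CPU. All spacings, sample counts and resolutions are configuration;
convergence in each of them is itself under test.

## Known limitations

- Signed heatmap distances use face pseudo-normals; on meshes with sharp
  creases the sign can flip locally near edges.
- Regional volumes assume the 33%/66% cutting planes do not intersect
  inside the muscle; strongly curved centerlines violate this and trip the
  conservation warning.
- The radial-scaling and tip-deviation deformations are defined about a
  straight axis; applying them to strongly bowed inputs distorts their
  nominal magnitudes.
- `mirror_and_scale` estimates length via the centerline unless a length
  is supplied; on pathological shapes where the centerline fit warns, pass
  the length explicitly.
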