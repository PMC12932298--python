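# Methods

This note documents the models, conventions and numerical choices behind
the package, and what the synthetic validation does and does not show.

## Contact-area definition

The contact area between two structures is the region of one surface lying
strictly within a Euclidean distance threshold (default 1.0 mm) of the
other.  Discretely: a triangle belongs to the patch when its centroid's
exact point-to-triangle distance to the partner surface is `< threshold`;
the patch area is the sum of its face areas.  Strict inequality is a fixed
deterministic convention — the boundary set has measure zero, so the choice
does not affect converged areas.  Each interface is measured in both
directions and the arithmetic mean reported; the two directional areas are
expected to agree, and a relative mismatch beyond 20% raises a logged QC
flag (never an error).  Face-centroid evaluation with face-area weighting
makes the discrete patch an unbiased estimator of the continuous area under
mesh refinement; halving the mean edge length changes phantom areas by
well under 2%.

Distance queries are exact: a KD-tree over target-triangle centroids gives
candidate sets with a provable bound (a triangle can only beat the current
best if its centroid lies within best + circumradius), oversized triangles
are bisected until their circumradius is near the median so the bound is
tight, and a brute-force all-pairs scan is kept as an in-package reference
(`nearest_distance_exhaustive`); the accelerated result matches it to
1e-9 mm on random meshes.

## Joint frame and compartments

The tibia is the common reference of all three interfaces, so the
coordinate system derives from the tibial bone surface: area-weighted PCA
gives medial-lateral (largest extent), anterior-posterior and
proximal-distal axes; the proximal-distal axis is oriented toward the
tibial cartilage; the medial direction is the side of the larger cartilage
facet (the medial tibial plateau is the larger one).  The medial/lateral
split plane passes through the midpoint of the two largest cartilage-facet
centroids, normal along the medial-lateral axis.  Faces are assigned to a
compartment by centroid side (points exactly on the plane count as
lateral), which keeps the partition face-exclusive and the total the exact
float sum of the two parts.  Each meniscus is wholly assigned to its
anatomical compartment rather than split by the plane.

Registration removes acquisition-frame subject motion only: the loaded
tibia is ICP-registered (exact closest-point queries, Kabsch updates,
strided deterministic sampling, convergence on relative RMS change 1e-5)
onto the unloaded tibia, and the recovered transform is applied to every
loaded surface.  Femoral motion relative to the tibia — the physiology of
interest — is untouched.  An identity transform is permitted for data that
are already position-locked.

## Segmentation

Bones: marker-based watershed floods the gradient magnitude (spacing-aware
central differences).  Exterior seeds must include the tissues immediately
outside the bone (cartilage, menisci), not just far background — otherwise
the flood crosses the weaker bone-cartilage ridge before background water
arrives and the bone region swallows the cartilage.  `markers_from_labels`
therefore seeds every non-target structure as exterior.

Sub-voxel refinement: marching cubes on the label mask gives the
voxel-boundary surface; each vertex then moves along its normal to the
half-intensity crossing — the point where the cubically interpolated image
passes midway between the interior and surrounding plateau levels.  The
profile is sampled at 0.05 mm steps over ±2 voxel diagonals: a cubic
interpolant of an edge settles onto its plateaus only ~2 samples past the
edge, so plateau levels estimated inside a ±1-diagonal window are biased
when the vertex starts off-centre.  Levels are estimated in two passes
(coarse min/max mid-level to locate the edge, then plateau means from
samples ≥ 2 voxels away from it), the admissible crossing and the vertex
move stay within ±1 diagonal, and vertices without a crossing (contrast
below 0.1) remain on the voxel boundary and are counted.  On a rasterized
ball (R = 10 mm, 0.4 mm voxels, 1% noise) the mean radial error is
~0.006 mm; a plane offset half a voxel is recovered to ~2 µm, limited by
the interpolant's plateau estimate.

Cartilage and menisci come from slice-wise closed contours (sagittal and
coronal respectively).  Corresponding contours on adjacent slices are
paired by nearest centroid (larger-area-first on ties, pairing suppressed
across gaps in the slice sequence), resampled to a common arc-length
density, phase-aligned, and joined by triangle strips; chain ends are
capped by ear clipping.  Cylinder and frustum stacks reconstruct their
lateral areas to ~0.02%.  The Gaussian inter-slice smoother (σ = 1.25 mm,
linear-extrapolation boundaries so affine surfaces are preserved) is for
display only; its output carries `visualization_only = True` and every
quantitative routine rejects it.

## The phantom and its ground truth

Geometry (defaults in mm): spherical condyles (bone radii 18.0 medial /
16.5 lateral + 2.2 cartilage shell to 100° polar extent), centred ±22
from the midline above two circular tibial cartilage facets (radii 20.2 /
19.8, thickness 2.0) on a box tibia; cartilage gaps 0.4 medial / 0.6
lateral; C-shaped menisci (annular sectors r = 11–16, arc 200° opening
toward the notch, outer height 7) whose superior dish is concentric with
the condyle at a uniform 0.5 mm gap — giving the anatomical wedge profile
(thin inner rim, tall outer rim) with tractable truth.  The femur leaves
the imaging volume proximally, as in a knee-protocol field of view, so
bone-volume checks apply to the fully contained structures.

Load response: femoral approach 0.06 plus 0.08° adduction (a rigid femur
cannot reproduce a medially dominant *percentage* increase by translation
alone — with one approach distance, ΔA/A ≈ Δg/(t−g) is larger where the
baseline contact is smaller, i.e. laterally; the tilt is what loads the
medial compartment preferentially, mirroring the physiological adduction
moment) and a 1.8 mm outward radial meniscal shift; the loaded acquisition
is additionally perturbed by a rigid motion (defaults 2°, ~1.6 mm) to
emulate inter-scan subject movement.

Images: each structure has a nominal intensity level (bone 1.0, menisci
0.75, cartilage 0.55 on background 0) with a linear partial-volume ramp of
0.5 mm (≈ one voxel) around every face, so the half-intensity isosurface
*is* the true boundary; Gaussian noise (SD 0.02) is added with a
subject-seeded generator (identical across conditions, so an identity load
response reproduces the unloaded acquisition bit for bit).  Contour stacks
are cut from fine analytic meshes at the voxel slice positions.

Ground truth: cartilage-cartilage areas use the exact sphere-on-plane
closed forms under the Euclidean criterion — plane-side disc
π((R+t)² − (R+g)²) and sphere-side cap 2πR(t−g).  (The widely used
projected-cap formula π(2R(t−g) − (t−g)²) is their small-(t−g)/R limit and
underestimates the exact bidirectional mean by 2.5–5% at knee-scale radii;
it is provided as `sphere_plane_area_small_gap` with a convergence test.)
Meniscotibial truth is the offset-footprint closed form (tibial side
A + P·t + πt², meniscal side A + P·t for footprint area A and perimeter
P, valid for t below the inner rim height).  Meniscofemoral truth has no
simple closed form once the meniscus shifts; it is computed by dense
quadrature: exact point-to-sphere distances over a fine (0.2 mm) analytic
meniscus mesh, and fine-mesh distance queries for the femoral side.

What the phantom does not emulate: realistic bone/cartilage shape
(condyles are spheres, the plateau is flat), tissue deformation under load
(the load response is rigid; no cartilage compression field), intensity
inhomogeneity or motion artifacts, and partial-volume behaviour beyond a
linear ramp.  Passing tests therefore validate the *measurement chain* —
segmentation accuracy, registration, distance computation, partitioning
and statistics — not anatomical realism of any particular knee.

## Cohorts and statistics

Synthetic cohorts jitter the geometry per subject (radii ±6%, gaps ±15%,
load response ±20%, random rigid perturbations ≤3°/≤1.5 mm, per-subject
seeds).  Cohort defaults were chosen once to produce a medial-dominant
baseline and the physiological response pattern; the printed group values
(e.g. +15.3% medial vs +6.8% lateral at seed 1) are properties of those
choices.

Statistics follow the paired-design conventions: per-subject change and
percentage change (group value = mean of per-subject percentages — the
only convention consistent with reporting a +64 mm² change on a 615 mm²
baseline as +11.6%), medial/lateral ratios formed per subject then
averaged, SDs with n−1, Shapiro-Wilk on the paired differences, two-sided
paired t-tests at α = 0.05 with no multiple-testing correction (both
overridable in `StatsConfig`).  Between-compartment and
meniscofemoral-vs-meniscotibial contrasts are paired within subjects.
Zero-baseline subjects are excluded from ratio/percentage summaries and
logged, never imputed.  A lightweight simulator (analytic truth ×
independent lognormal measurement noise, CV 5%) supports calibration
studies; with no load effect the paired t-test rejects at the nominal 5%
rate (checked over 1000 replicates).

## Problem sizes and determinism

Default grids are 225 × 130 × 86 voxels at 0.4 × 0.4 × 0.5 mm; contour
meshing uses 0.35 mm arc resampling (0.45 mm in cohort runs) and truth
quadrature 0.2 mm.  The nine-subject cohort pipeline completes in roughly
eight minutes on one CPU.  All randomness flows from explicit seeds
(subject seeds derive from the cohort seed), ICP sampling is strided
rather than random, and identical configuration + seed reproduces every
output file checksum.

## Known limitations

* The watershed and sub-voxel stages assume the reference labels (or a
  human) provide interior/exterior seeds; no automatic seeding from raw
  images is attempted.
* Contour stitching assumes roughly convex, slowly varying cross-sections
  (true for knee structures); pathological branching topologies fall back
  to nearest-centroid pairing and capping, which is logged.
* The sub-voxel surface is accurate where the partial-volume model holds
  (edge ramp narrower than the structure); very thin structures (< ~2
  voxels) would need a dedicated two-sided edge model.
* Compartment naming relies on the medial plateau facet being the larger;
  for data where this fails, the joint frame can be constructed manually.
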