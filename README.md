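# tibiofem

Quantifies how the contact areas of the tibiofemoral joint change when the
knee is axially loaded, from segmented 3D knee volumes of the same subject
scanned unloaded (0 N) and under load (400 N).

In the healthy knee, load is shared between direct cartilage-to-cartilage
contact and contact mediated by the menisci, and the balance between these
pathways — in particular the differential behaviour of the meniscofemoral
(superior) and meniscotibial (inferior) meniscal interfaces — distinguishes
physiological meniscal mobility from pathological extrusion.  This package
implements the full measurement chain needed to study that balance in vivo,
plus a synthetic knee phantom with closed-form ground truth to validate
every step.

## What it computes

For each subject, per load condition:

* **Bone surfaces** by marker-based 3D watershed of the spacing-aware
  gradient magnitude, refined vertex-wise to the half-intensity crossing of
  the cubically interpolated image (sub-voxel, data driven, no mesh
  smoothing).
* **Cartilage and meniscus surfaces** by stitching slice-wise closed
  contours (sagittal for cartilage, coronal for menisci) into closed
  triangle meshes.  A Gaussian inter-slice smoother (σ = 1.25 mm) exists
  for display only; its output is flagged and *refused* by all quantitative
  operations.
* **Registration**: the loaded acquisition is mapped onto the unloaded one
  by ICP on the tibial surface, removing inter-scan subject motion while
  preserving the femur's physiological motion under load.
* **Contact areas**: a surface region counts as in contact where its faces
  lie strictly within 1 mm Euclidean distance (exact point-to-triangle) of
  the partner surface.  Both directions of each interface are measured and
  averaged; the cartilage-cartilage patch is split into medial and lateral
  compartments at the mid-plateau plane of a tibia-based coordinate system;
  each meniscus reports meniscofemoral and meniscotibial areas separately.
* **Cohort statistics**: per-subject change and percentage change under
  load (mean of per-subject percentages), medial-to-lateral ratios,
  Shapiro-Wilk normality checks and two-sided paired t-tests (α = 0.05).

The synthetic phantom models the condyles as spheres over a planar tibial
cartilage plateau (sphere-on-plane contact has an exact closed form:
plane-side patch π((R+t)² − (R+g)²), sphere-side cap 2πR(t−g), for
effective radius R, gap g, threshold t) and the menisci as C-shaped wedge
annuli whose superior dish is concentric with the condyle; the load
response is a femoral approach plus small adduction tilt and an outward
radial meniscal shift.

## Worked example

```python
from tibiofem.pipeline import PipelineConfig, run_pipeline

tables, report, manifest = run_pipeline(
    PipelineConfig(seed=1, phantom_cohort=9, out_dir="out")
)
print(report.measures[["interface", "compartment",
                       "mean_unloaded", "mean_change", "mean_pct_change"]])
```

prints (seed 1, nine synthetic subjects):

```
              interface compartment  mean_unloaded  mean_change  mean_pct_change
0   cartilage_cartilage       total         123.77        14.86            12.01
1   cartilage_cartilage      medial          76.65        11.68            15.28
2   cartilage_cartilage     lateral          47.11         3.18             6.77
3        meniscofemoral       total         665.88      -432.36           -64.84
6         meniscotibial       total         677.60         0.63             0.08
```

Reading: under load the direct cartilage contact grows (+12.0% overall),
predominantly medially (+15.3% vs +6.8%) because of the adduction tilt;
the meniscofemoral contact collapses as the menisci displace radially
while the meniscotibial contact stays put (+0.1%, not significant) — the
menisci stay anchored to the plateau and slide under the femur.  The
medial-to-lateral cartilage contact ratio rises from 1.64 to 1.77.
Absolute magnitudes are properties of the phantom geometry; the package's
claim is the validated measurement chain, not any particular knee.

A thin CLI mirrors the library: `tibiofem phantom | segment | register |
contact | report | run` (see `tibiofem --help`).

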