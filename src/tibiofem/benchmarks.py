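"""Validation benchmarks: pipeline measurements against analytic truth.

Each function runs one self-contained validation study on synthetic data
and returns plain numbers; the test suite asserts on them and the
reproduction script reports them.  Everything is seeded and generated at
run time.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from .contact import (
    ContactAreaTable,
    ContactConfig,
    contact_patch,
    interface_areas,
    mean_contact_area,
    nearest_distance,
    nearest_distance_exhaustive,
)
from .core import Surface, LABEL_OF
from .joint_geometry import build_joint_frame, rigid_register
from .load_stats import change_metrics, paired_t
from .phantom import (
    LOADED,
    UNLOADED,
    PhantomSpec,
    cohort_specs,
    cohort_truth_areas,
    make_phantom,
    simulate_cohort_tables,
    sphere_plane_contact_area,
)
from .pipeline import SOFT_STRUCTURES, PipelineConfig, run_pipeline
from .segmentation import (
    MarkerSet,
    contours_to_mesh,
    markers_from_labels,
    subvoxel_surface,
    watershed3d,
)


def sphere_plane_case(
    R_eff: float, gap: float, threshold: float = 1.0, resample_step: float = 0.45
) -> dict:
    """Measured vs exact cartilage-cartilage area for one sphere-on-plane.

    Both condyles are set to the same effective radius and gap; the summed
    bidirectional-mean patch area over the two (disjoint) contacts is
    halved to give one sphere-on-plane measurement, compared against the
    exact closed form for the Euclidean criterion.
    """
    spec = PhantomSpec(
        condyle_radius_medial=R_eff - 2.2,
        condyle_radius_lateral=R_eff - 2.2,
        cartilage_thickness_femoral=2.2,
        plateau_gap_medial=gap,
        plateau_gap_lateral=gap,
        load_approach=0.0,
        load_adduction_deg=0.0,
        meniscus_radial_shift=0.0,
    )
    _, _, stacks, _ = make_phantom(
        spec, UNLOADED, with_image=False, with_truth_areas=False
    )
    fc = contours_to_mesh(stacks["femoral_cartilage"], resample_step)
    tc = contours_to_mesh(stacks["tibial_cartilage"], resample_step)
    cfg = ContactConfig(threshold=threshold)
    res = mean_contact_area(contact_patch(fc, tc, cfg), contact_patch(tc, fc, cfg), cfg)
    measured = 0.5 * res.area  # two identical condyles
    expected = sphere_plane_contact_area(R_eff, gap, threshold)
    return {
        "R_eff": R_eff,
        "gap": gap,
        "measured_mm2": measured,
        "expected_mm2": expected,
        "rel_error": (measured - expected) / expected if expected else np.nan,
    }


SPHERE_PLANE_GRID = tuple(
    (R, g) for R in (15.0, 20.0, 25.0) for g in (0.0, 0.2, 0.5)
)


def distance_oracle_deviation(seed: int, n_pairs: int = 20, n_vertices: int = 60) -> float:
    """Max |accelerated - exhaustive| nearest distance over random meshes."""
    rng = np.random.default_rng(seed % 2**31)
    worst = 0.0
    for _ in range(n_pairs):
        a = Surface(
            rng.normal(size=(n_vertices, 3)) * rng.uniform(0.3, 2.0),
            rng.integers(0, n_vertices, (150, 3)), "a",
        ).drop_degenerate()
        b = Surface(
            rng.normal(size=(n_vertices, 3)) * rng.uniform(0.3, 2.0) + rng.normal(size=3),
            rng.integers(0, n_vertices, (150, 3)), "b",
        ).drop_degenerate()
        dev = np.abs(nearest_distance(a, b) - nearest_distance_exhaustive(a, b)).max()
        worst = max(worst, float(dev))
    return worst


def subvoxel_sphere_benchmark(seed: int, radius: float = 10.0,
                              spacing: float = 0.4) -> dict:
    """Sub-voxel surface and watershed accuracy on a rasterized ball."""
    from .core import Image3D, LabelVolume

    sp = np.array([spacing] * 3)
    half = radius + 2.4
    origin = -np.array([half] * 3)
    shape = tuple(int(np.floor(2 * half / s)) for s in sp)
    ax = [origin[a] + (np.arange(shape[a]) + 0.5) * sp[a] for a in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    sdf = np.sqrt(X**2 + Y**2 + Z**2) - radius
    intens = np.clip(0.5 - sdf / 0.5, 0, 1) + np.random.default_rng(
        seed % 2**31
    ).normal(0, 0.01, shape)
    img = Image3D(intens.astype(np.float32), sp, origin)
    labels = LabelVolume((sdf < 0).astype(np.int16) * LABEL_OF["femur"], sp, origin)

    mid = tuple(s // 2 for s in shape)
    markers = [(mid, LABEL_OF["femur"])] + [
        ((1, 1, 1), 0), ((shape[0] - 2, shape[1] - 2, shape[2] - 2), 0),
        ((1, shape[1] - 2, 1), 0), ((shape[0] - 2, 1, shape[2] - 2), 0),
    ]
    ws = watershed3d(img, MarkerSet(markers))
    vol = ws.structure_volume("femur")
    vol_true = 4 / 3 * np.pi * radius**3

    surf = subvoxel_surface(img, ws, "femur")
    r = np.linalg.norm(surf.vertices, axis=1)
    return {
        "mean_radial_error_mm": float(np.abs(r - radius).mean()),
        "watershed_volume_rel_error": float(abs(vol - vol_true) / vol_true),
    }


def _reconstruct(spec: PhantomSpec, condition, resample_step=0.35):
    labs, img, stacks, truth = make_phantom(spec, condition, with_truth_areas=False)
    markers = markers_from_labels(labs, ("femur", "tibia"), seed=1)
    ws = watershed3d(img, markers)
    s = {"tibia": subvoxel_surface(img, ws, "tibia")}
    for name in SOFT_STRUCTURES:
        s[name] = contours_to_mesh(stacks[name], resample_step)
    return s, truth


def registration_benchmark(seed: int) -> dict:
    """Recovery of a known inter-scan rigid perturbation on phantom bones.

    Reconstructs both acquisitions of one phantom, registers the loaded
    tibia onto the unloaded one and compares (a) the recovered transform
    with the generator's, (b) contact areas measured after the recovered
    registration with those after exact truth alignment.
    """
    spec = cohort_specs(1, seed)[0]
    unl, _ = _reconstruct(spec, UNLOADED)
    load, truth = _reconstruct(spec, LOADED)
    T = rigid_register(load["tibia"], unl["tibia"])

    Rp = truth.transform_rotation
    tp = truth.transform_translation
    rot_err = np.rad2deg(
        np.arccos(np.clip((np.trace(T.rotation @ Rp) - 1) / 2, -1, 1))
    )  # T should equal the inverse perturbation (rotation Rp^T)
    trans_err = float(np.linalg.norm(T.translation - (-(Rp.T @ tp))))

    frame = build_joint_frame(unl["tibia"], unl["tibial_cartilage"])
    cfg = ContactConfig()

    def measure(transform_fn):
        surfs = {k: transform_fn(v) for k, v in load.items() if k != "tibia"}
        table = ContactAreaTable("reg")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            interface_areas(surfs, frame, cfg, condition="loaded", table=table)
        return table.areas

    a_rec = measure(T.apply_surface)
    a_true = measure(lambda s: s.transformed(Rp.T, -(Rp.T @ tp)))
    rel = [
        abs(a_rec[k] - a_true[k]) / a_true[k]
        for k in a_rec
        if a_true[k] > 1.0
    ]
    return {
        "residual_rms_mm": T.residual_rms,
        "rotation_error_deg": float(rot_err),
        "translation_error_mm": trans_err,
        "max_area_rel_diff_vs_truth_aligned": float(max(rel)),
    }


def cohort_benchmark(seed: int, n_subjects: int = 9) -> dict:
    """Full phantom-cohort pipeline and its load-response pattern."""
    cfg = PipelineConfig(seed=seed, phantom_cohort=n_subjects, log_level="WARNING")
    tables, report, manifest = run_pipeline(cfg)
    m = report.measures

    def row(itf, comp):
        r = m[(m.interface == itf) & (m.compartment == comp)].iloc[0]
        return r

    ratios = report.ratios
    ml = {
        cond: float(
            ratios[(ratios.interface == "cartilage_cartilage")
                   & (ratios.condition == cond)].iloc[0]["mean_ratio"]
        )
        for cond in ("unloaded", "loaded")
    }
    out = {
        "n_subjects": n_subjects,
        "cc_total_pct_change": float(row("cartilage_cartilage", "total")["mean_pct_change"]),
        "cc_medial_change_mm2": float(row("cartilage_cartilage", "medial")["mean_change"]),
        "cc_lateral_change_mm2": float(row("cartilage_cartilage", "lateral")["mean_change"]),
        "cc_medial_pct_change": float(row("cartilage_cartilage", "medial")["mean_pct_change"]),
        "cc_lateral_pct_change": float(row("cartilage_cartilage", "lateral")["mean_pct_change"]),
        "mf_total_change_mm2": float(row("meniscofemoral", "total")["mean_change"]),
        "mt_total_change_mm2": float(row("meniscotibial", "total")["mean_change"]),
        "ml_ratio_unloaded": ml["unloaded"],
        "ml_ratio_loaded": ml["loaded"],
        "max_registration_rms_mm": float(
            max(v["residual_rms_mm"] for v in manifest.registrations.values())
        ),
    }
    out["report"] = report
    return out


def headline_pattern_holds(bench: dict) -> bool:
    """Direction pattern: cc up (medial > lateral), mf down, mt smallest."""
    return (
        bench["cc_total_pct_change"] > 0
        and bench["cc_medial_change_mm2"] > bench["cc_lateral_change_mm2"] > 0
        and bench["cc_medial_pct_change"] > bench["cc_lateral_pct_change"]
        and bench["mf_total_change_mm2"] < 0
        and abs(bench["mt_total_change_mm2"]) < abs(bench["mf_total_change_mm2"])
        and abs(bench["mt_total_change_mm2"]) < abs(bench["cc_medial_change_mm2"])
    )


def calibration_benchmark(seed: int, n_replicates: int = 1000,
                          n_subjects: int = 9) -> dict:
    """Type-I error of the paired t-test on null cohorts, plus closed-form
    agreement of t and p with an independent implementation."""
    from scipy import stats as sps

    specs = cohort_specs(n_subjects, seed)
    truth = cohort_truth_areas(specs, with_load_effect=False, resolution=0.8)
    rejections = 0
    for i in range(n_replicates):
        tables = simulate_cohort_tables(
            n_subjects, seed=(seed * 131071 + i) % 2**31, truth=truth,
            measurement_cv=0.05,
        )
        a0 = np.array([t.total("unloaded", "cartilage_cartilage") for t in tables])
        a1 = np.array([t.total("loaded", "cartilage_cartilage") for t in tables])
        if paired_t(a1 - a0)["p"] < 0.05:
            rejections += 1

    d = np.array([4.1, -1.2, 3.3, 0.7, 5.9, -0.4, 2.2, 1.8, 3.0])
    res = paired_t(d)
    t_ref, p_ref = sps.ttest_rel(d, np.zeros(len(d)))
    return {
        "type_one_error_rate": rejections / n_replicates,
        "n_replicates": n_replicates,
        "t_deviation": float(abs(res["t"] - t_ref)),
        "p_deviation": float(abs(res["p"] - p_ref)),
    }
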