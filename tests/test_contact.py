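"""Distance engine, contact patches, bidirectional means, interface tables."""

import numpy as np
import pytest
from dataclasses import replace

from hypothesis import given, settings, strategies as st

from tibiofem.contact import (
    ContactConfig,
    ContactError,
    ContactPatch,
    closest_point_on_triangles,
    contact_patch,
    interface_areas,
    mean_contact_area,
    nearest_distance,
    nearest_distance_exhaustive,
)
from tibiofem.core import Surface, rotation_matrix


def _plane_surface(z, nx=10, ny=10, size=10.0, structure="a"):
    xs = np.linspace(0, size, nx)
    ys = np.linspace(0, size, ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    verts = np.stack([X.ravel(), Y.ravel(), np.full(X.size, float(z))], axis=1)
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            faces.append([a, a + ny, a + 1])
            faces.append([a + 1, a + ny, a + ny + 1])
    return Surface(verts, np.asarray(faces), structure)


def _random_mesh(rng, n=60, scale=1.0, offset=0.0, structure="m"):
    v = rng.normal(size=(n, 3)) * scale + offset
    f = rng.integers(0, n, (150, 3))
    return Surface(v, f, structure).drop_degenerate()


class TestPointTriangleKernel:
    def test_matches_dense_barycentric_minimisation(self):
        # independent oracle: dense sampling of barycentric coordinates
        rng = np.random.default_rng(0)
        for _ in range(30):
            tri = rng.normal(size=(3, 3))
            p = rng.normal(size=3) * 2
            _, d = closest_point_on_triangles(p[None], tri[None])
            u = np.linspace(0, 1, 201)
            U, V = np.meshgrid(u, u, indexing="ij")
            keep = U + V <= 1.0
            pts = (
                tri[0]
                + U[keep][:, None] * (tri[1] - tri[0])
                + V[keep][:, None] * (tri[2] - tri[0])
            )
            d_ref = np.linalg.norm(pts - p, axis=1).min()
            assert d[0] <= d_ref + 1e-12
            assert d[0] >= d_ref - 2e-2  # grid resolution slack

    def test_point_on_triangle_is_zero(self):
        tri = np.array([[[0.0, 0, 0], [2, 0, 0], [0, 2, 0]]])
        p = np.array([[0.5, 0.5, 0.0]])
        _, d = closest_point_on_triangles(p, tri)
        assert d[0] == pytest.approx(0.0, abs=1e-14)


class TestNearestDistance:
    def test_coincident_surfaces_zero(self):
        a = _plane_surface(0.0)
        assert nearest_distance(a, a).max() == pytest.approx(0.0, abs=1e-12)

    def test_parallel_planes_exact_gap(self):
        a, b = _plane_surface(0.0), _plane_surface(2.0, structure="b")
        d = nearest_distance(a, b)
        assert np.abs(d - 2.0).max() < 1e-9

    def test_accelerated_equals_exhaustive_on_random_meshes(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            a = _random_mesh(rng, scale=rng.uniform(0.3, 2))
            b = _random_mesh(rng, scale=rng.uniform(0.3, 2), offset=rng.normal())
            dev = np.abs(nearest_distance(a, b) - nearest_distance_exhaustive(a, b))
            assert dev.max() < 1e-9

    def test_capped_distances_exact_below_cutoff(self):
        rng = np.random.default_rng(7)
        a = _random_mesh(rng, scale=2.0)
        b = _random_mesh(rng, scale=2.0, offset=1.0)
        full = nearest_distance(a, b)
        capped = nearest_distance(a, b, max_distance=1.0)
        fin = np.isfinite(capped)
        assert np.array_equal(capped[fin], full[fin])
        assert np.all(full[~fin] > 1.0)
        assert np.all(full[fin] <= 1.0 + 1e-12)

    def test_visualization_only_rejected(self):
        a = _plane_surface(0.0)
        b = replace(_plane_surface(1.0), visualization_only=True)
        with pytest.raises(ContactError, match="visualization"):
            nearest_distance(a, b)
        with pytest.raises(ContactError):
            contact_patch(b, a)


class TestContactPatch:
    def test_planes_beyond_threshold_empty(self):
        a, b = _plane_surface(0.0), _plane_surface(2.0, structure="b")
        patch = contact_patch(a, b, ContactConfig(threshold=1.0))
        assert patch.area == 0.0
        assert len(patch.face_index) == 0

    def test_planes_within_threshold_full_overlap(self):
        a, b = _plane_surface(0.0), _plane_surface(0.5, structure="b")
        patch = contact_patch(a, b, ContactConfig(threshold=1.0))
        assert patch.area == pytest.approx(a.area, rel=1e-12)

    def test_strict_inequality_at_threshold(self):
        a, b = _plane_surface(0.0), _plane_surface(1.0, structure="b")
        patch = contact_patch(a, b, ContactConfig(threshold=1.0))
        assert patch.area == 0.0  # distance exactly 1.0 is excluded

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_threshold_monotone_superset(self, seed):
        rng = np.random.default_rng(seed)
        a = _random_mesh(rng, scale=1.5)
        b = _random_mesh(rng, scale=1.5, offset=0.8)
        d = nearest_distance(a, b)
        small = contact_patch(a, b, ContactConfig(threshold=0.7), distances=d)
        large = contact_patch(a, b, ContactConfig(threshold=1.4), distances=d)
        assert set(small.face_index) <= set(large.face_index)
        assert small.area <= large.area + 1e-12


class TestMeanContactArea:
    def _patch(self, area):
        return ContactPatch("a", "b", np.arange(0), float(area))

    def test_equal_areas_mean(self):
        res = mean_contact_area(self._patch(100), self._patch(100))
        assert res.area == 100.0 and not res.flagged

    def test_small_asymmetry_not_flagged(self):
        res = mean_contact_area(self._patch(100), self._patch(110))
        assert res.area == pytest.approx(105.0) and not res.flagged

    def test_large_asymmetry_flagged_not_error(self):
        with pytest.warns(UserWarning, match="asymmetry"):
            res = mean_contact_area(self._patch(100), self._patch(150))
        assert res.area == pytest.approx(125.0)
        assert res.flagged


class TestInterfaceAreas:
    def test_phantom_all_interfaces_within_3_percent(self, processed_phantom):
        pp = processed_phantom
        for (cond, itf, comp), measured in pp.table.areas.items():
            truth = pp.truth.areas[(cond, itf, comp)]
            assert measured == pytest.approx(truth, rel=0.03), (cond, itf, comp)

    def test_missing_structure_error_names_label(self, processed_phantom):
        surfs = {
            k: v
            for k, v in processed_phantom.surfaces["unloaded"].items()
            if k not in ("tibia", "medial_meniscus")
        }
        with pytest.raises(ContactError, match="medial_meniscus"):
            interface_areas(surfs, processed_phantom.frame)

    def test_empty_menisci_give_zero_rows_cc_unchanged(self, processed_phantom):
        pp = processed_phantom
        surfs = {k: v for k, v in pp.surfaces["unloaded"].items() if k != "tibia"}
        gutted = dict(surfs)
        for m in ("medial_meniscus", "lateral_meniscus"):
            gutted[m] = replace(surfs[m], faces=surfs[m].faces[:0])
        t = interface_areas(gutted, pp.frame, condition="unloaded")
        for comp in ("medial", "lateral"):
            assert t.areas[("unloaded", "meniscofemoral", comp)] == 0.0
            assert t.areas[("unloaded", "meniscotibial", comp)] == 0.0
            assert t.areas[("unloaded", "cartilage_cartilage", comp)] == pytest.approx(
                pp.table.areas[("unloaded", "cartilage_cartilage", comp)], rel=1e-9
            )

    def test_rigid_invariance_of_areas(self, processed_phantom):
        pp = processed_phantom
        R = rotation_matrix((0.2, 1.0, -0.4), 17.0)
        t = np.array([3.0, -2.0, 5.0])
        moved = {
            k: v.transformed(R, t)
            for k, v in pp.surfaces["unloaded"].items()
            if k != "tibia"
        }
        frame_moved = replace_frame(pp.frame, R, t)
        table = interface_areas(moved, frame_moved, condition="unloaded")
        for key, v in table.areas.items():
            ref = pp.table.areas[key]
            assert v == pytest.approx(ref, rel=1e-6), key

    def test_total_is_bitwise_sum_of_compartments(self, processed_phantom):
        t = processed_phantom.table
        for cond in ("unloaded", "loaded"):
            for itf in ("cartilage_cartilage", "meniscofemoral", "meniscotibial"):
                assert t.total(cond, itf) == (
                    t.areas[(cond, itf, "medial")] + t.areas[(cond, itf, "lateral")]
                )


def replace_frame(frame, R, t):
    from tibiofem.joint_geometry import JointFrame

    return JointFrame(
        origin=R @ frame.origin + t,
        axes=frame.axes @ R.T,
        medial_direction_sign=frame.medial_direction_sign,
        split_point=R @ frame.split_point + t,
        split_normal=R @ frame.split_normal,
    )
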