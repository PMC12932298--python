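"""Watershed, sub-voxel surfaces, contour meshing and display smoothing."""

import numpy as np
import pytest

from tibiofem.core import ContourStack, Image3D, LabelVolume, LABEL_OF
from tibiofem.segmentation import (
    MarkerSet,
    SegmentationConfig,
    contours_to_mesh,
    markers_from_labels,
    subvoxel_surface,
    visual_smooth,
    watershed3d,
)

from conftest import circle_polygon, cylinder_stack, make_sphere_volume


class TestWatershed:
    def test_constant_image_single_marker_floods_everything(self):
        img = Image3D(np.zeros((12, 12, 12)), (1, 1, 1), (0, 0, 0))
        out = watershed3d(img, MarkerSet([((6, 6, 6), LABEL_OF["tibia"])]))
        assert np.all(out.labels == LABEL_OF["tibia"])

    def test_empty_marker_set_rejected(self):
        img = Image3D(np.zeros((8, 8, 8)), (1, 1, 1), (0, 0, 0))
        with pytest.raises(ValueError, match="empty"):
            watershed3d(img, MarkerSet([]))

    def test_marker_outside_grid_rejected(self):
        img = Image3D(np.zeros((8, 8, 8)), (1, 1, 1), (0, 0, 0))
        with pytest.raises(ValueError, match="outside"):
            watershed3d(img, MarkerSet([((9, 0, 0), 1)]))

    def test_bright_planar_ridge_splits_volume(self):
        # gradient ridges on both flanks of a bright plane; the partition
        # boundary must stay within the ridge zone around the midplane
        shape = (24, 10, 10)
        I = np.zeros(shape)
        I[11:13] = 1.0
        img = Image3D(I, (1, 1, 1), (0, 0, 0))
        out = watershed3d(
            img, MarkerSet([((2, 5, 5), LABEL_OF["femur"]), ((21, 5, 5), LABEL_OF["tibia"])])
        )
        assert np.all(out.labels[:10] == LABEL_OF["femur"])
        assert np.all(out.labels[14:] == LABEL_OF["tibia"])
        # full partition: every voxel got exactly one of the two labels
        assert set(np.unique(out.labels)) == {LABEL_OF["femur"], LABEL_OF["tibia"]}

    def test_ball_volume_within_2_percent(self):
        img, labels = make_sphere_volume(radius=8.0, noise_sd=0.01, seed=2)
        n = img.shape
        markers = [((n[0] // 2, n[1] // 2, n[2] // 2), LABEL_OF["femur"])]
        markers += [((1, 1, 1), 0), ((n[0] - 2, n[1] - 2, n[2] - 2), 0),
                    ((1, n[1] - 2, 1), 0), ((n[0] - 2, 1, n[2] - 2), 0)]
        out = watershed3d(img, MarkerSet(markers))
        vol = out.structure_volume("femur")
        assert vol == pytest.approx(4 / 3 * np.pi * 8.0**3, rel=0.02)

    def test_partition_covers_every_voxel_once(self):
        img, labels = make_sphere_volume(radius=6.0)
        markers = markers_from_labels(labels, ("femur",), seed=0)
        out = watershed3d(img, markers)
        assert out.labels.shape == img.shape  # one label per voxel by dtype
        assert set(np.unique(out.labels)) <= set(range(7))


def _plane_image(z0, spacing=(0.4, 0.4, 0.5), ramp=0.5, shape=(20, 20, 30)):
    """Half-space z < z0 with a linear partial-volume edge ramp."""
    spacing = np.asarray(spacing)
    origin = np.zeros(3)
    ax = [origin[a] + (np.arange(shape[a]) + 0.5) * spacing[a] for a in range(3)]
    Z = np.meshgrid(*ax, indexing="ij")[2]
    intens = np.clip(0.5 - (Z - z0) / ramp, 0, 1)
    labels = (Z < z0).astype(np.int16) * LABEL_OF["tibia"]
    return (
        Image3D(intens, spacing, origin),
        LabelVolume(labels, spacing, origin),
    )


class TestSubvoxelSurface:
    # a crossing at a sample point recovers to 1e-3 mm; the half-voxel
    # offset case is limited by the spline's plateau estimate (a few um)
    @pytest.mark.parametrize("z0,tol", [(7.5, 1e-3), (7.25, 5e-3)])
    def test_plane_recovered(self, z0, tol):
        img, labels = _plane_image(z0)
        surf = subvoxel_surface(img, labels, "tibia")
        z = surf.vertices[:, 2]
        interior = (
            (surf.vertices[:, 0] > 1) & (surf.vertices[:, 0] < 7)
            & (surf.vertices[:, 1] > 1) & (surf.vertices[:, 1] < 7)
            & (z > 5.0) & (z < 10.0)
        )  # top face of the slab, away from the box edges
        assert interior.sum() > 50
        assert np.abs(z[interior] - z0).max() < tol

    def test_sphere_mean_radial_error_below_tenth_mm(self):
        img, labels = make_sphere_volume(radius=10.0, noise_sd=0.01, seed=4)
        surf = subvoxel_surface(img, labels, "femur")
        r = np.linalg.norm(surf.vertices, axis=1)
        assert np.abs(r - 10.0).mean() < 0.1

    def test_refinement_bounded_by_voxel_diagonal(self):
        img, labels = make_sphere_volume(radius=7.0, noise_sd=0.02, seed=5)
        from tibiofem.segmentation import _voxel_boundary_mesh

        initial = _voxel_boundary_mesh(labels, "femur")
        refined = subvoxel_surface(img, labels, "femur")
        diag = np.linalg.norm(img.spacing)
        move = np.linalg.norm(refined.vertices - initial.vertices, axis=1)
        assert move.max() <= diag + 1e-9

    def test_absent_structure_rejected(self):
        img, labels = make_sphere_volume(radius=6.0)
        with pytest.raises(ValueError, match="absent"):
            subvoxel_surface(img, labels, "medial_meniscus")

    def test_lattice_mismatch_rejected(self):
        img, labels = make_sphere_volume(radius=6.0)
        bad = LabelVolume(labels.labels, labels.spacing * 2, labels.origin)
        with pytest.raises(ValueError, match="lattice"):
            subvoxel_surface(img, bad, "femur")


class TestContoursToMesh:
    def test_cylinder_lateral_area(self):
        stack = cylinder_stack(radius=5.0, n_slices=11, slice_spacing=0.5)
        surf = contours_to_mesh(stack, resample_step=0.2)
        walls = np.abs(surf.face_normals()[:, 0]) < 0.5
        lateral = surf.face_areas()[walls].sum()
        assert lateral == pytest.approx(2 * np.pi * 5.0 * 10 * 0.5, rel=0.02)
        assert surf.to_trimesh().volume == pytest.approx(np.pi * 25 * 5.0, rel=0.02)

    def test_frustum_lateral_area(self):
        stack = cylinder_stack(radius=5.0, n_slices=11, slice_spacing=0.5,
                               shrink_per_slice=0.05)
        surf = contours_to_mesh(stack, resample_step=0.2)
        r1, r2 = 5.0, 5.0 * (1 - 0.05 * 10)
        slant = np.hypot(r1 - r2, 10 * 0.5)
        walls = np.abs(surf.face_normals()[:, 0]) < 0.99
        lateral = surf.face_areas()[walls].sum()
        assert lateral == pytest.approx(np.pi * (r1 + r2) * slant, rel=0.02)

    def test_single_slice_rejected(self):
        stack = ContourStack("x", "sagittal", [(0.0, [circle_polygon(3.0)])])
        with pytest.raises(ValueError, match="2 slices"):
            contours_to_mesh(stack)

    def test_area_error_decreases_with_sampling_density(self):
        true = 2 * np.pi * 5.0 * 10 * 0.5
        errs = []
        for step in (1.6, 0.8, 0.2):
            surf = contours_to_mesh(
                cylinder_stack(radius=5.0, n_slices=11, slice_spacing=0.5),
                resample_step=step,
            )
            walls = np.abs(surf.face_normals()[:, 0]) < 0.5
            errs.append(abs(surf.face_areas()[walls].sum() - true) / true)
        assert errs[0] > errs[1] > errs[2]

    def test_branching_two_components_meshed(self):
        # two circles per slice -> two closed tubes, matched by centroid
        slices = []
        for i in range(6):
            slices.append(
                (i * 0.5, [circle_polygon(2.0, center=(-4, 0)),
                           circle_polygon(1.5, center=(4, 0))])
            )
        surf = contours_to_mesh(ContourStack("x", "sagittal", slices), 0.2)
        comps = surf.to_trimesh().split(only_watertight=False)
        assert len(comps) == 2
        assert surf.area > 0


class TestVisualSmooth:
    def test_sigma_to_zero_is_identity(self):
        surf = contours_to_mesh(cylinder_stack(), 0.3)
        out = visual_smooth(surf, SegmentationConfig(visual_sigma=1e-9))
        assert np.abs(out.vertices - surf.vertices).max() < 1e-6

    def test_affine_surface_preserved(self):
        surf = contours_to_mesh(
            cylinder_stack(radius=5.0, n_slices=15, shrink_per_slice=0.03), 0.3
        )  # cone: vertex positions affine in the slice coordinate
        out = visual_smooth(surf)
        assert np.abs(out.vertices - surf.vertices).max() < 1e-9

    def test_corrugation_amplitude_reduced(self):
        slices = []
        for i in range(25):
            r = 5.0 + 0.5 * np.sin(2 * np.pi * i / 5.0)
            slices.append((i * 0.5, [circle_polygon(r)]))
        surf = contours_to_mesh(ContourStack("x", "sagittal", slices), 0.3)
        out = visual_smooth(surf, SegmentationConfig(visual_sigma=1.25))
        def amplitude(s):
            r = np.hypot(s.vertices[:, 1], s.vertices[:, 2])
            inner = (s.vertices[:, 0] > 2) & (s.vertices[:, 0] < 10)
            return r[inner].max() - r[inner].min()
        assert out.visualization_only
        assert amplitude(out) < 0.7 * amplitude(surf)

    def test_requires_contour_surface(self):
        from tibiofem.core import Surface

        tri = Surface([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 2]], "x")
        with pytest.raises(ValueError, match="contours_to_mesh"):
            visual_smooth(tri)
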