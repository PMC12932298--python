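"""Shared fixtures: small synthetic volumes and one fully processed phantom.

The expensive default-phantom fixture (both load conditions segmented,
registered and measured) is session-scoped and shared between the unit and
acceptance tests; everything is generated at run time from seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pytest

from tibiofem.contact import ContactAreaTable, ContactConfig, interface_areas
from tibiofem.core import ContourStack, Image3D, LabelVolume, LABEL_OF
from tibiofem.joint_geometry import build_joint_frame, rigid_register
from tibiofem.phantom import LOADED, UNLOADED, PhantomSpec, make_phantom
from tibiofem.pipeline import SOFT_STRUCTURES
from tibiofem.segmentation import (
    contours_to_mesh,
    markers_from_labels,
    subvoxel_surface,
    watershed3d,
)


def make_sphere_volume(radius=10.0, spacing=(0.4, 0.4, 0.5), margin=2.5,
                       ramp=0.5, noise_sd=0.0, seed=0, label="femur"):
    """Ball with a partial-volume linear edge ramp, centred on the grid."""
    spacing = np.asarray(spacing, float)
    half = radius + margin
    origin = -np.array([half, half, half])
    shape = tuple(int(np.floor(2 * half / s)) for s in spacing)
    ax = [origin[a] + (np.arange(shape[a]) + 0.5) * spacing[a] for a in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    sdf = np.sqrt(X**2 + Y**2 + Z**2) - radius
    intens = np.clip(0.5 - sdf / ramp, 0.0, 1.0)
    if noise_sd > 0:
        intens = intens + np.random.default_rng(seed).normal(0, noise_sd, shape)
    labels = (sdf < 0).astype(np.int16) * LABEL_OF[label]
    return (
        Image3D(intens.astype(np.float32), spacing, origin),
        LabelVolume(labels, spacing, origin),
    )


def circle_polygon(radius, n=256, center=(0.0, 0.0)):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.stack(
        [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)], axis=1
    )


def cylinder_stack(radius=5.0, n_slices=11, slice_spacing=0.5, n_pts=256,
                   shrink_per_slice=0.0, structure="tibial_cartilage"):
    slices = []
    for i in range(n_slices):
        r = radius * (1.0 - shrink_per_slice * i)
        slices.append((i * slice_spacing, [circle_polygon(r, n_pts)]))
    return ContourStack(structure, "sagittal", slices)


@dataclass
class ProcessedPhantom:
    """Both acquisitions of the default phantom, measured end to end."""

    spec: PhantomSpec
    truth: object  # GroundTruth (with both conditions' analytic areas)
    surfaces: dict  # condition -> {structure: Surface} (loaded: registered)
    raw_loaded: dict  # loaded surfaces before registration
    frame: object
    transform: object  # recovered loaded->unloaded rigid transform
    table: ContactAreaTable


@pytest.fixture(scope="session")
def processed_phantom() -> ProcessedPhantom:
    spec = PhantomSpec(seed=11)
    surfaces, raw_loaded, truth = {}, {}, None
    for cond in (UNLOADED, LOADED):
        labs, img, stacks, gt = make_phantom(
            spec, cond, with_truth_areas=(cond is LOADED)
        )
        if cond is LOADED:
            truth = gt
        markers = markers_from_labels(labs, ("femur", "tibia"), seed=1)
        ws = watershed3d(img, markers)
        s = {"tibia": subvoxel_surface(img, ws, "tibia")}
        for name in SOFT_STRUCTURES:
            s[name] = contours_to_mesh(stacks[name], resample_step=0.35)
        surfaces[cond.label] = s
    raw_loaded = dict(surfaces["loaded"])
    T = rigid_register(surfaces["loaded"]["tibia"], surfaces["unloaded"]["tibia"])
    surfaces["loaded"] = {k: T.apply_surface(v) for k, v in surfaces["loaded"].items()}
    frame = build_joint_frame(
        surfaces["unloaded"]["tibia"], surfaces["unloaded"]["tibial_cartilage"]
    )
    table = ContactAreaTable("default_phantom")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for cond in ("unloaded", "loaded"):
            interface_areas(
                {k: surfaces[cond][k] for k in SOFT_STRUCTURES},
                frame,
                ContactConfig(),
                condition=cond,
                table=table,
            )
    return ProcessedPhantom(spec, truth, surfaces, raw_loaded, frame, T, table)
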