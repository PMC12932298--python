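"""Shared containers for volumes, surfaces and contour stacks.

All geometry lives in physical millimetre coordinates (right-handed axes).
Voxel centres sit at ``origin + (index + 0.5) * spacing``; spacing may be
anisotropic (the imaging protocol this package targets uses
0.4 x 0.4 x 0.5 mm), so no computation is ever done in index space.

Axis convention used throughout: x = medial-lateral (RL), y =
anterior-posterior (AP), z = proximal-distal (FH).  Sagittal slices are
planes of constant x, coronal slices planes of constant y.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

# Canonical structure labels (value order fixed: a LabelVolume uses these ints).
STRUCTURES = (
    "background",
    "femur",
    "tibia",
    "femoral_cartilage",
    "tibial_cartilage",
    "medial_meniscus",
    "lateral_meniscus",
)
LABEL_OF = {name: i for i, name in enumerate(STRUCTURES)}


def _as_vec3(x) -> np.ndarray:
    v = np.asarray(x, dtype=float).reshape(3)
    return v


@dataclass
class Image3D:
    """Scalar intensity grid with physical geometry."""

    intensities: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    orientation: str = "RAS"

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=np.float32)
        self.spacing = _as_vec3(self.spacing)
        self.origin = _as_vec3(self.origin)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if not np.all(self.spacing > 0):
            raise ValueError("spacing must be positive on every axis")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def voxel_centers_1d(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing[a]
            for a in range(3)
        )

    def mm_to_index(self, points_mm: np.ndarray) -> np.ndarray:
        """Continuous voxel indices (0 = centre of first voxel) for mm points."""
        p = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return (p - self.origin) / self.spacing - 0.5


@dataclass
class LabelVolume:
    """Integer-labelled grid over the same lattice as an :class:`Image3D`.

    Every voxel carries exactly one label from :data:`STRUCTURES`.
    """

    labels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    label_names: tuple[str, ...] = STRUCTURES

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        self.spacing = _as_vec3(self.spacing)
        self.origin = _as_vec3(self.origin)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.all(self.spacing > 0):
            raise ValueError("spacing must be positive on every axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, structure: str) -> np.ndarray:
        return self.labels == self.label_names.index(structure)

    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def structure_volume(self, structure: str) -> float:
        """Voxel-count volume of one structure in mm^3."""
        return float(np.count_nonzero(self.mask(structure))) * self.voxel_volume()

    def same_lattice(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class Surface:
    """Triangulated surface in mm with a structure identity tag.

    ``visualization_only`` marks surfaces that have been smoothed for display;
    quantitative operations refuse them.
    """

    vertices: np.ndarray
    faces: np.ndarray
    structure: str = ""
    visualization_only: bool = False
    provenance: str = ""

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        t = self.triangles()
        c = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        return 0.5 * np.linalg.norm(c, axis=1)

    def face_centroids(self) -> np.ndarray:
        return self.triangles().mean(axis=1)

    def face_normals(self) -> np.ndarray:
        t = self.triangles()
        c = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        n = np.linalg.norm(c, axis=1)
        n[n == 0] = 1.0
        return c / n[:, None]

    @property
    def area(self) -> float:
        return float(self.face_areas().sum())

    def drop_degenerate(self, eps: float = 1e-12) -> "Surface":
        keep = self.face_areas() > eps
        return replace(self, faces=self.faces[keep])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Surface":
        v = self.vertices @ np.asarray(rotation, float).T + _as_vec3(translation)
        return replace(self, vertices=v)

    def submesh(self, face_index: np.ndarray) -> "Surface":
        """Surface restricted to a face subset (vertices kept as-is)."""
        return replace(self, faces=self.faces[np.asarray(face_index)])

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
        )

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh, structure: str = "", **kw) -> "Surface":
        return cls(np.asarray(mesh.vertices), np.asarray(mesh.faces), structure, **kw)


@dataclass
class ContourStack:
    """Per-slice closed polygons of one structure, as drawn slice by slice.

    ``plane`` is the slicing plane ('sagittal': slices of constant x,
    'coronal': constant y).  ``slices`` maps the slice coordinate (mm along
    the plane normal) to one or more closed polygons, each an (n, 2) array of
    in-plane mm coordinates.  In-plane axis order: sagittal -> (y, z),
    coronal -> (x, z).
    """

    structure: str
    plane: str
    slices: list[tuple[float, list[np.ndarray]]] = field(default_factory=list)

    PLANES = ("sagittal", "coronal")
    _NORMAL_AXIS = {"sagittal": 0, "coronal": 1}
    _INPLANE_AXES = {"sagittal": (1, 2), "coronal": (0, 2)}

    def __post_init__(self):
        if self.plane not in self.PLANES:
            raise ValueError(f"plane must be one of {self.PLANES}")
        coords = [s for s, _ in self.slices]
        if any(b <= a for a, b in zip(coords, coords[1:])):
            raise ValueError("slice coordinates must be strictly increasing")

    @property
    def normal_axis(self) -> int:
        return self._NORMAL_AXIS[self.plane]

    @property
    def inplane_axes(self) -> tuple[int, int]:
        return self._INPLANE_AXES[self.plane]

    def n_slices(self) -> int:
        return len(self.slices)

    def to_3d(self, slice_coord: float, polygon: np.ndarray) -> np.ndarray:
        """Lift an in-plane polygon to 3D mm coordinates."""
        out = np.empty((len(polygon), 3))
        out[:, self.normal_axis] = slice_coord
        a, b = self.inplane_axes
        out[:, a] = polygon[:, 0]
        out[:, b] = polygon[:, 1]
        return out


def rotation_matrix(axis, angle_deg: float) -> np.ndarray:
    """Rotation about an arbitrary axis through the origin (degrees)."""
    axis = _as_vec3(axis)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)
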