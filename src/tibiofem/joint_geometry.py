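"""Bone-based joint coordinate system, rigid registration, compartment split.

The tibia is the common reference of all three contact interfaces, so the
coordinate system derives from it: principal directions of the tibial bone
surface give the medial-lateral (largest extent), anterior-posterior and
proximal-distal axes; the proximal-distal axis points toward the cartilage
side.  The medial direction is identified from the tibial cartilage facets
(the medial plateau facet is the larger).  The medial/lateral split plane
passes through the midpoint of the two largest cartilage facet centroids
with its normal along the medial-lateral axis.

Registration removes acquisition-frame subject motion between the unloaded
and loaded scans by an iterative closest-point fit of the loaded tibia onto
the unloaded tibia; the femoral motion under load is physiology and is
deliberately not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contact import _TriangleDistanceIndex
from .core import Surface


class GeometryError(ValueError):
    pass


@dataclass
class JointFrame:
    """Orthonormal joint coordinate system with the compartment split plane."""

    origin: np.ndarray  # mm
    axes: np.ndarray  # rows: medial-lateral, anterior-posterior, proximal-distal
    medial_direction_sign: float  # +1: +ML axis points medially
    split_point: np.ndarray
    split_normal: np.ndarray  # parallel to the ML axis

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float)
        self.axes = np.asarray(self.axes, float)
        self.split_point = np.asarray(self.split_point, float)
        self.split_normal = np.asarray(self.split_normal, float)
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-9):
            raise GeometryError("frame axes must be orthonormal")
        cosang = abs(float(self.split_normal @ self.axes[0]))
        if abs(cosang - 1.0) > 1e-9:
            raise GeometryError("split normal must be parallel to the ML axis")

    def medial_side(self, points: np.ndarray) -> np.ndarray:
        """True where a point lies on the medial side of the split plane."""
        s = (np.atleast_2d(points) - self.split_point) @ (
            self.split_normal * self.medial_direction_sign
        )
        return s > 0


@dataclass
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` in mm."""

    rotation: np.ndarray
    translation: np.ndarray
    residual_rms: float = 0.0
    n_iterations: int = 0
    residual_trace: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, float)
        self.translation = np.asarray(self.translation, float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise GeometryError("rotation must be proper (det = +1)")
        if not np.allclose(
            self.rotation @ self.rotation.T, np.eye(3), atol=1e-9
        ):
            raise GeometryError("rotation must be orthonormal")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def apply_surface(self, surface: Surface) -> Surface:
        return surface.transformed(self.rotation, self.translation)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def _area_weighted_pca(surface: Surface):
    """Area-weighted centroid and principal directions of a surface."""
    c = surface.face_centroids()
    w = surface.face_areas()
    w = w / w.sum()
    mean = w @ c
    d = c - mean
    cov = (d * w[:, None]).T @ d
    evals, evecs = np.linalg.eigh(cov)  # ascending
    return mean, evals[::-1], evecs[:, ::-1].T  # rows, descending variance


def build_joint_frame(tibia: Surface, tibial_cartilage: Surface) -> JointFrame:
    """Joint coordinate system from the tibial bone and cartilage surfaces.

    Equivariant under global rigid motion: ``frame(R S + t) = R frame(S) + t``.
    Raises on degenerate principal directions (no unique axis ordering).
    """
    if tibia.n_faces == 0 or tibial_cartilage.n_faces == 0:
        raise GeometryError("empty surface passed to build_joint_frame")
    t_mean, evals, axes = _area_weighted_pca(tibia)
    rel_gap = np.diff(evals[::-1]) / max(evals[0], 1e-300)
    if np.any(np.abs(rel_gap) < 1e-6):
        raise GeometryError(
            "degenerate principal directions of the tibial surface; "
            f"eigenvalues {evals}"
        )
    ml, ap, pd_ = axes

    cart_mean = _surface_centroid(tibial_cartilage)
    if (cart_mean - t_mean) @ pd_ < 0:
        pd_ = -pd_
    # the two largest cartilage components are the plateau facets
    facets = sorted(
        tibial_cartilage.to_trimesh().split(only_watertight=False),
        key=lambda m: m.area,
        reverse=True,
    )[:2]
    if len(facets) < 2:
        raise GeometryError(
            "tibial cartilage must expose two plateau facets to place the "
            "compartment split plane"
        )
    c_big, c_small = [np.asarray(m.center_mass if m.is_watertight else m.centroid)
                      for m in facets]
    # orient ML toward the larger (medial) facet
    if (c_big - c_small) @ ml < 0:
        ml = -ml
    ap = np.cross(pd_, ml)  # right-handed (ML, AP, PD)

    split_point = 0.5 * (c_big + c_small)
    return JointFrame(
        origin=cart_mean,
        axes=np.stack([ml, ap, pd_]),
        medial_direction_sign=1.0,
        split_point=split_point,
        split_normal=ml,
    )


def _surface_centroid(surface: Surface) -> np.ndarray:
    w = surface.face_areas()
    return (surface.face_centroids() * w[:, None]).sum(axis=0) / w.sum()


def split_compartments(surface: Surface, frame: JointFrame):
    """Face-exclusive medial/lateral partition at the split plane.

    Faces are assigned by which side their centroid lies on (points exactly
    on the plane count as lateral, a measure-zero deterministic tie rule),
    so medial and lateral faces are disjoint and their union is the input.
    """
    if frame is None:
        raise GeometryError("split_compartments requires a joint frame")
    med = frame.medial_side(surface.face_centroids())
    return surface.submesh(np.nonzero(med)[0]), surface.submesh(np.nonzero(~med)[0])


def _kabsch(src: np.ndarray, dst: np.ndarray):
    """Least-squares rigid transform mapping src points onto dst points."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return R, cd - R @ cs


def rigid_register(
    moving_bone: Surface,
    fixed_bone: Surface,
    max_iterations: int = 80,
    tolerance: float = 1e-5,
    n_samples: int = 3000,
) -> RigidTransform:
    """Iterative closest-point registration of one bone surface onto another.

    Initialises by centroid alignment, then alternates exact closest-point
    queries (point to triangle) with the least-squares rigid update until
    the RMS point-to-surface residual stabilises (relative change below
    ``tolerance``).  Returns the transform mapping ``moving_bone`` into the
    fixed frame, with the residual RMS and per-iteration trace attached.
    Deterministic: sampling is strided, not random.
    """
    if moving_bone.n_faces == 0 or fixed_bone.n_faces == 0:
        raise GeometryError("empty surface passed to rigid_register")
    index = _TriangleDistanceIndex(fixed_bone)
    stride = max(1, len(moving_bone.vertices) // n_samples)
    pts0 = moving_bone.vertices[::stride]

    R = np.eye(3)
    t = _surface_centroid(fixed_bone) - _surface_centroid(moving_bone)
    trace = []
    prev = np.inf
    for it in range(1, max_iterations + 1):
        pts = pts0 @ R.T + t
        dist, closest = index.query(pts)
        rms = float(np.sqrt(np.mean(dist**2)))
        trace.append(rms)
        R_step, t_step = _kabsch(pts, closest)
        R = R_step @ R
        t = R_step @ t + t_step
        if abs(prev - rms) < tolerance * max(rms, 1e-9) + 1e-9:
            return RigidTransform(R, t, residual_rms=rms, n_iterations=it,
                                  residual_trace=trace)
        prev = rms
    raise GeometryError(
        f"ICP did not converge in {max_iterations} iterations; residual "
        f"trace tail {trace[-5:]}"
    )
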