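"""Synthetic knee phantom with closed-form ground-truth contact areas.

The phantom emulates a tibiofemoral joint imaged unloaded and under a 400 N
axial load: two spherical femoral condyles carrying a cartilage shell, a
tibial plateau with two circular cartilage facets, and C-shaped wedge
menisci seated on the plateau around each condyle axis.  The load response
is a femoral approach toward the tibia plus a small adduction tilt (the
medial compartment compresses more, as the physiological adduction moment
dictates) and an outward radial displacement of the menisci; the loaded
acquisition is additionally moved by a small rigid perturbation emulating
inter-scan subject motion.

Geometry is deliberately simple so that the contact areas defined by the
1 mm Euclidean-distance criterion have exact closed forms (sphere on plane,
offset annular sectors) or dense-quadrature values (meniscofemoral), giving
an analytic oracle for the whole measurement pipeline.

Axes: x = medial-lateral (medial at +x), y = anterior-posterior,
z = proximal-distal (tibial cartilage surface at z = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from .core import (
    ContourStack,
    Image3D,
    LabelVolume,
    LABEL_OF,
    STRUCTURES,
    Surface,
    rotation_matrix,
)

COMPARTMENTS = ("medial", "lateral")


class PhantomError(ValueError):
    pass


@dataclass(frozen=True)
class LoadCondition:
    label: str
    force: float  # newtons

    def __post_init__(self):
        if self.label not in ("unloaded", "loaded"):
            raise PhantomError("condition label must be 'unloaded' or 'loaded'")
        if self.force < 0:
            raise PhantomError("force must be >= 0")


UNLOADED = LoadCondition("unloaded", 0.0)
LOADED = LoadCondition("loaded", 400.0)


@dataclass
class PhantomSpec:
    """Parametric description of the synthetic knee and its load response.

    Lengths in mm, angles in degrees.  Defaults give a medial-dominant
    baseline (larger medial condyle, smaller medial gap) and a load response
    whose direction pattern matches in vivo observations: cartilage contact
    up (more medially), meniscofemoral contact down, meniscotibial stable.
    """

    condyle_radius_medial: float = 18.0  # bone radius
    condyle_radius_lateral: float = 16.5
    condyle_center_offsets: tuple = ((22.0, 0.0, 0.0), (-22.0, 0.0, 0.0))
    cartilage_thickness_femoral: float = 2.2
    cartilage_thickness_tibial: float = 2.0
    plateau_gap_medial: float = 0.4  # minimal cartilage-to-cartilage gap, unloaded
    plateau_gap_lateral: float = 0.6
    meniscus_inner_radius: float = 11.0
    meniscus_outer_radius: float = 16.0
    meniscus_height: float = 7.0
    meniscus_arc_span: float = 200.0  # degrees, opening toward the notch
    meniscus_femoral_gap: float = 0.5  # uniform gap of the superior dish
    load_approach: float = 0.06  # femoral translation toward tibia under load
    load_adduction_deg: float = 0.08  # varus tilt under load (medial drops)
    meniscus_radial_shift: float = 1.8  # outward displacement under load
    rigid_perturbation_deg: float = 2.0
    rigid_perturbation_axis: tuple = (0.3, 1.0, 0.5)
    rigid_perturbation_translation: tuple = (1.2, -0.8, 0.6)
    voxel_spacing: tuple = (0.4, 0.4, 0.5)
    noise_sd: float = 0.02
    seed: int = 0

    # fixed internal choices (not part of the study conditions)
    plateau_patch_radius: tuple = (20.2, 19.8)  # (medial, lateral) facet radii
    cartilage_cap_deg: float = 100.0  # angular extent of the femoral shell
    tibia_box: tuple = (42.5, 22.0, 8.0)  # half-x, half-y, depth below cartilage
    grid_halfextent: tuple = (46.0, 26.0)  # x, y
    grid_zrange: tuple = (-16.0, 27.0)
    intensity_levels: tuple = (0.0, 1.0, 1.0, 0.55, 0.55, 0.75, 0.75)
    edge_ramp: float = 0.5  # mm, partial-volume ramp width

    def __post_init__(self):
        self.validate()

    # -- derived quantities ------------------------------------------------
    def bone_radius(self, comp: str) -> float:
        return (
            self.condyle_radius_medial
            if comp == "medial"
            else self.condyle_radius_lateral
        )

    def effective_radius(self, comp: str) -> float:
        """Condyle + femoral cartilage radius (the contacting sphere)."""
        return self.bone_radius(comp) + self.cartilage_thickness_femoral

    def plateau_gap(self, comp: str) -> float:
        return self.plateau_gap_medial if comp == "medial" else self.plateau_gap_lateral

    def facet_radius(self, comp: str) -> float:
        """Tibial cartilage facet radius; the medial facet is the larger."""
        return self.plateau_patch_radius[0 if comp == "medial" else 1]

    def condyle_axis(self, comp: str) -> np.ndarray:
        """Unloaded condyle axis position (x, y) on the plateau."""
        off = self.condyle_center_offsets[0 if comp == "medial" else 1]
        return np.asarray(off[:2], dtype=float)

    def condyle_center(self, comp: str) -> np.ndarray:
        off = self.condyle_center_offsets[0 if comp == "medial" else 1]
        x, y = self.condyle_axis(comp)
        z = self.effective_radius(comp) + self.plateau_gap(comp) + float(off[2])
        return np.array([x, y, z])

    def dish_radius(self, comp: str) -> float:
        return self.effective_radius(comp) + self.meniscus_femoral_gap

    def meniscus_top_height(self, comp: str, r) -> np.ndarray:
        """Height of the superior meniscal surface at radius r from the axis."""
        c = self.condyle_center(comp)
        dish = c[2] - np.sqrt(np.maximum(self.dish_radius(comp) ** 2 - np.asarray(r) ** 2, 0.0))
        return np.minimum(dish, self.meniscus_height)

    def meniscus_center_azimuth(self, comp: str) -> float:
        """Azimuth (about the condyle axis) of the C's outward midline."""
        return 0.0 if comp == "medial" else np.pi

    def outward_direction(self, comp: str) -> np.ndarray:
        return np.array([1.0, 0.0, 0.0]) if comp == "medial" else np.array([-1.0, 0.0, 0.0])

    def load_rotation(self) -> np.ndarray:
        # positive adduction drops the medial (+x) side
        return rotation_matrix((0.0, 1.0, 0.0), self.load_adduction_deg)

    def femur_transform(self, condition: LoadCondition):
        """(R, t) applied to femur + femoral cartilage in anatomy space."""
        if condition.label == "unloaded":
            return np.eye(3), np.zeros(3)
        return self.load_rotation(), np.array([0.0, 0.0, -self.load_approach])

    def meniscus_shift(self, comp: str, condition: LoadCondition) -> np.ndarray:
        if condition.label == "unloaded":
            return np.zeros(3)
        return self.meniscus_radial_shift * self.outward_direction(comp)

    def perturbation(self, condition: LoadCondition):
        """Rigid transform anatomy -> scanner frame of this acquisition."""
        if condition.label == "unloaded":
            return np.eye(3), np.zeros(3)
        R = rotation_matrix(self.rigid_perturbation_axis, self.rigid_perturbation_deg)
        return R, np.asarray(self.rigid_perturbation_translation, float)

    def loaded_gap(self, comp: str, condition: LoadCondition) -> float:
        """Minimal cartilage-to-cartilage gap of one compartment."""
        R, t = self.femur_transform(condition)
        c = R @ self.condyle_center(comp) + t
        return float(c[2] - self.effective_radius(comp))

    def validate(self):
        s = self
        pos = {
            "condyle_radius_medial": s.condyle_radius_medial,
            "condyle_radius_lateral": s.condyle_radius_lateral,
            "cartilage_thickness_femoral": s.cartilage_thickness_femoral,
            "cartilage_thickness_tibial": s.cartilage_thickness_tibial,
            "meniscus_inner_radius": s.meniscus_inner_radius,
            "meniscus_outer_radius": s.meniscus_outer_radius,
            "meniscus_height": s.meniscus_height,
            "meniscus_arc_span": s.meniscus_arc_span,
        }
        for k, v in pos.items():
            if v <= 0:
                raise PhantomError(f"{k} must be strictly positive (got {v})")
        if s.meniscus_outer_radius <= s.meniscus_inner_radius:
            raise PhantomError("meniscus_outer_radius must exceed meniscus_inner_radius")
        if s.plateau_gap_medial < 0 or s.plateau_gap_lateral < 0:
            raise PhantomError("plateau gaps must be >= 0")
        sp = np.asarray(s.voxel_spacing, float)
        if np.any(sp <= 0) or np.any(sp > 2):
            raise PhantomError("voxel_spacing components must lie in (0, 2] mm")
        if s.load_approach < 0 or s.meniscus_radial_shift < 0:
            raise PhantomError("load response parameters must be >= 0")
        for comp in COMPARTMENTS:
            g = s.loaded_gap(comp, LOADED)
            if g < -1e-12:  # touching (g = 0) is allowed
                raise PhantomError(
                    f"interpenetrating geometry: loaded {comp} cartilage gap "
                    f"{g:.3f} mm <= 0 (load_approach/adduction too large for "
                    f"plateau_gap_{comp})"
                )
        for comp in COMPARTMENTS:
            h_in = s.meniscus_top_height(comp, s.meniscus_inner_radius)
            if h_in <= 0.5:
                raise PhantomError(
                    f"{comp} meniscus inner rim height {h_in:.2f} mm too small; "
                    "reduce meniscus_inner_radius or meniscus_femoral_gap"
                )
        reach = s.meniscus_outer_radius + s.meniscus_radial_shift
        if reach + 1.0 > s.facet_radius("lateral") + 1e-9:
            raise PhantomError(
                "shifted meniscus footprint (+1 mm band) exceeds the tibial "
                f"cartilage facet (reach {reach + 1.0:.1f} > "
                f"{s.facet_radius('lateral')} mm)"
            )


# ---------------------------------------------------------------------------
# closed-form sphere-on-plane contact areas (the cartilage-cartilage oracle)
# ---------------------------------------------------------------------------

def sphere_plane_contact_area(
    R_eff: float, gap: float, threshold: float, side: str = "mean"
) -> float:
    """Exact contact area for a sphere of radius ``R_eff`` above a plane.

    Under the Euclidean criterion (surface points strictly within
    ``threshold`` of the other surface): the plane-side patch is the disc
    ``pi*((R+t)^2 - (R+g)^2)`` and the sphere-side patch is the spherical cap
    ``2*pi*R*(t-g)``; ``side`` selects 'plane', 'sphere' or their arithmetic
    'mean' (the bidirectional average the pipeline reports).
    """
    g = threshold - gap
    if g <= 0:
        return 0.0
    plane = np.pi * ((R_eff + threshold) ** 2 - (R_eff + gap) ** 2)
    sphere = 2.0 * np.pi * R_eff * g
    return {"plane": plane, "sphere": sphere, "mean": 0.5 * (plane + sphere)}[side]


def sphere_plane_area_small_gap(R_eff: float, gap: float, threshold: float) -> float:
    """First-order (projected-cap) approximation ``pi*(2*R*g' - g'^2)``.

    Classic small-penetration formula; underestimates the exact Euclidean
    areas by O(threshold/R) (2-5% for knee-scale radii at 1 mm).
    """
    g = max(threshold - gap, 0.0)
    return np.pi * (2.0 * R_eff * g - g * g)


# ---------------------------------------------------------------------------
# fine analytic meshes (ground-truth surfaces, quadrature and contour source)
# ---------------------------------------------------------------------------

def _grid_faces(ni: int, nj: int, wrap_j: bool = False) -> np.ndarray:
    """Triangle faces of an (ni, nj) vertex grid."""
    i = np.arange(ni - 1)[:, None]
    j = np.arange(nj if wrap_j else nj - 1)[None, :]
    jp = (j + 1) % nj if wrap_j else j + 1
    v00 = i * nj + j
    v01 = i * nj + jp
    v10 = (i + 1) * nj + j
    v11 = (i + 1) * nj + jp
    f1 = np.stack(np.broadcast_arrays(v00, v01, v11), axis=-1).reshape(-1, 3)
    f2 = np.stack(np.broadcast_arrays(v00, v11, v10), axis=-1).reshape(-1, 3)
    return np.vstack([f1, f2])


def _weld(vertices: np.ndarray, faces: np.ndarray) -> trimesh.Trimesh:
    m = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    m.merge_vertices(merge_tex=True, merge_norm=True)
    m.update_faces(m.nondegenerate_faces())
    return m


def femoral_shell_mesh(spec: PhantomSpec, comp: str, res: float = 0.25) -> trimesh.Trimesh:
    """Spherical cartilage shell of one condyle (outer + inner + rim)."""
    c = spec.condyle_center(comp)
    R_out = spec.effective_radius(comp)
    R_in = spec.bone_radius(comp)
    cap = np.deg2rad(spec.cartilage_cap_deg)

    nph = max(16, int(np.ceil(2 * np.pi * R_out / res)))

    def sphere_patch(R):
        nth = max(8, int(np.ceil(cap * R / res)))
        th = np.linspace(0.0, cap, nth + 1)[1:]  # skip the pole ring
        ph = np.linspace(0.0, 2 * np.pi, nph, endpoint=False)
        T, P = np.meshgrid(th, ph, indexing="ij")
        # theta measured from the downward (-z) axis
        v = np.stack(
            [
                R * np.sin(T) * np.cos(P),
                R * np.sin(T) * np.sin(P),
                -R * np.cos(T),
            ],
            axis=-1,
        ).reshape(-1, 3)
        faces = _grid_faces(nth, nph, wrap_j=True)
        pole = np.array([[0.0, 0.0, -R]])
        verts = np.vstack([v, pole])
        pid = len(verts) - 1
        ring0 = np.arange(nph)
        fan = np.stack(
            [np.full(nph, pid), ring0, np.roll(ring0, -1)], axis=1
        )
        return verts, np.vstack([faces, fan]), nth

    vo, fo, ntho = sphere_patch(R_out)
    vi, fi, nthi = sphere_patch(R_in)
    verts = np.vstack([vo, vi])
    # inner patch flipped so normals point out of the solid shell
    faces = [fo, fi[:, ::-1] + len(vo)]
    # rim: join the two theta = cap boundary rings (identical phi sampling)
    ring_o = (ntho - 1) * nph + np.arange(nph)
    ring_i = len(vo) + (nthi - 1) * nph + np.arange(nph)
    rp = np.roll(np.arange(nph), -1)
    faces.append(np.stack([ring_o, ring_o[rp], ring_i[rp]], axis=1))
    faces.append(np.stack([ring_o, ring_i[rp], ring_i], axis=1))
    out = _weld(verts + c, np.vstack(faces))
    if out.volume < 0:
        out.invert()
    return out


def meniscus_mesh(spec: PhantomSpec, comp: str, res: float = 0.25) -> trimesh.Trimesh:
    """Wedge-profile annular sector solid about the condyle axis (unshifted)."""
    ax = spec.condyle_axis(comp)
    r1, r2 = spec.meniscus_inner_radius, spec.meniscus_outer_radius
    span = np.deg2rad(spec.meniscus_arc_span)
    phi0 = spec.meniscus_center_azimuth(comp)
    nr = max(6, int(np.ceil((r2 - r1) / res)))
    nph = max(16, int(np.ceil(span * r2 / res)))
    r = np.linspace(r1, r2, nr + 1)
    ph = phi0 + np.linspace(-span / 2, span / 2, nph + 1)
    Rg, Pg = np.meshgrid(r, ph, indexing="ij")
    X = ax[0] + Rg * np.cos(Pg)
    Y = ax[1] + Rg * np.sin(Pg)
    Htop = spec.meniscus_top_height(comp, Rg)

    top = np.stack([X, Y, Htop], axis=-1).reshape(-1, 3)
    bot = np.stack([X, Y, np.zeros_like(Htop)], axis=-1).reshape(-1, 3)
    ft = _grid_faces(nr + 1, nph + 1)
    parts = [
        (top, ft),
        (bot, ft[:, ::-1]),
    ]

    nz = max(2, int(np.ceil(spec.meniscus_height / res)))

    def wall(p_top, p_bot, flip):
        # vertical wall between a top edge polyline and its bottom
        # projection, subdivided in height so faces stay near `res`-sized
        f01 = np.linspace(0.0, 1.0, nz + 1)[:, None, None]
        v = (1 - f01) * p_bot[None] + f01 * p_top[None]
        n = len(p_top)
        f = _grid_faces(nz + 1, n)
        return (v.reshape(-1, 3), f[:, ::-1] if flip else f)

    # outer wall (r = r2), inner wall (r = r1), two end walls
    top3 = np.stack([X, Y, Htop], axis=-1)
    bot3 = np.stack([X, Y, np.zeros_like(Htop)], axis=-1)
    parts.append(wall(top3[-1], bot3[-1], flip=False))
    parts.append(wall(top3[0], bot3[0], flip=True))
    parts.append(wall(top3[:, 0], bot3[:, 0], flip=False))
    parts.append(wall(top3[:, -1], bot3[:, -1], flip=True))

    verts, faces = [], []
    off = 0
    for v, f in parts:
        verts.append(v.reshape(-1, 3))
        faces.append(np.asarray(f) + off)
        off += len(verts[-1])
    mesh = _weld(np.vstack(verts), np.vstack(faces))
    if mesh.volume < 0:
        mesh.invert()
    return mesh


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Analytic reference for one generated phantom acquisition."""

    condition: str
    areas: dict  # (condition, interface, compartment) -> mm^2, both conditions
    transform_rotation: np.ndarray  # anatomy -> scanner frame of this acquisition
    transform_translation: np.ndarray
    surfaces: dict = field(default_factory=dict)  # structure -> Surface (this acquisition)
    gaps: dict = field(default_factory=dict)  # (condition, compartment) -> cc gap mm
    threshold: float = 1.0


def _meniscus_closed_form_mt(spec: PhantomSpec, threshold: float) -> float:
    """Mean meniscotibial area: offset-footprint closed form (per meniscus).

    Tibial side: the t-neighbourhood of the simple footprint region,
    ``A + P*t + pi*t^2`` (valid for t below the inner radius and wall
    heights); meniscal side: bottom face plus the wall band, ``A + P*t``.
    """
    t = threshold
    r1, r2 = spec.meniscus_inner_radius, spec.meniscus_outer_radius
    span = np.deg2rad(spec.meniscus_arc_span)
    A = 0.5 * span * (r2 ** 2 - r1 ** 2)
    P = span * (r1 + r2) + 2.0 * (r2 - r1)
    tibial = A + P * t + np.pi * t * t
    menisc = A + P * t
    return 0.5 * (tibial + menisc)


def _quadrature_mf(
    spec: PhantomSpec,
    comp: str,
    condition: LoadCondition,
    threshold: float,
    res: float = 0.2,
    meshes: dict | None = None,
) -> float:
    """Mean meniscofemoral area by dense quadrature on the true geometry.

    Meniscal side: fine-mesh faces of the meniscus within threshold of the
    femoral outer sphere (exact point-to-sphere distances).  Femoral side:
    fine shell faces within threshold of the meniscus fine mesh.
    """
    from .contact import _TriangleDistanceIndex

    meshes = meshes if meshes is not None else {}
    key = ("meniscus", comp)
    if key not in meshes:
        meshes[key] = meniscus_mesh(spec, comp, res)
    men = meshes[key]
    shift = spec.meniscus_shift(comp, condition)
    Rf, tf = spec.femur_transform(condition)
    c = Rf @ spec.condyle_center(comp) + tf
    R_eff = spec.effective_radius(comp)

    mv = men.vertices + shift
    tri = mv[men.faces]
    cent = tri.mean(axis=1)
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    d = np.linalg.norm(cent - c, axis=1) - R_eff
    men_area = float(areas[np.abs(d) < threshold].sum())

    key2 = ("shell", comp)
    if key2 not in meshes:
        meshes[key2] = femoral_shell_mesh(spec, comp, res)
    shell = meshes[key2]
    sv = shell.vertices @ Rf.T + tf
    tri_s = sv[shell.faces]
    cent_s = tri_s.mean(axis=1)
    areas_s = 0.5 * np.linalg.norm(
        np.cross(tri_s[:, 1] - tri_s[:, 0], tri_s[:, 2] - tri_s[:, 0]), axis=1
    )
    # cull shell faces outside the meniscus's cylindrical extent (+margin)
    ax2 = spec.condyle_axis(comp) + shift[:2]
    margin = 2.0 * threshold
    rr = np.hypot(cent_s[:, 0] - ax2[0], cent_s[:, 1] - ax2[1])
    near = (
        (rr > spec.meniscus_inner_radius - margin)
        & (rr < spec.meniscus_outer_radius + margin)
        & (cent_s[:, 2] > -margin)
        & (cent_s[:, 2] < spec.meniscus_height + margin)
    )
    idx = _TriangleDistanceIndex(Surface(mv, men.faces))
    dist, _ = idx.query(cent_s[near], max_distance=threshold)
    shell_area = float(areas_s[near][dist < threshold].sum())
    return 0.5 * (men_area + shell_area)


def analytic_contact_area(
    spec: PhantomSpec,
    condition: LoadCondition,
    threshold: float = 1.0,
    meshes: dict | None = None,
    resolution: float = 0.2,
) -> dict:
    """Ground-truth contact areas (mm^2) per interface and compartment.

    Cartilage-cartilage and meniscotibial interfaces use exact closed forms;
    meniscofemoral uses dense quadrature on the analytic surfaces (the
    curved-on-curved band has no simple closed form once the meniscus is
    displaced).  All areas are non-decreasing in ``threshold`` and degenerate
    gaps return 0.
    """
    if threshold <= 0:
        raise PhantomError("threshold must be > 0")
    out = {}
    for comp in COMPARTMENTS:
        gap = spec.loaded_gap(comp, condition)
        out[("cartilage_cartilage", comp)] = sphere_plane_contact_area(
            spec.effective_radius(comp), gap, threshold
        )
        out[("meniscotibial", comp)] = _meniscus_closed_form_mt(spec, threshold)
        out[("meniscofemoral", comp)] = _quadrature_mf(
            spec, comp, condition, threshold, res=resolution, meshes=meshes
        )
    return out


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _grid_axes(spec: PhantomSpec):
    sp = np.asarray(spec.voxel_spacing, float)
    hx, hy = spec.grid_halfextent
    z0, z1 = spec.grid_zrange
    origin = np.array([-hx, -hy, z0])
    shape = tuple(
        int(np.floor(ext / s))
        for ext, s in zip((2 * hx, 2 * hy, z1 - z0), sp)
    )
    axes = [origin[a] + (np.arange(shape[a]) + 0.5) * sp[a] for a in range(3)]
    return origin, sp, shape, axes


def _structure_sdfs(spec: PhantomSpec, condition: LoadCondition, pts: dict):
    """Approximate signed distances (negative inside) for each structure.

    ``pts`` holds the anatomy-frame coordinates X, Y, Z of the voxel centres
    (the rigid perturbation of the acquisition is already undone).  The
    returned max-of-halfspace compositions are exact near faces, which is
    where the partial-volume ramp lives.
    """
    X, Y, Z = pts["X"], pts["Y"], pts["Z"]
    Rf, tf = spec.femur_transform(condition)
    # femur-local coordinates (undo the load transform)
    q = np.stack([X - tf[0], Y - tf[1], Z - tf[2]], axis=-1) @ Rf
    Xf, Yf, Zf = q[..., 0], q[..., 1], q[..., 2]

    sdf = {}
    femur_parts = []
    shell_parts = []
    for comp in COMPARTMENTS:
        c = spec.condyle_center(comp)
        dr = np.sqrt((Xf - c[0]) ** 2 + (Yf - c[1]) ** 2 + (Zf - c[2]) ** 2)
        femur_parts.append(dr - spec.bone_radius(comp))
        cosang = np.clip((c[2] - Zf) / np.maximum(dr, 1e-12), -1, 1)
        ang = np.arccos(cosang)  # polar angle from the downward axis
        ang_d = (ang - np.deg2rad(spec.cartilage_cap_deg)) * np.maximum(dr, 1e-12)
        shell_parts.append(
            np.maximum.reduce(
                [dr - spec.effective_radius(comp), spec.bone_radius(comp) - dr, ang_d]
            )
        )
    # connector bar between the condyles, keeping the femur a single body;
    # placed above the cartilage caps' angular extent so it never carves
    # into the shell annulus
    ccm = spec.condyle_center("medial")
    ccl = spec.condyle_center("lateral")
    mid = 0.5 * (ccm + ccl)
    half = 0.5 * abs(ccm[0] - ccl[0])
    rad_c = 1.2
    cap = np.deg2rad(spec.cartilage_cap_deg)
    z_clear = max(
        spec.condyle_center(comp)[2] - np.cos(cap) * spec.effective_radius(comp)
        for comp in COMPARTMENTS
    )
    bar_z = z_clear + rad_c + 0.2
    d_ax = np.sqrt((Yf - mid[1]) ** 2 + (Zf - bar_z) ** 2) - rad_c
    d_len = np.abs(Xf - mid[0]) - half
    femur_parts.append(np.maximum(d_ax, d_len))
    sdf["femur"] = np.minimum.reduce(femur_parts)
    sdf["femoral_cartilage"] = np.minimum.reduce(shell_parts)

    bx, by, depth = spec.tibia_box
    tt = spec.cartilage_thickness_tibial
    sdf["tibia"] = np.maximum.reduce(
        [np.abs(X) - bx, np.abs(Y) - by, Z + tt, -(Z + tt + depth)]
    )
    patch_parts = []
    for comp in COMPARTMENTS:
        ax = spec.condyle_axis(comp)
        rr = np.sqrt((X - ax[0]) ** 2 + (Y - ax[1]) ** 2)
        patch_parts.append(
            np.maximum.reduce([rr - spec.facet_radius(comp), Z, -(Z + tt)])
        )
    sdf["tibial_cartilage"] = np.minimum.reduce(patch_parts)

    for comp in COMPARTMENTS:
        ax2 = spec.condyle_axis(comp) + spec.meniscus_shift(comp, condition)[:2]
        rr = np.sqrt((X - ax2[0]) ** 2 + (Y - ax2[1]) ** 2)
        phi = np.arctan2(Y - ax2[1], X - ax2[0])
        dphi = np.abs(
            (phi - spec.meniscus_center_azimuth(comp) + np.pi) % (2 * np.pi) - np.pi
        )
        htop = spec.meniscus_top_height(comp, np.clip(rr, spec.meniscus_inner_radius,
                                                      spec.meniscus_outer_radius))
        sdf[f"{comp}_meniscus"] = np.maximum.reduce(
            [
                rr - spec.meniscus_outer_radius,
                spec.meniscus_inner_radius - rr,
                -Z,
                Z - htop,
                (dphi - np.deg2rad(spec.meniscus_arc_span) / 2) * np.maximum(rr, 1e-12),
            ]
        )
    return sdf


_PRIORITY = ("femur", "tibia", "femoral_cartilage", "tibial_cartilage",
             "medial_meniscus", "lateral_meniscus")


def rasterize(spec: PhantomSpec, condition: LoadCondition):
    """Label volume and partial-volume grayscale image of one acquisition."""
    origin, sp, shape, axes = _grid_axes(spec)
    Xg, Yg, Zg = np.meshgrid(*axes, indexing="ij")
    Rp, tp = spec.perturbation(condition)
    # scanner -> anatomy coordinates
    P = np.stack([Xg - tp[0], Yg - tp[1], Zg - tp[2]], axis=-1) @ Rp
    pts = {"X": P[..., 0], "Y": P[..., 1], "Z": P[..., 2]}
    sdf = _structure_sdfs(spec, condition, pts)

    labels = np.zeros(shape, dtype=np.int16)
    for name in reversed(_PRIORITY):
        labels[sdf[name] < 0] = LABEL_OF[name]

    levels = dict(zip(STRUCTURES, spec.intensity_levels))
    intens = np.zeros(shape, dtype=np.float64)
    for name in _PRIORITY:
        w = np.clip(0.5 - sdf[name] / spec.edge_ramp, 0.0, 1.0)
        intens += levels[name] * w
    # noise realisation is tied to the subject seed only, so an identity
    # load response reproduces the unloaded acquisition bit for bit
    rng = np.random.default_rng((spec.seed * 2654435761 + 11) % 2**31)
    if spec.noise_sd > 0:
        intens = intens + rng.normal(0.0, spec.noise_sd, size=shape)

    return (
        LabelVolume(labels, sp, origin),
        Image3D(intens.astype(np.float32), sp, origin),
    )


# ---------------------------------------------------------------------------
# contour stacks
# ---------------------------------------------------------------------------

def _assemble_loops(segments: np.ndarray, tol: float = 1e-6) -> list[np.ndarray]:
    """Join unordered 2D section segments into closed polygon loops."""
    if len(segments) == 0:
        return []
    pts = segments.reshape(-1, 2)
    keys = np.round(pts / tol).astype(np.int64)
    _, first, inv = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    coords = pts[first]
    ends = inv.reshape(-1, 2)
    adj: dict[int, list] = {}
    for si, (a, b) in enumerate(ends):
        if a == b:
            continue
        adj.setdefault(int(a), []).append((si, int(b)))
        adj.setdefault(int(b), []).append((si, int(a)))
    used = np.zeros(len(ends), bool)
    loops = []
    for si0 in range(len(ends)):
        a, b = ends[si0]
        if used[si0] or a == b:
            continue
        used[si0] = True
        start, cur = int(a), int(b)
        loop = [start, cur]
        while cur != start:
            step = next(
                ((sj, other) for sj, other in adj.get(cur, []) if not used[sj]),
                None,
            )
            if step is None:
                break
            used[step[0]] = True
            cur = step[1]
            loop.append(cur)
        if cur == start and len(loop) > 3:
            loops.append(coords[np.asarray(loop[:-1])])
    return loops


def _section_stack(
    mesh: trimesh.Trimesh, structure: str, plane: str, coords: np.ndarray
) -> ContourStack:
    """Slice a mesh at the given plane coordinates into closed 2D polygons."""
    axis = ContourStack._NORMAL_AXIS[plane]
    ua, va = ContourStack._INPLANE_AXES[plane]
    normal = np.zeros(3)
    normal[axis] = 1.0
    lo, hi = mesh.bounds[:, axis]
    cs = np.asarray([c for c in coords if lo + 1e-6 < c < hi - 1e-6], float)
    if len(cs) == 0:
        return ContourStack(structure, plane, [])
    lines, to_3d, _ = trimesh.intersections.mesh_multiplane(
        mesh, normal * cs[0], normal, cs - cs[0]
    )
    slices = []
    for c, seg2d, M in zip(cs, lines, to_3d):
        polys = []
        for lp in _assemble_loops(np.asarray(seg2d)):
            p3 = lp @ M[:3, :2].T + M[:3, 3]
            polys.append(np.stack([p3[:, ua], p3[:, va]], axis=1))
        if polys:
            slices.append((float(c), polys))
    return ContourStack(structure, plane, slices)


def _tibial_cartilage_stack(spec: PhantomSpec, condition: LoadCondition,
                            coords: np.ndarray, step: float = 0.3) -> ContourStack:
    """Sagittal sections of the two plateau facets.

    The unperturbed acquisition uses exact analytic rectangles; a perturbed
    acquisition sections the (transformed) facet solids like any other mesh.
    """
    Rp, tp = spec.perturbation(condition)
    tt = spec.cartilage_thickness_tibial
    if np.allclose(Rp, np.eye(3)) and np.allclose(tp, 0):
        slices = []
        for x0 in coords:
            polys = []
            for comp in COMPARTMENTS:
                ax = spec.condyle_axis(comp)
                r = spec.facet_radius(comp)
                dx = x0 - ax[0]
                if abs(dx) >= r - 1e-9:
                    continue
                w = np.sqrt(r * r - dx * dx)
                ys = np.append(np.arange(ax[1] - w, ax[1] + w, step), ax[1] + w)
                top = np.stack([ys, np.zeros_like(ys)], axis=1)
                bot = np.stack([ys[::-1], np.full_like(ys, -tt)], axis=1)
                polys.append(np.vstack([top, bot]))
            if polys:
                slices.append((float(x0), polys))
        return ContourStack("tibial_cartilage", "sagittal", slices)

    parts = []
    for comp in COMPARTMENTS:
        ax = spec.condyle_axis(comp)
        r = spec.facet_radius(comp)
        th = np.arange(0.0, 2 * np.pi, step / r)
        circ = np.stack(
            [ax[0] + r * np.cos(th), ax[1] + r * np.sin(th), np.zeros_like(th)],
            axis=1,
        )
        parts.append(_weld(*_extrude_rings(circ, circ + np.array([0, 0, -tt]))))
    mesh = trimesh.util.concatenate(parts)
    mesh.apply_transform(_hom(Rp, tp))
    return _section_stack(mesh, "tibial_cartilage", "sagittal", coords)


def _extrude_rings(top: np.ndarray, bot: np.ndarray):
    n = len(top)
    verts = np.vstack([top, bot])
    wall = _grid_faces(2, n, wrap_j=True)
    # caps by fanning (the facet is convex)
    fan_top = np.stack(
        [np.zeros(n - 2, int), np.arange(1, n - 1), np.arange(2, n)], axis=1
    )
    fan_bot = fan_top[:, ::-1] + n
    return verts, np.vstack([wall, fan_top, fan_bot])


def _hom(R, t):
    M = np.eye(4)
    M[:3, :3] = R
    M[:3, 3] = t
    return M


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def make_phantom(
    spec: PhantomSpec,
    condition: LoadCondition,
    mesh_res: float = 0.25,
    with_image: bool = True,
    with_truth_areas: bool = True,
    truth_resolution: float = 0.2,
):
    """Generate one acquisition of the synthetic knee.

    Returns ``(labels, image, contour_stacks, ground_truth)``: a 7-label
    volume, a grayscale image with partial-volume edge profiles, per-slice
    contour stacks (cartilage sagittal, menisci coronal — standing in for
    manual delineation), and the analytic ground truth.  Identical spec and
    seed give bitwise-identical output.
    """
    spec.validate()
    labels, image = rasterize(spec, condition) if with_image else (None, None)
    origin, sp, shape, axes = _grid_axes(spec)

    Rp, tp = spec.perturbation(condition)
    Rf, tf = spec.femur_transform(condition)
    M_pert = _hom(Rp, tp)

    meshes = {}
    stacks = {}
    surfaces = {}
    xs, ys = axes[0], axes[1]
    for comp in COMPARTMENTS:
        shell = femoral_shell_mesh(spec, comp, mesh_res)
        shell.apply_transform(M_pert @ _hom(Rf, tf))
        meshes[("shell", comp)] = shell
        men = meniscus_mesh(spec, comp, mesh_res)
        men.apply_transform(M_pert @ _hom(np.eye(3), spec.meniscus_shift(comp, condition)))
        meshes[("men", comp)] = men
        surfaces[f"{comp}_meniscus"] = Surface.from_trimesh(
            men, f"{comp}_meniscus", provenance="analytic"
        )
        stacks[f"{comp}_meniscus"] = _section_stack(
            men, f"{comp}_meniscus", "coronal", ys
        )
    fc = trimesh.util.concatenate(
        [meshes[("shell", "medial")], meshes[("shell", "lateral")]]
    )
    surfaces["femoral_cartilage"] = Surface.from_trimesh(
        fc, "femoral_cartilage", provenance="analytic"
    )
    stacks["femoral_cartilage"] = _section_stack(fc, "femoral_cartilage", "sagittal", xs)
    stacks["tibial_cartilage"] = _tibial_cartilage_stack(spec, condition, xs)

    area_meshes = {}
    areas = {}
    gaps = {}
    for cond in (UNLOADED, LOADED):
        if with_truth_areas:
            a = analytic_contact_area(
                spec, cond, meshes=area_meshes, resolution=truth_resolution
            )
            for (itf, comp), v in a.items():
                areas[(cond.label, itf, comp)] = v
        for comp in COMPARTMENTS:
            gaps[(cond.label, comp)] = spec.loaded_gap(comp, cond)

    truth = GroundTruth(
        condition=condition.label,
        areas=areas,
        transform_rotation=Rp,
        transform_translation=tp,
        surfaces=surfaces,
        gaps=gaps,
    )
    return labels, image, stacks, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def cohort_specs(n: int, seed: int, base: PhantomSpec | None = None) -> list[PhantomSpec]:
    """Per-subject phantom specs with anatomically plausible variation."""
    base = base or PhantomSpec()
    rng = np.random.default_rng(seed % 2**31)
    out = []
    for i in range(n):
        u = lambda lo, hi: float(rng.uniform(lo, hi))
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        out.append(
            replace(
                base,
                condyle_radius_medial=base.condyle_radius_medial * u(0.94, 1.06),
                condyle_radius_lateral=base.condyle_radius_lateral * u(0.94, 1.06),
                cartilage_thickness_femoral=base.cartilage_thickness_femoral * u(0.9, 1.1),
                cartilage_thickness_tibial=base.cartilage_thickness_tibial * u(0.9, 1.1),
                plateau_gap_medial=base.plateau_gap_medial * u(0.85, 1.15),
                plateau_gap_lateral=base.plateau_gap_lateral * u(0.85, 1.15),
                meniscus_inner_radius=base.meniscus_inner_radius * u(0.95, 1.05),
                meniscus_outer_radius=base.meniscus_outer_radius * u(0.97, 1.03),
                meniscus_arc_span=base.meniscus_arc_span + u(-12, 12),
                load_approach=base.load_approach * u(0.8, 1.2),
                load_adduction_deg=base.load_adduction_deg * u(0.8, 1.2),
                meniscus_radial_shift=base.meniscus_radial_shift * u(0.8, 1.2),
                rigid_perturbation_deg=u(0.5, 3.0),
                rigid_perturbation_axis=tuple(axis),
                rigid_perturbation_translation=tuple(rng.uniform(-1.5, 1.5, 3)),
                seed=int((seed * 9176 + 31 * i + 7) % 2**31),
            )
        )
    return out


def cohort_truth_areas(
    specs: list[PhantomSpec],
    with_load_effect: bool = True,
    resolution: float = 0.35,
) -> list[dict]:
    """Per-subject analytic areas for both conditions (no imaging, no noise)."""
    out = []
    for s in specs:
        meshes = {}
        per = {}
        for cond in (UNLOADED, LOADED):
            geom_cond = cond if with_load_effect else UNLOADED
            per[cond.label] = analytic_contact_area(
                s, geom_cond, meshes=meshes, resolution=resolution
            )
        out.append(per)
    return out


def simulate_cohort_tables(
    n: int,
    seed: int,
    base: PhantomSpec | None = None,
    with_load_effect: bool = True,
    measurement_cv: float = 0.05,
    resolution: float = 0.35,
    truth: list[dict] | None = None,
):
    """Lightweight cohort of contact-area tables from the analytic oracle.

    Bypasses imaging: per-subject geometry variation plus independent
    multiplicative lognormal measurement noise on the analytic areas.  With
    ``with_load_effect=False`` both conditions share the unloaded geometry
    (a null cohort for calibration studies).  A precomputed ``truth`` (from
    :func:`cohort_truth_areas` on the same specs) lets replicate studies
    redraw only the measurement noise.
    """
    from .contact import ContactAreaTable

    specs = cohort_specs(n, seed, base)
    if truth is None:
        truth = cohort_truth_areas(specs, with_load_effect, resolution)
    rng = np.random.default_rng((seed * 7919 + 13) % 2**31)
    tables = []
    for i in range(n):
        tab = ContactAreaTable(subject=f"sim{i:02d}")
        for cond in (UNLOADED, LOADED):
            for (itf, comp), v in truth[i][cond.label].items():
                noise = float(np.exp(rng.normal(0.0, measurement_cv)))
                tab.areas[(cond.label, itf, comp)] = v * noise
        tables.append(tab)
    return tables
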