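"""Distance-threshold contact areas between structure surfaces.

The contact area between two structures is the region of one surface lying
within a Euclidean distance threshold (default 1 mm, strict ``<``) of the
other.  Distances are evaluated at face centroids against the *surface* of
the partner (exact point-to-triangle, not vertex-to-vertex), the patch area
is the sum of the included face areas, and the two directions of each
interface are averaged arithmetically.  A logged QC record flags interfaces
whose two directional areas disagree by more than ``bilateral_tolerance``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import Surface

INTERFACES = ("cartilage_cartilage", "meniscofemoral", "meniscotibial")
COMPARTMENTS = ("medial", "lateral")


class ContactError(ValueError):
    pass


@dataclass
class ContactConfig:
    threshold: float = 1.0  # mm, strict less-than
    bilateral_tolerance: float = 0.20  # relative area mismatch that trips QC

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if not (0 < self.bilateral_tolerance < 1):
            raise ValueError("bilateral_tolerance must be in (0, 1)")


# ---------------------------------------------------------------------------
# point-to-triangle kernel (Eberly's region decomposition, vectorised)
# ---------------------------------------------------------------------------

def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray):
    """Closest point on triangle i to point i, for paired arrays.

    Parameters are ``points`` (n, 3) and ``triangles`` (n, 3, 3); returns
    ``(closest (n, 3), dist (n,))``.
    """
    p = np.asarray(points, float)
    tri = np.asarray(triangles, float)
    b = tri[:, 0]
    e0 = tri[:, 1] - b
    e1 = tri[:, 2] - b
    d = b - p
    a00 = np.einsum("ij,ij->i", e0, e0)
    a01 = np.einsum("ij,ij->i", e0, e1)
    a11 = np.einsum("ij,ij->i", e1, e1)
    b0 = np.einsum("ij,ij->i", e0, d)
    b1 = np.einsum("ij,ij->i", e1, d)
    det = np.maximum(a00 * a11 - a01 * a01, 1e-300)
    s = a01 * b1 - a11 * b0
    t = a01 * b0 - a00 * b1

    s_out = np.empty_like(s)
    t_out = np.empty_like(t)

    def clamp01(x):
        return np.minimum(np.maximum(x, 0.0), 1.0)

    safe = np.maximum
    inside = (s + t <= det) & (s >= 0) & (t >= 0)
    s_out[inside] = (s / det)[inside]
    t_out[inside] = (t / det)[inside]

    # edge/vertex regions
    denom = safe(a00 - 2 * a01 + a11, 1e-300)

    r3 = (s + t <= det) & (s < 0) & (t >= 0)  # edge s=0
    t3 = clamp01(-b1 / safe(a11, 1e-300))
    s_out[r3], t_out[r3] = 0.0, t3[r3]

    r5 = (s + t <= det) & (s >= 0) & (t < 0)  # edge t=0
    s5 = clamp01(-b0 / safe(a00, 1e-300))
    s_out[r5], t_out[r5] = s5[r5], 0.0

    r4 = (s + t <= det) & (s < 0) & (t < 0)  # corner at b
    use_s = b0 < 0
    s4 = np.where(use_s, clamp01(-b0 / safe(a00, 1e-300)), 0.0)
    t4 = np.where(use_s, 0.0, clamp01(-b1 / safe(a11, 1e-300)))
    s_out[r4], t_out[r4] = s4[r4], t4[r4]

    r1 = (s + t > det) & (s >= 0) & (t >= 0)  # edge s+t=1
    numer = (a11 + b1) - (a01 + b0)
    s1 = clamp01(numer / denom)
    s_out[r1], t_out[r1] = s1[r1], (1.0 - s1)[r1]

    r2 = (s + t > det) & (s < 0)  # corner at e1 end
    tmp = (a01 + b0) - (a11 + b1)
    on_edge = tmp < 0
    s2 = np.where(on_edge, clamp01(-tmp / denom), 0.0)
    t2 = np.where(on_edge, 1.0 - s2, clamp01(-b1 / safe(a11, 1e-300)))
    s_out[r2], t_out[r2] = s2[r2], t2[r2]

    r6 = (s + t > det) & (s >= 0) & (t < 0)  # corner at e0 end
    tmp6 = (a01 + b1) - (a00 + b0)
    on_edge6 = tmp6 < 0
    t6 = np.where(on_edge6, clamp01(-tmp6 / denom), 0.0)
    s6 = np.where(on_edge6, 1.0 - t6, clamp01(-b0 / safe(a00, 1e-300)))
    s_out[r6], t_out[r6] = s6[r6], t6[r6]

    closest = b + s_out[:, None] * e0 + t_out[:, None] * e1
    dist = np.linalg.norm(closest - p, axis=1)
    return closest, dist


def _split_oversized(tri: np.ndarray, max_iter: int = 12) -> np.ndarray:
    """Longest-edge bisection of triangles much larger than the median.

    The union of the pieces is the original surface, so distances are
    unchanged; bounding the circumradius keeps the KD-tree candidate balls
    small when a mesh mixes fine strips with large cap triangles.
    """
    cent = tri.mean(axis=1)
    radii = np.linalg.norm(tri - cent[:, None, :], axis=2).max(axis=1)
    target = max(1.5 * float(np.median(radii)), 1e-9)
    for _ in range(max_iter):
        big = radii > target
        if not big.any():
            break
        keep = tri[~big]
        t = tri[big]
        e = np.stack(
            [t[:, 1] - t[:, 0], t[:, 2] - t[:, 1], t[:, 0] - t[:, 2]], axis=1
        )
        longest = np.argmax(np.linalg.norm(e, axis=2), axis=1)
        i0 = longest
        i1 = (longest + 1) % 3
        i2 = (longest + 2) % 3
        n = len(t)
        rows = np.arange(n)
        a, b, c = t[rows, i0], t[rows, i1], t[rows, i2]
        m = 0.5 * (a + b)
        child1 = np.stack([a, m, c], axis=1)
        child2 = np.stack([m, b, c], axis=1)
        tri = np.concatenate([keep, child1, child2])
        cent = tri.mean(axis=1)
        radii = np.linalg.norm(tri - cent[:, None, :], axis=2).max(axis=1)
    return tri


class _TriangleDistanceIndex:
    """Exact nearest point-to-triangle queries via centroid-KDTree pruning.

    A candidate triangle can only beat the current best if its centroid lies
    within (best distance + its circumradius) of the query point, so a query
    against the nearest centroid gives an upper bound and a ball query of
    radius (bound + max circumradius) encloses all possible minimisers.
    """

    def __init__(self, surface: Surface):
        tri = surface.triangles()
        keep = surface.face_areas() > 1e-12
        tri = tri[keep]
        if len(tri) == 0:
            raise ContactError("target surface has no non-degenerate faces")
        self.triangles = _split_oversized(tri)
        self.centroids = self.triangles.mean(axis=1)
        self.radii = np.linalg.norm(
            self.triangles - self.centroids[:, None, :], axis=2
        ).max(axis=1)
        self.r_max = float(self.radii.max())
        self.tree = cKDTree(self.centroids)

    def query(self, points: np.ndarray, max_distance: float | None = None):
        """Distances (and closest points) from each point to the surface.

        With ``max_distance`` set, points whose distance provably exceeds it
        are returned as ``inf`` (their closest point is NaN); all reported
        finite distances are exact.
        """
        points = np.atleast_2d(np.asarray(points, float))
        n = len(points)
        dist = np.full(n, np.inf)
        closest = np.full((n, 3), np.nan)

        d_c1, _ = self.tree.query(points)
        if max_distance is None:
            active = np.arange(n)
        else:
            active = np.nonzero(d_c1 - self.r_max <= max_distance)[0]
            if len(active) == 0:
                return dist, closest

        k = min(24, len(self.triangles))
        for start in range(0, len(active), 65536):
            sl = active[start : start + 65536]
            pts = points[sl]
            d_c, idx = self.tree.query(pts, k=k)
            d_c = np.atleast_2d(d_c)
            idx = np.atleast_2d(idx)
            m = len(pts)
            cp, dd = closest_point_on_triangles(
                np.repeat(pts, k, axis=0), self.triangles[idx.ravel()]
            )
            dd = dd.reshape(m, k)
            cp = cp.reshape(m, k, 3)
            j = np.argmin(dd, axis=1)
            best = dd[np.arange(m), j]
            dist[sl] = best
            closest[sl] = cp[np.arange(m), j]

            # a triangle outside the k candidates has centroid distance
            # >= d_c[:, -1], hence surface distance >= d_c[:, -1] - r_max
            bound = d_c[:, -1] - self.r_max
            unresolved = best > bound
            if max_distance is not None:
                unresolved &= bound <= max_distance

            # widen to k2 candidates for the unresolved points in one
            # vectorised round; only stragglers reach the per-point loop
            k2 = min(128, len(self.triangles))
            if k2 > k and unresolved.any():
                ui = np.nonzero(unresolved)[0]
                d_c2, idx2 = self.tree.query(pts[ui], k=k2)
                d_c2 = np.atleast_2d(d_c2)
                idx2 = np.atleast_2d(idx2)
                cp2, dd2 = closest_point_on_triangles(
                    np.repeat(pts[ui], k2, axis=0), self.triangles[idx2.ravel()]
                )
                dd2 = dd2.reshape(len(ui), k2)
                cp2 = cp2.reshape(len(ui), k2, 3)
                j2 = np.argmin(dd2, axis=1)
                b2 = dd2[np.arange(len(ui)), j2]
                better = b2 < best[ui]
                dist[sl[ui[better]]] = b2[better]
                closest[sl[ui[better]]] = cp2[np.arange(len(ui)), j2][better]
                best[ui] = np.minimum(best[ui], b2)
                bound2 = d_c2[:, -1] - self.r_max
                still = best[ui] > bound2
                if max_distance is not None:
                    still &= bound2 <= max_distance
                unresolved[:] = False
                unresolved[ui[still]] = True

            for i in np.nonzero(unresolved)[0]:
                r = min(best[i], np.inf if max_distance is None else max_distance)
                cand = self.tree.query_ball_point(pts[i], r + self.r_max + 1e-12)
                if not cand:
                    continue
                cpi, ddi = closest_point_on_triangles(
                    np.broadcast_to(pts[i], (len(cand), 3)),
                    self.triangles[np.asarray(cand)],
                )
                jj = np.argmin(ddi)
                if ddi[jj] < dist[sl[i]]:
                    dist[sl[i]] = ddi[jj]
                    closest[sl[i]] = cpi[jj]

        if max_distance is not None:
            over = dist > max_distance
            dist[over] = np.inf
            closest[over] = np.nan
        return dist, closest


def _check_quantitative(*surfaces: Surface):
    for s in surfaces:
        if s.visualization_only:
            raise ContactError(
                f"surface '{s.structure}' is smoothed for visualization only; "
                "quantitative contact analysis requires the unsmoothed surface"
            )
        if s.n_faces == 0:
            raise ContactError(f"surface '{s.structure}' is empty")


def nearest_distance(
    source: Surface,
    target: Surface,
    max_distance: float | None = None,
    return_points: bool = False,
):
    """Exact Euclidean distance from each source face centroid to the target.

    Distances are point-to-triangle against every target face (accelerated by
    a KD-tree with exact pruning).  With ``max_distance``, distances beyond it
    are reported as ``inf`` but all finite values remain exact.
    """
    _check_quantitative(source, target)
    index = _TriangleDistanceIndex(target)
    dist, closest = index.query(source.face_centroids(), max_distance)
    return (dist, closest) if return_points else dist


def nearest_distance_exhaustive(source: Surface, target: Surface) -> np.ndarray:
    """Brute-force all-pairs scan; reference for the accelerated query."""
    _check_quantitative(source, target)
    pts = source.face_centroids()
    tri = target.triangles()
    out = np.full(len(pts), np.inf)
    for j in range(len(tri)):
        _, d = closest_point_on_triangles(pts, np.broadcast_to(tri[j], (len(pts), 3, 3)))
        np.minimum(out, d, out=out)
    return out


# ---------------------------------------------------------------------------
# patches and tables
# ---------------------------------------------------------------------------

@dataclass
class ContactPatch:
    """Faces of ``source`` lying strictly within threshold of ``target``."""

    source: str
    target: str
    face_index: np.ndarray
    area: float
    distances: np.ndarray | None = None  # per-source-face, inf beyond cutoff


def contact_patch(
    source: Surface,
    target: Surface,
    config: ContactConfig | None = None,
    distances: np.ndarray | None = None,
) -> ContactPatch:
    """Contact patch of ``source`` against ``target``.

    Face inclusion uses the strict inequality ``distance < threshold`` (the
    boundary set has measure zero; strictness is fixed for determinism).
    Precomputed ``distances`` (e.g. from a threshold sweep) may be passed in.
    """
    config = config or ContactConfig()
    if distances is None:
        distances = nearest_distance(source, target, max_distance=config.threshold)
    idx = np.nonzero(distances < config.threshold)[0]
    area = float(source.face_areas()[idx].sum())
    return ContactPatch(source.structure, target.structure, idx, area, distances)


@dataclass
class MeanContactArea:
    area: float
    area_ab: float
    area_ba: float
    asymmetry: float
    flagged: bool


def mean_contact_area(
    patch_ab: ContactPatch, patch_ba: ContactPatch, config: ContactConfig | None = None
) -> MeanContactArea:
    """Arithmetic mean of the two directional patch areas of one interface.

    The two areas are expected to be approximately equal; a relative
    difference beyond ``bilateral_tolerance`` is flagged (warning, not error).
    """
    config = config or ContactConfig()
    a, b = patch_ab.area, patch_ba.area
    mean = 0.5 * (a + b)
    asym = abs(a - b) / mean if mean > 0 else 0.0
    flagged = asym > config.bilateral_tolerance
    if flagged:
        warnings.warn(
            f"bilateral contact-area asymmetry {asym:.1%} between "
            f"{patch_ab.source}->{patch_ab.target} and reverse",
            stacklevel=2,
        )
    return MeanContactArea(mean, a, b, asym, flagged)


@dataclass
class ContactAreaTable:
    """Per-subject, per-condition contact areas (mm^2) by interface/compartment."""

    subject: str
    areas: dict = field(default_factory=dict)  # (condition, interface, compartment) -> mm^2
    qc: dict = field(default_factory=dict)  # (condition, interface) -> asymmetry

    def total(self, condition: str, interface: str) -> float:
        return sum(self.areas[(condition, interface, c)] for c in COMPARTMENTS)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject": self.subject,
                "condition": cond,
                "interface": itf,
                "compartment": comp,
                "area_mm2": v,
                "qc_asymmetry": self.qc.get(
                    (cond, f"{itf}_{comp}"), self.qc.get((cond, itf), np.nan)
                ),
            }
            for (cond, itf, comp), v in sorted(self.areas.items())
        ]
        return pd.DataFrame(rows)


_REQUIRED = ("femoral_cartilage", "tibial_cartilage", "medial_meniscus", "lateral_meniscus")


def interface_areas(
    surfaces: dict[str, Surface],
    frame,
    config: ContactConfig | None = None,
    subject: str = "subject",
    condition: str = "unloaded",
    table: ContactAreaTable | None = None,
) -> ContactAreaTable:
    """One condition's row set of the contact-area table.

    cartilage-cartilage is femoral vs tibial cartilage, compartment-split at
    the joint frame's mid-plateau plane; each meniscus contributes only to its
    own compartment's meniscofemoral (vs femoral cartilage) and meniscotibial
    (vs tibial cartilage) rows.  Every interface is measured in both
    directions and bidirectionally averaged.
    """
    from .joint_geometry import split_compartments

    config = config or ContactConfig()
    for name in _REQUIRED:
        if name not in surfaces:
            raise ContactError(f"missing structure for contact analysis: '{name}'")
    for name in ("femoral_cartilage", "tibial_cartilage"):
        if surfaces[name].n_faces == 0:
            raise ContactError(f"empty cartilage surface: '{name}'")
    table = table or ContactAreaTable(subject)

    fc, tc = surfaces["femoral_cartilage"], surfaces["tibial_cartilage"]

    def split_area(surface, patch):
        med, lat = split_compartments(surface.submesh(patch.face_index), frame)
        return med.area, lat.area

    p_ab = contact_patch(fc, tc, config)
    p_ba = contact_patch(tc, fc, config)
    m_ab, l_ab = split_area(fc, p_ab)
    m_ba, l_ba = split_area(tc, p_ba)
    res = mean_contact_area(p_ab, p_ba, config)
    table.areas[(condition, "cartilage_cartilage", "medial")] = 0.5 * (m_ab + m_ba)
    table.areas[(condition, "cartilage_cartilage", "lateral")] = 0.5 * (l_ab + l_ba)
    table.qc[(condition, "cartilage_cartilage")] = res.asymmetry

    for comp in COMPARTMENTS:
        meniscus = surfaces[f"{comp}_meniscus"]
        for itf, cart in (("meniscofemoral", fc), ("meniscotibial", tc)):
            if meniscus.n_faces == 0:  # absent meniscus: zero contact
                table.areas[(condition, itf, comp)] = 0.0
                table.qc[(condition, f"{itf}_{comp}")] = 0.0
                continue
            q_ab = contact_patch(meniscus, cart, config)
            q_ba = contact_patch(cart, meniscus, config)
            res = mean_contact_area(q_ab, q_ba, config)
            table.areas[(condition, itf, comp)] = res.area
            table.qc[(condition, f"{itf}_{comp}")] = res.asymmetry

    return table
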