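"""Surface reconstruction from images, labels and slice-wise contours.

Three reconstruction routes, mirroring how the structures are segmented in
practice:

* bones: marker-based 3D watershed on the spacing-aware gradient magnitude,
  followed by sub-voxel repositioning of the voxel-boundary surface onto the
  half-intensity crossing of the cubically interpolated image (data-driven,
  no mesh smoothing);
* cartilage and menisci: slice-by-slice closed contours (sagittal for
  cartilage, coronal for menisci) stitched into a closed triangle mesh;
* a Gaussian inter-slice smoother for display only — its output is flagged
  ``visualization_only`` and refused by all quantitative operations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.measure import marching_cubes
from skimage.segmentation import watershed as _skimage_watershed

from .core import ContourStack, Image3D, LabelVolume, Surface

log = logging.getLogger(__name__)


@dataclass
class SegmentationConfig:
    visual_sigma: float = 1.25  # mm, inter-slice display smoothing
    gradient_operator: str = "central"  # spacing-aware central differences
    interpolation: str = "cubic"  # intensity interpolation for refinement
    profile_step: float = 0.05  # mm, sampling step along the surface normal
    min_contrast: float = 0.1  # minimum plateau contrast for a valid crossing

    def __post_init__(self):
        if self.visual_sigma <= 0:
            raise ValueError("visual_sigma must be > 0")


@dataclass
class MarkerSet:
    """Seed voxels (index triples) with their structure labels."""

    markers: list  # of ((i, j, k), label:int)

    def validate(self, shape):
        if not self.markers:
            raise ValueError("marker set is empty")
        for ijk, lab in self.markers:
            if not all(0 <= ijk[a] < shape[a] for a in range(3)):
                raise ValueError(f"marker {tuple(ijk)} outside grid of shape {shape}")

    def to_volume(self, shape) -> np.ndarray:
        """Marker volume with labels shifted by +1 (0 = unlabeled)."""
        self.validate(shape)
        vol = np.zeros(shape, dtype=np.int32)
        for ijk, lab in self.markers:
            vol[tuple(int(v) for v in ijk)] = int(lab) + 1
        return vol


def markers_from_labels(
    labels: LabelVolume, structures: tuple[str, ...], erosion_mm: float = 1.5,
    n_per_structure: int = 40, seed: int = 0,
) -> MarkerSet:
    """Seed markers sampled from eroded reference masks.

    Stands in for the interactive step of marking areas inside and outside
    the target bones on several slices.  Every non-target structure
    (including adjacent cartilage and menisci, which lie immediately outside
    the bone) contributes exterior seeds, so the flood settles on the
    bone-tissue ridge rather than leaking through unmarked basins; erosion
    keeps seeds safely interior to their structure.
    """
    rng = np.random.default_rng(seed)
    out = []

    def sample(name, lab, ero_mm, n):
        mask = labels.mask(name)
        it = max(1, int(round(ero_mm / labels.spacing.min())))
        core = ndimage.binary_erosion(mask, iterations=it)
        if not core.any():
            core = mask
        idx = np.argwhere(core)
        take = idx[rng.choice(len(idx), min(n, len(idx)), replace=False)]
        out.extend([(tuple(v), lab) for v in take])

    background = labels.label_names.index("background")
    for name in labels.label_names:
        if name in structures:
            sample(name, labels.label_names.index(name), erosion_mm, n_per_structure)
        elif name == "background":
            sample(name, background, erosion_mm, 2 * n_per_structure)
        else:
            # thin structures: light erosion, exterior label
            sample(name, background, 0.5, n_per_structure)
    return MarkerSet(out)


def gradient_magnitude(image: Image3D) -> np.ndarray:
    g = np.gradient(image.intensities.astype(np.float64), *image.spacing)
    return np.sqrt(g[0] ** 2 + g[1] ** 2 + g[2] ** 2)


def watershed3d(image: Image3D, markers: MarkerSet) -> LabelVolume:
    """Marker-based watershed of the gradient-magnitude relief.

    Floods the spacing-aware gradient magnitude from the seed voxels; region
    boundaries settle on gradient ridges (tissue interfaces).  The result is
    a full partition of the grid (every voxel exactly one label) and is
    deterministic for fixed inputs.
    """
    marker_vol = markers.to_volume(image.shape)
    relief = gradient_magnitude(image)
    labels = _skimage_watershed(relief, markers=marker_vol)
    return LabelVolume(
        (labels - 1).astype(np.int16), image.spacing.copy(), image.origin.copy()
    )


# ---------------------------------------------------------------------------
# sub-voxel surface extraction
# ---------------------------------------------------------------------------

def _voxel_boundary_mesh(labels: LabelVolume, structure: str) -> Surface:
    mask = labels.mask(structure)
    if not mask.any():
        raise ValueError(f"structure '{structure}' absent from label volume")
    padded = np.pad(mask.astype(np.float32), 1)
    verts, faces, _, _ = marching_cubes(
        padded, level=0.5, spacing=tuple(labels.spacing)
    )
    verts = verts - labels.spacing + labels.origin + 0.5 * labels.spacing
    return Surface(verts, faces, structure, provenance="voxel_boundary")


def subvoxel_surface(
    image: Image3D,
    labels: LabelVolume,
    structure: str,
    config: SegmentationConfig | None = None,
) -> Surface:
    """Sub-voxel-accurate surface of a labelled structure.

    The voxel-boundary surface (marching cubes of the label mask) is
    repositioned vertex by vertex along the local normal onto the
    half-intensity crossing of the cubically interpolated image — the point
    where the intensity passes midway between the structure's interior level
    and the surrounding level.  No mesh smoothing is applied; accuracy comes
    from the image's partial-volume edge profile.  Vertices without a
    detectable crossing stay on the voxel boundary and are counted.
    """
    config = config or SegmentationConfig()
    if not labels.same_lattice(image):
        raise ValueError("image and label volume are on different lattices")
    surf = _voxel_boundary_mesh(labels, structure)
    mesh = surf.to_trimesh()
    normals = np.asarray(mesh.vertex_normals, dtype=float)

    # orient normals outward by majority vote against the mask
    mask = labels.mask(structure).astype(np.float32)
    eps = 0.5 * float(labels.spacing.min())
    inner = _sample_volume(mask, image, surf.vertices - eps * normals, order=1)
    outer = _sample_volume(mask, image, surf.vertices + eps * normals, order=1)
    if np.mean(inner - outer) < 0:
        normals = -normals

    L = float(np.linalg.norm(image.spacing))  # one voxel diagonal
    # the profile is sampled over +/- 2 diagonals: the cubic interpolant of
    # an edge settles onto its plateaus only ~2 voxels past the edge, so the
    # level estimate needs the wider window; the vertex move itself stays
    # clamped to +/- one diagonal
    steps = np.arange(-2 * L, 2 * L + 1e-9, config.profile_step)
    pts = surf.vertices[:, None, :] + steps[None, :, None] * normals[:, None, :]
    coeffs = ndimage.spline_filter(image.intensities.astype(np.float64), order=3)
    prof = _sample_volume(coeffs, image, pts.reshape(-1, 3), order=3, prefiltered=True)
    prof = prof.reshape(len(surf.vertices), len(steps))

    # two-pass crossing: a coarse mid-range level locates the edge, then
    # the inside/outside plateau levels are re-estimated from samples away
    # from it (end means or percentiles would sit on the interpolant's edge
    # foot whenever the window is asymmetric about the edge)
    level0 = 0.5 * (prof.min(axis=1) + prof.max(axis=1))
    s0, found0 = _detect_crossing(prof, level0, steps, config.profile_step,
                                  search_limit=L)

    # clear both the partial-volume ramp and the interpolant's settle zone
    margin = 2.0 * float(image.spacing.max())
    d = steps[None, :] - s0[:, None]
    side_in = d < -margin
    side_out = d > margin
    n_in = side_in.sum(axis=1)
    n_out = side_out.sum(axis=1)
    ok = (n_in >= 2) & (n_out >= 2) & found0
    with np.errstate(invalid="ignore"):
        m_in = np.where(ok, (prof * side_in).sum(axis=1) / np.maximum(n_in, 1), np.nan)
        m_out = np.where(ok, (prof * side_out).sum(axis=1) / np.maximum(n_out, 1), np.nan)
    level = np.where(ok, 0.5 * (m_in + m_out), level0)
    contrast = np.where(ok, np.abs(m_in - m_out), prof.max(axis=1) - prof.min(axis=1))

    s, found = _detect_crossing(prof, level, steps, config.profile_step,
                                search_limit=L)
    has_contrast = contrast > config.min_contrast
    found &= has_contrast
    s = np.clip(s, -L, L)

    new_verts = surf.vertices.copy()
    new_verts[found] += s[found, None] * normals[found]
    n_missed = int((~found).sum())
    if n_missed:
        log.info("subvoxel_surface(%s): %d/%d vertices without intensity crossing",
                 structure, n_missed, len(found))
    return Surface(
        new_verts, surf.faces, structure,
        provenance=f"watershed+subvoxel(unmoved={n_missed})",
    )


def _detect_crossing(prof: np.ndarray, level: np.ndarray, steps: np.ndarray,
                     step: float, search_limit: float | None = None):
    """Sign change of (profile - level) nearest the window centre.

    Returns the sub-step crossing position (linear interpolation within the
    bracketing interval) and a found flag per profile; ``search_limit``
    restricts admissible crossings to |position| below it.
    """
    g = prof - level[:, None]
    sign_change = g[:, :-1] * g[:, 1:] <= 0
    if search_limit is not None:
        sign_change &= (np.abs(steps[:-1]) <= search_limit)[None, :]
    mid = (prof.shape[1] - 1) / 2.0
    cols = np.arange(prof.shape[1] - 1)
    penalty = np.where(sign_change, np.abs(cols - mid)[None, :], np.inf)
    best = np.argmin(penalty, axis=1)
    rows = np.arange(len(best))
    found = np.isfinite(penalty[rows, best])
    g0 = g[rows, best]
    g1 = g[rows, best + 1]
    denom = g0 - g1
    frac = np.where(np.abs(denom) > 1e-300, g0 / np.where(denom == 0, 1, denom), 0.5)
    return steps[best] + frac * step, found


def _sample_volume(data, image: Image3D, points_mm, order=3, prefiltered=False):
    idx = image.mm_to_index(points_mm).T
    return ndimage.map_coordinates(
        data, idx, order=order, mode="nearest", prefilter=not prefiltered and order > 1
    )


# ---------------------------------------------------------------------------
# contour-stack meshing
# ---------------------------------------------------------------------------

def _polygon_area2d(p: np.ndarray) -> float:
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _ensure_ccw(p: np.ndarray) -> np.ndarray:
    return p if _polygon_area2d(p) >= 0 else p[::-1]


def _resample_closed(p: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to n points, uniform in arc length."""
    closed = np.vstack([p, p[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    t = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, p.shape[1]))
    for d in range(p.shape[1]):
        out[:, d] = np.interp(t, s, closed[:, d])
    return out


def triangulate_polygon2d(p: np.ndarray) -> np.ndarray:
    """Ear-clipping triangulation of a simple polygon; returns index triples."""
    n = len(p)
    if n < 3:
        return np.empty((0, 3), dtype=np.int64)
    idx = list(range(n)) if _polygon_area2d(p) >= 0 else list(range(n - 1, -1, -1))
    tris = []
    guard = 0
    while len(idx) > 3 and guard < 4 * n * n:
        m = len(idx)
        clipped = False
        for k in range(m):
            guard += 1
            i0, i1, i2 = idx[(k - 1) % m], idx[k], idx[(k + 1) % m]
            a, b, c = p[i0], p[i1], p[i2]
            cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            if cross <= 1e-14:
                continue  # reflex or degenerate corner
            others = np.array([j for j in idx if j not in (i0, i1, i2)])
            if len(others):
                q = p[others]
                d0 = (b[0] - a[0]) * (q[:, 1] - a[1]) - (b[1] - a[1]) * (q[:, 0] - a[0])
                d1 = (c[0] - b[0]) * (q[:, 1] - b[1]) - (c[1] - b[1]) * (q[:, 0] - b[0])
                d2 = (a[0] - c[0]) * (q[:, 1] - c[1]) - (a[1] - c[1]) * (q[:, 0] - c[0])
                if np.any((d0 > 0) & (d1 > 0) & (d2 > 0)):
                    continue
            tris.append((i0, i1, i2))
            idx.pop(k)
            clipped = True
            break
        if not clipped:  # numerically stuck: fan the rest
            break
    if len(idx) >= 3:
        for k in range(1, len(idx) - 1):
            tris.append((idx[0], idx[k], idx[k + 1]))
    return np.asarray(tris, dtype=np.int64)


def _match_polygons(prev: list, nxt: list) -> list[tuple[int, int]]:
    """Greedy nearest-centroid pairing; ties broken larger-area-first."""
    if not prev or not nxt:
        return []
    cp = np.array([np.mean(q, axis=0) for q in prev])
    cn = np.array([np.mean(q, axis=0) for q in nxt])
    ap = np.array([abs(_polygon_area2d(q)) for q in prev])
    pairs = [
        (np.linalg.norm(cp[i] - cn[j]), -ap[i], i, j)
        for i in range(len(prev))
        for j in range(len(nxt))
    ]
    used_p, used_n, out = set(), set(), []
    for _, _, i, j in sorted(pairs):
        if i not in used_p and j not in used_n:
            out.append((i, j))
            used_p.add(i)
            used_n.add(j)
    return out


def _align_phase(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cyclic shift of b minimising summed squared distance to a."""
    n = len(a)
    best, best_cost = 0, np.inf
    # coarse-to-fine search keeps this O(n * n/8)
    for k in range(0, n, max(1, n // 64)):
        cost = float(np.sum((a - np.roll(b, -k, axis=0)) ** 2))
        if cost < best_cost:
            best, best_cost = k, cost
    for k in range(best - max(1, n // 64), best + max(1, n // 64) + 1):
        cost = float(np.sum((a - np.roll(b, -k % n, axis=0)) ** 2))
        if cost < best_cost:
            best, best_cost = k % n, cost
    return np.roll(b, -best, axis=0)


def contours_to_mesh(stack: ContourStack, resample_step: float = 0.35) -> Surface:
    """Closed triangle mesh from a stack of slice-wise closed contours.

    Corresponding contours on adjacent slices (nearest-centroid pairing,
    larger-area-first on ties) are resampled to a common arc-length density,
    phase-aligned and joined by triangle strips; chain ends and unmatched
    contours are capped by ear-clipping.  Branching is resolved by the same
    nearest-centroid rule and logged.
    """
    slices = [(c, [q for q in polys if len(q) >= 3]) for c, polys in stack.slices]
    slices = [(c, polys) for c, polys in slices if polys]
    if len(slices) < 2:
        raise ValueError("contour stack needs at least 2 slices with polygons")

    polys = [[_ensure_ccw(np.asarray(q, float)) for q in p] for _, p in slices]
    coords = [c for c, _ in slices]

    # chains of matched contour indices across slices
    chains = []  # each: list of (slice_idx, poly_idx)
    open_chains: dict[int, list] = {}
    for j in range(len(polys[0])):
        ch = [(0, j)]
        chains.append(ch)
        open_chains[j] = ch
    steps = np.diff(coords)
    max_step = 1.5 * float(np.median(steps)) if len(steps) else np.inf
    for s in range(len(slices) - 1):
        # a gap in the slice sequence separates distinct structures
        bridge = coords[s + 1] - coords[s] <= max_step + 1e-9
        pairs = _match_polygons(polys[s], polys[s + 1]) if bridge else []
        if len(polys[s]) != len(polys[s + 1]):
            log.info("contours_to_mesh(%s): branching at slice %g (%d -> %d contours)",
                     stack.structure, coords[s], len(polys[s]), len(polys[s + 1]))
        nxt_open: dict[int, list] = {}
        matched_next = set()
        for i, j in pairs:
            ch = open_chains.get(i)
            if ch is None:
                continue
            ch.append((s + 1, j))
            nxt_open[j] = ch
            matched_next.add(j)
        for j in range(len(polys[s + 1])):
            if j not in matched_next:
                ch = [(s + 1, j)]
                chains.append(ch)
                nxt_open[j] = ch
        open_chains = nxt_open

    axis = stack.normal_axis
    ua, va = stack.inplane_axes
    verts_all, faces_all, grids = [], [], []
    v_offset = 0
    for ch in chains:
        if len(ch) < 2:
            continue  # isolated contour: no solid between slices, skip (logged)
        ring_pts = [polys[s][j] for s, j in ch]
        n = max(
            8, max(int(np.ceil(_perimeter(q) / resample_step)) for q in ring_pts)
        )
        rings = [_resample_closed(q, n) for q in ring_pts]
        for k in range(1, len(rings)):
            rings[k] = _align_phase(rings[k - 1], rings[k])
        S = len(rings)
        grid3 = np.empty((S, n, 3))
        for k, (s, _) in enumerate(ch):
            grid3[k, :, axis] = coords[s]
            grid3[k, :, ua] = rings[k][:, 0]
            grid3[k, :, va] = rings[k][:, 1]
        ids = (np.arange(S * n) + v_offset).reshape(S, n)
        verts_all.append(grid3.reshape(-1, 3))
        i = np.arange(n)
        ip = (i + 1) % n
        for k in range(S - 1):
            a0, a1, b0, b1 = ids[k, i], ids[k, ip], ids[k + 1, i], ids[k + 1, ip]
            faces_all.append(np.stack([a0, a1, b0], axis=1))
            faces_all.append(np.stack([a1, b1, b0], axis=1))
        # caps: bottom (lowest slice) and top
        cap0 = triangulate_polygon2d(rings[0])
        faces_all.append(ids[0][cap0[:, [0, 2, 1]]])  # normal toward -axis
        cap1 = triangulate_polygon2d(rings[-1])
        faces_all.append(ids[-1][cap1])  # normal toward +axis
        grids.append((ids, np.array([coords[s] for s, _ in ch])))
        v_offset += S * n

    if not verts_all:
        raise ValueError("no contour chain spans two or more slices")
    surf = Surface(
        np.vstack(verts_all),
        np.vstack([f for f in faces_all if len(f)]),
        stack.structure,
        provenance=f"contour_stack:{stack.plane}",
    )
    surf = surf.drop_degenerate()
    if surf.to_trimesh().volume < 0:
        surf = replace(surf, faces=surf.faces[:, ::-1])
    surf.chains = grids
    surf.slice_axis = axis
    return surf


def _perimeter(p: np.ndarray) -> float:
    closed = np.vstack([p, p[:1]])
    return float(np.linalg.norm(np.diff(closed, axis=0), axis=1).sum())


def visual_smooth(surface: Surface, config: SegmentationConfig | None = None) -> Surface:
    """Gaussian inter-slice smoothing for visualization only.

    Filters the in-plane vertex positions of each contour chain across the
    slicing direction with Gaussian weights of scale ``visual_sigma`` (mm).
    The slice coordinates themselves are untouched.  The result is flagged
    ``visualization_only``; quantitative operations reject such surfaces.
    Boundary slices are handled by linear extrapolation so affine surfaces
    are preserved exactly.
    """
    config = config or SegmentationConfig()
    chains = getattr(surface, "chains", None)
    axis = getattr(surface, "slice_axis", None)
    if chains is None or axis is None:
        raise ValueError("visual_smooth requires a surface from contours_to_mesh")
    verts = surface.vertices.copy()
    inplane = [a for a in range(3) if a != axis]
    for ids, coords in chains:
        S = ids.shape[0]
        if S < 2:
            continue
        h = float(np.mean(np.diff(coords)))
        sigma = config.visual_sigma / max(h, 1e-12)
        if sigma < 1e-6:
            continue
        pad = max(1, int(np.ceil(4 * sigma)))
        for a in inplane:
            grid = verts[ids][:, :, a]
            lo = grid[0] + (grid[0] - grid[1]) * np.arange(pad, 0, -1)[:, None]
            hi = grid[-1] + (grid[-1] - grid[-2]) * np.arange(1, pad + 1)[:, None]
            padded = np.vstack([lo, grid, hi])
            sm = ndimage.gaussian_filter1d(padded, sigma, axis=0, mode="nearest")
            verts[ids.ravel(), a] = sm[pad : pad + S].ravel()
    out = replace(surface, vertices=verts, visualization_only=True)
    out.chains = chains
    out.slice_axis = axis
    return out
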