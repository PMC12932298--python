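"""File formats: NIfTI volumes, PLY/STL surfaces, contour JSON, CSV tables.

Volumes interchange as NIfTI with an axis-aligned affine; the affine's
world coordinates are authoritative and map voxel index ``i`` to the voxel
centre ``origin + (i + 0.5) * spacing`` used throughout the package.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

from .contact import ContactAreaTable
from .core import ContourStack, Image3D, LabelVolume, Surface


class DataError(ValueError):
    pass


def _affine(spacing: np.ndarray, origin: np.ndarray) -> np.ndarray:
    A = np.eye(4)
    A[:3, :3] = np.diag(spacing)
    A[:3, 3] = origin + 0.5 * spacing  # NIfTI world coord of voxel (0,0,0)
    return A


def write_volume(vol: Image3D | LabelVolume, path) -> Path:
    path = Path(path)
    if isinstance(vol, LabelVolume):
        data = vol.labels.astype(np.int16)
    else:
        data = vol.intensities.astype(np.float32)
    img = nib.Nifti1Image(data, _affine(vol.spacing, vol.origin))
    nib.save(img, str(path))
    return path


def read_volume(path, as_labels: bool | None = None):
    """Read a NIfTI volume as Image3D or LabelVolume.

    Integer on-disk dtypes load as labels unless ``as_labels`` overrides.
    Non-axis-aligned affines are rejected explicitly rather than silently
    resampled.
    """
    path = Path(path)
    img = nib.load(str(path))
    A = img.affine
    lin = A[:3, :3]
    if not np.allclose(lin, np.diag(np.diag(lin)), atol=1e-6):
        raise DataError(f"{path}: affine is not axis-aligned; resample first")
    spacing = np.diag(lin).copy()
    if np.any(spacing <= 0):
        raise DataError(f"{path}: affine implies non-positive spacing {spacing}")
    origin = A[:3, 3] - 0.5 * spacing
    data = np.asanyarray(img.dataobj)
    if as_labels is None:
        as_labels = np.issubdtype(data.dtype, np.integer)
    if as_labels:
        return LabelVolume(data.astype(np.int16), spacing, origin)
    return Image3D(data.astype(np.float32), spacing, origin)


def check_same_lattice(image: Image3D, labels: LabelVolume):
    if not labels.same_lattice(image):
        raise DataError(
            "image and label volume disagree in shape/spacing/origin: "
            f"{image.shape}/{image.spacing}/{image.origin} vs "
            f"{labels.shape}/{labels.spacing}/{labels.origin}"
        )


def write_surface(surface: Surface, path) -> Path:
    """Write a surface as PLY or STL (by extension)."""
    path = Path(path)
    mesh = surface.to_trimesh()
    mesh.export(str(path))
    return path


def read_surface(path, structure: str = "") -> Surface:
    mesh = trimesh.load_mesh(str(path), process=False)
    return Surface.from_trimesh(mesh, structure)


def write_contour_stack(stack: ContourStack, path) -> Path:
    path = Path(path)
    payload = {
        "structure": stack.structure,
        "plane": stack.plane,
        "slices": [
            [coord, [poly.tolist() for poly in polys]]
            for coord, polys in stack.slices
        ],
    }
    path.write_text(json.dumps(payload))
    return path


def read_contour_stack(path) -> ContourStack:
    payload = json.loads(Path(path).read_text())
    return ContourStack(
        payload["structure"],
        payload["plane"],
        [
            (float(coord), [np.asarray(p, float) for p in polys])
            for coord, polys in payload["slices"]
        ],
    )


def write_tables(tables: list[ContactAreaTable], path) -> Path:
    """Tidy CSV: subject, condition, interface, compartment, area, QC."""
    path = Path(path)
    df = pd.concat([t.to_frame() for t in tables], ignore_index=True)
    df.to_csv(path, index=False)
    return path


def write_transform(transform, path) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps(
            {
                "rotation": transform.rotation.tolist(),
                "translation_mm": transform.translation.tolist(),
                "residual_rms_mm": transform.residual_rms,
                "n_iterations": transform.n_iterations,
            }
        )
    )
    return path


def read_transform(path):
    from .joint_geometry import RigidTransform

    d = json.loads(Path(path).read_text())
    return RigidTransform(
        np.asarray(d["rotation"]),
        np.asarray(d["translation_mm"]),
        residual_rms=d.get("residual_rms_mm", 0.0),
        n_iterations=d.get("n_iterations", 0),
    )


def write_report(report, out_dir) -> dict:
    """Write a LoadChangeReport as CSV tables plus a JSON summary."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["measures"] = out_dir / "load_change_measures.csv"
    report.measures.to_csv(paths["measures"], index=False)
    paths["ratios"] = out_dir / "ml_ratios.csv"
    report.ratios.to_csv(paths["ratios"], index=False)
    if len(report.contrasts):
        paths["tests"] = out_dir / "paired_tests.csv"
        report.contrasts.to_csv(paths["tests"], index=False)
    paths["formatted"] = out_dir / "load_change_formatted.csv"
    report.formatted().to_csv(paths["formatted"], index=False)
    summary = {
        "n_subjects": report.n_subjects,
        "alpha": report.config.alpha,
        "excluded": [list(map(str, e[:2])) + [e[2]] for e in report.excluded],
    }
    paths["summary"] = out_dir / "report_summary.json"
    paths["summary"].write_text(json.dumps(summary, indent=2))
    return {k: str(v) for k, v in paths.items()}


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
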