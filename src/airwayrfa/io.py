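"""Readers/writers for run artifacts: NIfTI volumes, VTK grids, CSV, JSON."""

from __future__ import annotations

import json

import nibabel as nib
import numpy as np
import yaml

__all__ = ["write_nifti", "read_nifti", "write_vtk_structured_points",
           "write_json", "load_config"]


def write_nifti(path, array: np.ndarray, spacing_mm: float) -> None:
    """Write a volume (labels or field) as NIfTI with isotropic mm spacing."""
    affine = np.diag([spacing_mm, spacing_mm, spacing_mm, 1.0])
    data = np.asarray(array)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_nifti(path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj), float(img.affine[0, 0])


def write_vtk_structured_points(path, array: np.ndarray, spacing_mm: float,
                                name: str = "field") -> None:
    """Legacy ASCII VTK STRUCTURED_POINTS writer for quick visualization."""
    data = np.asarray(array, dtype=float)
    nx, ny, nz = data.shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"{name}\nASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"SPACING {spacing_mm} {spacing_mm} {spacing_mm}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, data.ravel(order="F"), fmt="%.6g")


def write_json(path, payload: dict) -> None:
    def _default(obj):
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return str(obj)

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=_default)


def load_config(path) -> dict:
    """Load a YAML/JSON experiment config (geometry/materials/protocol blocks)."""
    with open(path) as fh:
        return yaml.safe_load(fh)
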