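"""Shared 7-point finite-volume machinery on the isotropic voxel grid.

Fluxes use harmonic-mean face coefficients; for an isotropic spacing ``h``
(metres) the face conductance between neighbouring voxels is
``coef_face * h`` (units: property-unit times metres), since face area over
centre distance is ``h^2 / h``.  A Dirichlet ghost face on the domain
boundary has conductance ``2 * coef * h`` (half centre distance).
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

__all__ = ["face_harmonic", "assemble_fv", "boundary_face_mask"]


def face_harmonic(prop: np.ndarray) -> list[np.ndarray]:
    """Harmonic means of a cell property across interior faces, per axis."""
    out = []
    for axis in range(3):
        a = np.swapaxes(prop, 0, axis)[:-1]
        b = np.swapaxes(prop, 0, axis)[1:]
        out.append(np.swapaxes(2.0 * a * b / (a + b), 0, axis))
    return out


def assemble_fv(coef: np.ndarray, h_m: float, dirichlet_mask: np.ndarray,
                dirichlet_values: np.ndarray):
    """Assemble the FV diffusion operator over the non-Dirichlet voxels.

    Returns ``(A, b, unknown_index)`` where ``A x = b`` solves
    ``-div(coef grad u) = 0`` with the given Dirichlet set and homogeneous
    Neumann on the remaining domain boundary.  ``unknown_index`` maps flat
    voxel index to row of ``A`` (-1 for Dirichlet voxels).  ``A`` is SPD in
    conductance units (coef-unit times metres).
    """
    shape = coef.shape
    n = int(np.prod(shape))
    unknown = ~dirichlet_mask.ravel()
    unknown_index = np.full(n, -1, dtype=np.int64)
    unknown_index[unknown] = np.arange(unknown.sum())
    nunk = int(unknown.sum())

    vals_flat = dirichlet_values.ravel()
    diag = np.zeros(nunk)
    b = np.zeros(nunk)
    rows, cols, data = [], [], []

    faces = face_harmonic(coef)
    flat = np.arange(n).reshape(shape)
    for axis in range(3):
        idx_sw = np.swapaxes(flat, 0, axis)
        ia = idx_sw[:-1].ravel()
        ib = idx_sw[1:].ravel()
        g = np.swapaxes(faces[axis], 0, axis).ravel() * h_m
        ua, ub = unknown_index[ia], unknown_index[ib]
        both = (ua >= 0) & (ub >= 0)
        rows.append(ua[both]); cols.append(ub[both]); data.append(-g[both])
        rows.append(ub[both]); cols.append(ua[both]); data.append(-g[both])
        np.add.at(diag, ua[both], g[both])
        np.add.at(diag, ub[both], g[both])
        a_only = (ua >= 0) & (ub < 0)
        np.add.at(diag, ua[a_only], g[a_only])
        np.add.at(b, ua[a_only], g[a_only] * vals_flat[ib[a_only]])
        b_only = (ua < 0) & (ub >= 0)
        np.add.at(diag, ub[b_only], g[b_only])
        np.add.at(b, ub[b_only], g[b_only] * vals_flat[ia[b_only]])

    rows.append(np.arange(nunk)); cols.append(np.arange(nunk)); data.append(diag)
    A = sparse.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nunk, nunk))
    return A, b, unknown_index


def boundary_face_mask(shape, face: str) -> np.ndarray:
    """Boolean mask selecting the boundary voxel layer of one face."""
    mask = np.zeros(shape, dtype=bool)
    axis = "xyz".index(face[0])
    sl = [slice(None)] * 3
    sl[axis] = 0 if face[1] == "-" else -1
    mask[tuple(sl)] = True
    return mask
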