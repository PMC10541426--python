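"""Pennes bioheat time stepping on the voxel grid.

The temperature field obeys

    rho*c dT/dt = div(k grad T) + rho*Q + U - rho_b*c_b*omega*(T - Tb)

with the SAR source U from the electrostatic solve, harmonic-mean face
conductivities, and (by default) a Dirichlet body-core bath T = Tb on every
domain face; a homogeneous Neumann (insulated) variant exists for energy-
balance checks.  The metal cast participates in conduction with its own
thermal properties, which is what makes the electrode-volume-mean sensor a
physically meaningful average of the ablated tissue.

Two schemes are provided: explicit Euler with an automatic step obeying the
diffusion stability bound dt <= min(rho*c*h^2/(6k)), and backward Euler
(sparse conjugate-gradient solve per step) for stiff label mixes such as
air-bearing domains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import LinearOperator, cg

from ._stencil import face_harmonic
from .errors import ConfigurationError, SolverError, StabilityError
from .geometry import VoxelDomain
from .materials import MaterialTable

__all__ = ["ThermalState", "BioheatSolver", "step_bioheat", "read_sensor"]


@dataclass
class ThermalState:
    """Temperature grid (degC), elapsed time (s), running per-voxel maximum."""

    T: np.ndarray
    t: float = 0.0
    Tmax: np.ndarray = None

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        if self.Tmax is None:
            self.Tmax = self.T.copy()


class BioheatSolver:
    """Precomputed Pennes operator for one domain + material table."""

    def __init__(self, domain: VoxelDomain, table: MaterialTable,
                 boundary: str = "dirichlet", scheme: str = "explicit",
                 dt: float | None = None, rtol: float = 1e-10):
        if boundary not in ("dirichlet", "neumann"):
            raise ConfigurationError("boundary must be 'dirichlet' or 'neumann'")
        if scheme not in ("explicit", "implicit"):
            raise ConfigurationError("scheme must be 'explicit' or 'implicit'")
        self.domain = domain
        self.table = table
        self.boundary = boundary
        self.scheme = scheme
        self.rtol = rtol
        self.h_m = domain.spacing * 1e-3
        labels = domain.labels
        self.rho_c = table.property_grid(labels, "rho") * table.property_grid(labels, "c")
        self.k = table.property_grid(labels, "k")
        self.perf = table.perfusion_grid(labels)          # rho_b c_b omega, W/m^3/K
        self.q_vol = (table.property_grid(labels, "rho")
                      * table.property_grid(labels, "q_met"))  # W/m^3
        self.Tb = table.T_b
        self.faces = face_harmonic(self.k)                 # W/m/K across faces
        # explicit stability bound, tightest voxel
        self.stable_dt = float((self.rho_c * self.h_m**2 / (6.0 * self.k)).min())
        self.dt = dt if dt is not None else 0.9 * self.stable_dt
        self._A = None
        self._inv_diag = None
        self._A_dt = None

    # -- operators ---------------------------------------------------------

    def make_state(self, T0: float | np.ndarray | None = None) -> ThermalState:
        T0 = self.Tb if T0 is None else T0
        T = np.full(self.domain.shape, T0, dtype=float) if np.isscalar(T0) \
            else np.asarray(T0, dtype=float).copy()
        return ThermalState(T=T)

    def _divergence(self, T: np.ndarray) -> np.ndarray:
        """div(k grad T) in W/m^3 for the current boundary condition."""
        h2 = self.h_m**2
        out = np.zeros_like(T)
        for axis in range(3):
            g = np.swapaxes(self.faces[axis], 0, axis)
            Ts = np.swapaxes(T, 0, axis)
            os_ = np.swapaxes(out, 0, axis)
            flux = g * (Ts[1:] - Ts[:-1]) / h2   # W/m^3 contribution per face
            os_[:-1] += flux
            os_[1:] -= flux
            if self.boundary == "dirichlet":
                kk = np.swapaxes(self.k, 0, axis)
                os_[0] += 2.0 * kk[0] * (self.Tb - Ts[0]) / h2
                os_[-1] += 2.0 * kk[-1] * (self.Tb - Ts[-1]) / h2
        return out

    def step(self, state: ThermalState, U: np.ndarray, dt: float) -> ThermalState:
        """One explicit Euler step of length dt (checked against stability)."""
        if dt <= 0:
            raise ConfigurationError("dt must be positive")
        if dt > self.stable_dt * (1.0 + 1e-9):
            raise StabilityError(
                f"dt={dt:.4g}s exceeds the explicit stability bound "
                f"{self.stable_dt:.4g}s = min(rho*c*h^2/(6k))")
        rate = (self._divergence(state.T) + U + self.q_vol
                - self.perf * (state.T - self.Tb)) / self.rho_c
        state.T = state.T + dt * rate
        state.t += dt
        np.maximum(state.Tmax, state.T, out=state.Tmax)
        return state

    # -- implicit scheme ---------------------------------------------------

    def _assemble_implicit(self, dt: float) -> None:
        shape = self.domain.shape
        n = int(np.prod(shape))
        flat = np.arange(n).reshape(shape)
        rows, cols, data = [], [], []
        diag = np.zeros(n)
        bdry = np.zeros(n)  # conductance to the Dirichlet bath, W/K-like (per h)
        for axis in range(3):
            idx = np.swapaxes(flat, 0, axis)
            g = np.swapaxes(self.faces[axis], 0, axis).ravel() * self.h_m  # W/K
            ia, ib = idx[:-1].ravel(), idx[1:].ravel()
            rows.append(ia); cols.append(ib); data.append(-g)
            rows.append(ib); cols.append(ia); data.append(-g)
            np.add.at(diag, ia, g)
            np.add.at(diag, ib, g)
            if self.boundary == "dirichlet":
                kk = np.swapaxes(self.k, 0, axis)
                np.add.at(bdry, idx[0].ravel(), 2.0 * kk[0].ravel() * self.h_m)
                np.add.at(bdry, idx[-1].ravel(), 2.0 * kk[-1].ravel() * self.h_m)
        vol = self.domain.voxel_volume_m3
        cap = self.rho_c.ravel() * vol / dt               # J/K/s = W/K
        full_diag = diag + bdry + cap + self.perf.ravel() * vol
        rows.append(np.arange(n)); cols.append(np.arange(n)); data.append(full_diag)
        A = sparse.csr_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n))
        self._A = A
        self._cap = cap
        self._bdry = bdry
        self._inv_diag = 1.0 / A.diagonal()
        self._A_dt = dt

    def step_implicit(self, state: ThermalState, U: np.ndarray, dt: float) -> ThermalState:
        """One backward-Euler step (unconditionally stable sparse solve)."""
        if self._A is None or self._A_dt != dt:
            self._assemble_implicit(dt)
        vol = self.domain.voxel_volume_m3
        b = (self._cap * state.T.ravel()
             + (U.ravel() + self.q_vol.ravel()) * vol
             + self.perf.ravel() * vol * self.Tb
             + self._bdry * self.Tb)
        M = LinearOperator(self._A.shape, matvec=lambda v: self._inv_diag * v)
        x, info = cg(self._A, b, x0=state.T.ravel(), rtol=self.rtol, atol=0.0,
                     maxiter=5000, M=M)
        if info != 0:
            raise SolverError(f"implicit bioheat solve failed (info={info})")
        state.T = x.reshape(self.domain.shape)
        state.t += dt
        np.maximum(state.Tmax, state.T, out=state.Tmax)
        return state

    def advance(self, state: ThermalState, U: np.ndarray, duration: float) -> ThermalState:
        """Advance by ``duration`` seconds using the configured scheme."""
        if duration <= 0:
            return state
        if self.scheme == "implicit":
            n = max(int(round(duration / self.dt)), 1)
            dt = duration / n
            for _ in range(n):
                self.step_implicit(state, U, dt)
        else:
            n = max(int(np.ceil(duration / self.dt)), 1)
            dt = duration / n
            for _ in range(n):
                self.step(state, U, dt)
        return state

    def total_energy(self, state: ThermalState) -> float:
        """sum(rho*c*T*vol), J — for the insulated energy-balance check."""
        return float((self.rho_c * state.T).sum() * self.domain.voxel_volume_m3)


def step_bioheat(state: ThermalState, domain: VoxelDomain, table: MaterialTable,
                 U: np.ndarray, dt: float) -> ThermalState:
    """Single explicit Pennes step (convenience wrapper around the solver)."""
    return BioheatSolver(domain, table).step(state, U, dt)


def read_sensor(state: ThermalState, domain: VoxelDomain) -> tuple[float, float]:
    """Catheter temperature readings: (sensor_T, tip_T) in degC.

    ``sensor_T`` is the volume mean of T over the cast (the catheter
    thermocouple sits in the metal column, whose high thermal conductivity
    averages the surrounding ablated tissue); ``tip_T`` is the point reading
    at the deepest tip voxel, reported alongside.
    """
    mask = domain.mask(domain.source_label())
    if not mask.any():
        raise ConfigurationError("no electrode voxels to read a sensor from")
    sensor = float(state.T[mask].mean())
    tip = float(state.T[tuple(domain.electrode_tip_voxel)]) \
        if domain.electrode_tip_voxel is not None else sensor
    return sensor, tip
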