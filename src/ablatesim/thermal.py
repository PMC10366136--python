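"""Enthalpy-method heat transport with a latent-heat plateau.

The temperature field is advanced through the volumetric enthalpy H
(J/mm^3), which absorbs the latent heat of the water-vaporization phase
change:

    dH/dt = k * laplacian(T) + S

solved by explicit finite differences (7-point Laplacian, FTCS) with
adiabatic (zero-flux) lattice boundaries.  Enthalpy maps to temperature as

    T = H / (rho c_p)            for H <  rho c_p T_v
    T = T_v                      for rho c_p T_v <= H < rho (c_p T_v + L_v)

so a voxel sits at the vaporization temperature while it accumulates latent
heat; once H reaches the threshold H_th = rho (c_p T_v + L_v) the voxel is
removed by :func:`ablatesim.tissue.vaporize_voxels`.  The zero reference is
H = 0 at 0 degC.

Faces between dissimilar materials conduct with the harmonic-mean
conductivity (the standard conservative finite-difference treatment).  The
explicit scheme is stable for dt <= rho c_p dx^2 / (6 k) for every material
present; air, with its tiny volumetric heat capacity, is the binding
constraint in the layered model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .damage import CELSIUS_TO_KELVIN, ArrheniusParams
from .errors import ConfigurationError, ConsistencyError, DomainError
from .tissue import TISSUE, MaterialProperties, VoxelGrid


@dataclass
class FieldState:
    """Co-registered volumetric fields evolved by the coupling loop."""

    H: np.ndarray       # enthalpy density, J/mm^3
    T: np.ndarray       # temperature, degC
    S: np.ndarray       # absorbed power density, W/mm^3
    Omega: np.ndarray   # Arrhenius damage parameter
    time: float = 0.0

    def copy(self) -> "FieldState":
        return FieldState(self.H.copy(), self.T.copy(), self.S.copy(),
                          self.Omega.copy(), self.time)


def initial_state(grid: VoxelGrid, temperature_c: float = 22.0) -> FieldState:
    """Uniform initial condition (default: 22 degC room temperature)."""
    rho_cp = _material_array(grid, "rho_cp")
    H = rho_cp[grid.material_id] * temperature_c
    T = np.full(grid.shape, float(temperature_c))
    return FieldState(H=H, T=T, S=np.zeros(grid.shape),
                      Omega=np.zeros(grid.shape))


# ---------------------------------------------------------------------------
# scalar/array operations
# ---------------------------------------------------------------------------

def threshold_enthalpy(props: MaterialProperties) -> float:
    """Vaporization threshold H_th = rho (c_p T_v + L_v), J/mm^3."""
    return props.rho * (props.c_p * props.T_v + props.L_v)


def enthalpy_to_temperature(H, props: MaterialProperties, strict: bool = True):
    """Map enthalpy density to temperature for a single material.

    Below the plateau ``T = H/(rho c_p)``; between ``rho c_p T_v`` and the
    removal threshold the temperature is clamped at ``T_v`` (latent heat is
    being absorbed).  At exactly ``H = rho c_p T_v`` the two branches agree
    (continuity), so the clamp is applied from that point on.

    With ``strict=True`` an enthalpy above the removal threshold on a
    still-present voxel raises :class:`ConsistencyError`, since such a voxel
    should already have been vaporized.  The coupling loop, which only
    checks for removal at the end of each transport window, uses
    ``strict=False`` and keeps pending voxels clamped at ``T_v``.
    """
    H = np.asarray(H, dtype=np.float64)
    if np.any(H < 0.0):
        raise DomainError("enthalpy must be >= 0 (zero reference at 0 degC)")
    h_plateau = props.rho_cp * props.T_v
    if strict and math.isfinite(props.T_v):
        if np.any(H > threshold_enthalpy(props)):
            raise ConsistencyError(
                "enthalpy above the vaporization threshold on a present "
                "voxel: removal was missed")
    T = H / props.rho_cp
    if math.isfinite(props.T_v):
        T = np.where(H >= h_plateau, props.T_v, T)
    return float(T) if T.ndim == 0 else T


def stability_limit(props: MaterialProperties, voxel_size: float) -> float:
    """Largest stable explicit step, dt = rho c_p dx^2 / (6 k), seconds."""
    if voxel_size <= 0:
        raise DomainError("voxel_size must be positive")
    if props.k == 0.0:
        return math.inf
    return props.rho_cp * voxel_size ** 2 / (6.0 * props.k)


def grid_stability_limit(grid: VoxelGrid) -> float:
    """Binding stability limit over every material present in the grid."""
    present = np.unique(grid.material_id)
    return min(stability_limit(grid.materials[int(m)], grid.voxel_size)
               for m in present)


# ---------------------------------------------------------------------------
# material lookup tables for the kernel
# ---------------------------------------------------------------------------

def _material_array(grid: VoxelGrid, attr: str) -> np.ndarray:
    n = max(grid.materials) + 1
    out = np.zeros(n)
    for mid, props in grid.materials.items():
        out[mid] = getattr(props, attr)
    return out


def _kernel_tables(grid: VoxelGrid):
    """Per-material rho*c_p / plateau tables and the face-conductivity table.

    The face table holds the harmonic mean of the two adjacent materials'
    conductivities, which keeps the scheme conservative across interfaces.
    """
    n = max(grid.materials) + 1
    rho_cp = _material_array(grid, "rho_cp")
    k = _material_array(grid, "k")
    t_v = np.array([grid.materials[m].T_v if m in grid.materials else np.inf
                    for m in range(n)])
    h_plateau = np.where(np.isfinite(t_v), rho_cp * t_v, np.inf)
    k_face = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            if k[a] > 0 and k[b] > 0:
                k_face[a, b] = 2.0 * k[a] * k[b] / (k[a] + k[b])
    return rho_cp, h_plateau, t_v, k_face


@njit(cache=True)
def _advance_kernel(H, Omega, T, S, mat, rho_cp, h_plateau, t_v, k_face,
                    dt, n_sub, inv_dx2, arr_a, arr_ea_r, t_cutoff,
                    tissue_id):  # pragma: no cover - exercised via wrappers
    nx, ny, nz = H.shape
    for _ in range(n_sub):
        # temperature from enthalpy (plateau clamp at and above rho c_p T_v)
        for i in range(nx):
            for j in range(ny):
                for k3 in range(nz):
                    m = mat[i, j, k3]
                    h = H[i, j, k3]
                    if h >= h_plateau[m]:
                        T[i, j, k3] = t_v[m]
                    else:
                        T[i, j, k3] = h / rho_cp[m]
        # conduction + source + damage
        for i in range(nx):
            for j in range(ny):
                for k3 in range(nz):
                    m = mat[i, j, k3]
                    tc = T[i, j, k3]
                    lap = 0.0
                    if i > 0:
                        lap += k_face[m, mat[i - 1, j, k3]] * (T[i - 1, j, k3] - tc)
                    if i < nx - 1:
                        lap += k_face[m, mat[i + 1, j, k3]] * (T[i + 1, j, k3] - tc)
                    if j > 0:
                        lap += k_face[m, mat[i, j - 1, k3]] * (T[i, j - 1, k3] - tc)
                    if j < ny - 1:
                        lap += k_face[m, mat[i, j + 1, k3]] * (T[i, j + 1, k3] - tc)
                    if k3 > 0:
                        lap += k_face[m, mat[i, j, k3 - 1]] * (T[i, j, k3 - 1] - tc)
                    if k3 < nz - 1:
                        lap += k_face[m, mat[i, j, k3 + 1]] * (T[i, j, k3 + 1] - tc)
                    H[i, j, k3] += dt * (lap * inv_dx2 + S[i, j, k3])
                    if m == tissue_id and tc >= t_cutoff and arr_a > 0.0:
                        Omega[i, j, k3] += dt * arr_a * math.exp(
                            -arr_ea_r / (tc + CELSIUS_TO_KELVIN))
    # refresh T after the last substep
    for i in range(nx):
        for j in range(ny):
            for k3 in range(nz):
                m = mat[i, j, k3]
                h = H[i, j, k3]
                if h >= h_plateau[m]:
                    T[i, j, k3] = t_v[m]
                else:
                    T[i, j, k3] = h / rho_cp[m]


def advance(state: FieldState, grid: VoxelGrid, dt: float, n_sub: int,
            arrhenius: ArrheniusParams | None = None,
            arrhenius_cutoff_c: float = 35.0) -> FieldState:
    """Advance H/T (and optionally Omega) by ``n_sub`` explicit steps in place.

    The Arrhenius increment is evaluated per substep from the current
    temperature; voxels colder than ``arrhenius_cutoff_c`` are skipped —
    below ~35 degC the liver damage rate is many orders of magnitude away
    from contributing to Omega on ablation timescales.
    """
    if dt <= 0 or n_sub < 0:
        raise DomainError("dt must be positive and n_sub non-negative")
    limit = grid_stability_limit(grid)
    if dt > limit * (1.0 + 1e-12):
        raise ConfigurationError(
            f"dt={dt:g}s violates the explicit stability limit {limit:g}s")
    rho_cp, h_plateau, t_v, k_face = _kernel_tables(grid)
    a = arrhenius.A if arrhenius is not None else 0.0
    ea_r = arrhenius.E_a / arrhenius.R if arrhenius is not None else 1.0
    _advance_kernel(state.H, state.Omega, state.T, state.S, grid.material_id,
                    rho_cp, h_plateau, t_v, k_face, dt, n_sub,
                    1.0 / grid.voxel_size ** 2, a, ea_r,
                    arrhenius_cutoff_c, TISSUE)
    state.time += dt * n_sub
    return state


def step_enthalpy(state: FieldState, grid: VoxelGrid, dt: float) -> FieldState:
    """One conduction step of dH/dt = k laplacian(T) + S; returns a new state.

    Refuses steps above the explicit stability limit of any material present.
    """
    new = state.copy()
    advance(new, grid, dt, 1, arrhenius=None)
    return new
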