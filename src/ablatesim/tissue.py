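"""Voxelized air/tissue model with heating-dependent optical state.

The simulation domain is a rectangular lattice of cubic voxels holding an air
layer above a homogeneous tissue slab.  Two things change during irradiation:

* the reduced scattering coefficient of each tissue voxel rises linearly with
  its thermally damaged fraction ``alpha`` between the native and the fully
  coagulated value (the dynamic-optical-properties model), while the
  absorption coefficient is held fixed — at near-infrared wavelengths the
  heat-induced change in absorption is negligible compared to scattering;
* voxels whose enthalpy passes the vaporization threshold are removed and
  replaced by air, carving a crater into the slab.  Removal is irreversible.

Internal unit system: mm, g, s, J, degrees Celsius (thermal conductivity is
W/(mm*K), density g/mm^3).  Helper converters are provided for the units in
which these quantities are usually quoted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, DomainError

# material labels used in VoxelGrid.material_id
AIR = 0
TISSUE = 1
VAPORIZED = 2

MATERIAL_NAMES = {AIR: "air", TISSUE: "tissue", VAPORIZED: "vaporized"}


# ---------------------------------------------------------------------------
# unit converters (into the internal mm/g/s/J/degC system)
# ---------------------------------------------------------------------------

def k_from_w_per_m_k(value: float) -> float:
    """Thermal conductivity W/(m*K) -> W/(mm*K)."""
    return value / 1000.0


def k_from_w_per_cm_k(value: float) -> float:
    """Thermal conductivity W/(cm*K) -> W/(mm*K)."""
    return value / 10.0


def rho_from_g_per_cm3(value: float) -> float:
    """Density g/cm^3 -> g/mm^3."""
    return value / 1000.0


# ---------------------------------------------------------------------------
# material properties
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaterialProperties:
    """Optical and thermal constants of one material.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient (1/mm).
    mu_s_prime_native, mu_s_prime_coagulated : float
        Reduced scattering coefficient (1/mm) of the native and of the fully
        coagulated state.  For non-scattering materials (air) both are 0.
    g : float
        Scattering anisotropy (mean cosine of the single-scattering angle).
    n : float
        Refractive index.
    k : float
        Thermal conductivity, W/(mm*K).
    rho : float
        Density, g/mm^3.
    c_p : float
        Specific heat capacity, J/(g*K).
    T_v : float
        Vaporization temperature, degC.  ``math.inf`` for materials that do
        not vaporize (air).
    L_v : float
        Latent heat of vaporization, J/g.
    """

    mu_a: float
    mu_s_prime_native: float
    mu_s_prime_coagulated: float
    g: float
    n: float
    k: float
    rho: float
    c_p: float
    T_v: float
    L_v: float

    def __post_init__(self) -> None:
        for name in ("mu_a", "mu_s_prime_native", "mu_s_prime_coagulated",
                     "k", "rho", "c_p", "L_v"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not (0.0 <= self.g < 1.0):
            raise ConfigurationError("anisotropy g must lie in [0, 1)")
        if self.n < 1.0:
            raise ConfigurationError("refractive index n must be >= 1")
        if self.mu_s_prime_coagulated < self.mu_s_prime_native:
            raise ConfigurationError(
                "coagulated reduced scattering must be >= native value")

    @property
    def rho_cp(self) -> float:
        """Volumetric heat capacity rho*c_p, J/(mm^3*K)."""
        return self.rho * self.c_p

    def mu_s_from_reduced(self, mu_s_prime: float | np.ndarray):
        """Scattering coefficient mu_s = mu_s'/(1-g) (similarity relation)."""
        return mu_s_prime / (1.0 - self.g)


def air_properties(
    k: float = k_from_w_per_m_k(0.026),
    rho: float = rho_from_g_per_cm3(1.2e-3),
    c_p: float = 1.005,
) -> MaterialProperties:
    """Dry air near room temperature: transparent, non-scattering, n = 1."""
    return MaterialProperties(
        mu_a=0.0, mu_s_prime_native=0.0, mu_s_prime_coagulated=0.0,
        g=0.0, n=1.0, k=k, rho=rho, c_p=c_p, T_v=math.inf, L_v=0.0)


def liver_properties(
    mu_a: float = 0.07,
    mu_s_prime_native: float = 1.0,
    mu_s_prime_coagulated: float = 2.65,
    g: float = 0.9,
    n: float = 1.44,
    k: float = k_from_w_per_m_k(0.52),
    rho: float = rho_from_g_per_cm3(1.05),
    c_p: float = 3.6,
    T_v: float = 100.0,
    L_v: float = 2257.0,
) -> MaterialProperties:
    """Porcine-liver-like constants at 980 nm.

    These defaults are literature-style placeholders, not authoritative
    measurements: the absorption coefficient is the 0.07 1/mm measured for
    native liver at 980 nm, the coagulated reduced scattering is 2.65x the
    native value, the anisotropy 0.9 and index 1.44 are the values assumed in
    the inverse analysis of liver optics, and the thermal constants are
    water-dominated soft-tissue values.  Supply measured values through the
    scenario configuration for quantitative work.
    """
    return MaterialProperties(
        mu_a=mu_a, mu_s_prime_native=mu_s_prime_native,
        mu_s_prime_coagulated=mu_s_prime_coagulated, g=g, n=n,
        k=k, rho=rho, c_p=c_p, T_v=T_v, L_v=L_v)


# ---------------------------------------------------------------------------
# voxel grid
# ---------------------------------------------------------------------------

@dataclass
class VoxelGrid:
    """Cubic-voxel lattice of an air layer above a tissue slab.

    Axes are (x, y, z) with z the depth direction; the lateral origin is at
    the slab center so the tissue surface center sits at (x, y) = (0, 0).
    ``surface_z`` is the depth (mm) of the *original* air-tissue interface;
    it does not move when vaporization carves a crater.
    """

    shape: tuple[int, int, int]
    voxel_size: float
    material_id: np.ndarray
    surface_z: float
    materials: dict[int, MaterialProperties]
    removed: np.ndarray = field(default=None)  # cumulative removal mask

    def __post_init__(self) -> None:
        if self.removed is None:
            self.removed = np.zeros(self.shape, dtype=bool)

    # -- geometry helpers ---------------------------------------------------
    @property
    def surface_index(self) -> int:
        """Index of the first tissue slice along z in the original model."""
        return int(round(self.surface_z / self.voxel_size))

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        if axis < 2:  # x, y centered on 0
            return (np.arange(n) - (n - 1) / 2.0) * self.voxel_size
        return (np.arange(n) + 0.5) * self.voxel_size  # z from the top face

    def half_extent(self, axis: int) -> float:
        return self.shape[axis] * self.voxel_size / 2.0

    @property
    def tissue(self) -> MaterialProperties:
        return self.materials[TISSUE]

    @property
    def air(self) -> MaterialProperties:
        return self.materials[AIR]

    def tissue_mask(self) -> np.ndarray:
        return self.material_id == TISSUE

    def copy(self) -> "VoxelGrid":
        return replace(self, material_id=self.material_id.copy(),
                       removed=self.removed.copy())


def build_grid(
    shape: tuple[int, int, int] = (300, 300, 150),
    voxel_size: float = 0.1,
    air_thickness: float = 5.0,
    tissue_thickness: float = 10.0,
    air: MaterialProperties | None = None,
    tissue: MaterialProperties | None = None,
) -> VoxelGrid:
    """Build the layered air/tissue voxel model.

    The default geometry is a 300 x 300 x 150 lattice of 0.1 mm cubic voxels
    with 5 mm of air above 10 mm of tissue, i.e. the tissue surface at
    z = 5 mm.  The layer thicknesses must tile the z extent exactly.
    """
    nx, ny, nz = shape
    if nx <= 0 or ny <= 0 or nz <= 0 or voxel_size <= 0:
        raise ConfigurationError("grid shape and voxel size must be positive")
    if air_thickness < 0 or tissue_thickness <= 0:
        raise ConfigurationError("layer thicknesses must be positive")
    n_air = air_thickness / voxel_size
    n_tis = tissue_thickness / voxel_size
    if abs(n_air - round(n_air)) > 1e-9 or abs(n_tis - round(n_tis)) > 1e-9:
        raise ConfigurationError(
            "layer thicknesses must be integer multiples of the voxel size")
    n_air, n_tis = int(round(n_air)), int(round(n_tis))
    if n_air + n_tis != nz:
        raise ConfigurationError(
            f"air ({n_air}) + tissue ({n_tis}) slices must equal nz ({nz})")

    material_id = np.empty(shape, dtype=np.int8)
    material_id[:, :, :n_air] = AIR
    material_id[:, :, n_air:] = TISSUE
    air = air or air_properties()
    # vaporized voxels behave as air both optically and thermally
    materials = {AIR: air, TISSUE: tissue or liver_properties(),
                 VAPORIZED: air}
    return VoxelGrid(shape=shape, voxel_size=voxel_size,
                     material_id=material_id, surface_z=air_thickness,
                     materials=materials)


# ---------------------------------------------------------------------------
# optical field (DOP update)
# ---------------------------------------------------------------------------

@dataclass
class OpticalField:
    """Per-voxel optical coefficients consumed by the transport kernel.

    ``mu_s`` is the full scattering coefficient mu_s'/(1-g); air and
    vaporized voxels carry mu_a = mu_s = 0 and n = 1.
    """

    mu_a: np.ndarray
    mu_s: np.ndarray
    g: np.ndarray
    n: np.ndarray

    def mu_s_prime(self) -> np.ndarray:
        return self.mu_s * (1.0 - self.g)


def update_optical_field(grid: VoxelGrid, alpha: np.ndarray) -> OpticalField:
    """Map the damage-ratio field to per-voxel optics.

    Tissue voxels get the linear mixture of native and coagulated reduced
    scattering, ``mu_s'(alpha) = (1-alpha)*mu_s'_native + alpha*mu_s'_coag``,
    with mu_a unchanged by heating; air and vaporized voxels get air optics.

    Parameters
    ----------
    alpha : ndarray
        Thermally damaged fraction per voxel, in [0, 1].
    """
    alpha = np.asarray(alpha, dtype=np.float64)
    if alpha.shape != grid.shape:
        raise DomainError("alpha field shape does not match the grid")
    if np.any(alpha < 0.0) or np.any(alpha > 1.0):
        raise DomainError("alpha must lie in [0, 1]")

    tis = grid.tissue
    tissue_mask = grid.material_id == TISSUE
    mu_a = np.zeros(grid.shape)
    mu_s = np.zeros(grid.shape)
    g = np.zeros(grid.shape)
    n = np.ones(grid.shape)

    msp = ((1.0 - alpha) * tis.mu_s_prime_native
           + alpha * tis.mu_s_prime_coagulated)
    mu_a[tissue_mask] = tis.mu_a
    mu_s[tissue_mask] = tis.mu_s_from_reduced(msp[tissue_mask])
    g[tissue_mask] = tis.g
    n[tissue_mask] = tis.n
    return OpticalField(mu_a=mu_a, mu_s=mu_s, g=g, n=n)


def vaporize_voxels(
    grid: VoxelGrid, H: np.ndarray, H_th: float
) -> tuple[VoxelGrid, np.ndarray]:
    """Remove tissue voxels whose enthalpy reached the vaporization threshold.

    Every tissue voxel with ``H >= H_th`` (inclusive — deterministic
    tie-break) becomes a vaporized/air voxel.  The grid is updated in place;
    the returned mask is the cumulative removal mask, which is monotone
    non-decreasing across calls.  The caller is responsible for resetting the
    enthalpy of removed voxels (the vapor carries its energy away).
    """
    if H_th <= 0:
        raise DomainError("H_th must be positive")
    newly = (grid.material_id == TISSUE) & (H >= H_th)
    grid.material_id[newly] = VAPORIZED
    grid.removed |= newly
    return grid, grid.removed
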