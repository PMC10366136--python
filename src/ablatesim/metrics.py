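"""Lesion metrics and validation statistics.

Lesion sizes are measured on the zx cross-section through y = 0 (the plane
the experimental cross-sections are cut on): width is the extent along x,
depth the extent along z below the *original* tissue surface (so the
vaporization depth is the crater depth), and area the voxel count times the
voxel face area.  Widths/depths use mask bounding extents — the
reproducible in-silico analogue of tracing the lesion outline in an image
tool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .scheduler import SimulationResult
from .tissue import TISSUE, VoxelGrid


@dataclass(frozen=True)
class LesionMetrics:
    """Vaporization and coagulation extents on the y = 0 plane."""

    vaporization_width: float    # mm
    vaporization_depth: float    # mm
    vaporization_area: float     # mm^2
    coagulation_width: float     # mm
    coagulation_depth: float     # mm
    coagulation_area: float      # mm^2


def _plane_extents(plane: np.ndarray, surface_iz: int, dx: float):
    """(width, depth, area) of a 2D boolean mask on the zx plane."""
    if not plane.any():
        return 0.0, 0.0, 0.0
    xs, zs = np.nonzero(plane)
    width = (xs.max() - xs.min() + 1) * dx
    depth = (zs.max() - surface_iz + 1) * dx
    area = int(plane.sum()) * dx * dx
    return float(width), float(depth), float(area)


def lesion_metrics(result: SimulationResult) -> LesionMetrics:
    """Extract lesion extents from the removal and coagulation masks.

    The plane is the voxel row whose center is nearest y = 0 (for even grid
    sizes this is the row just on the +y side).  Coagulation is Omega >= 1
    on tissue that was not removed; removed voxels count as vaporization.
    """
    grid = result.grid
    ny = grid.shape[1]
    iy = ny // 2
    surface_iz = grid.surface_index
    dx = grid.voxel_size

    vap_plane = result.removed[:, iy, :]
    coag_plane = result.coagulated[:, iy, :]
    vw, vd, va = _plane_extents(vap_plane, surface_iz, dx)
    cw, cd, ca = _plane_extents(coag_plane, surface_iz, dx)
    return LesionMetrics(vaporization_width=vw, vaporization_depth=vd,
                         vaporization_area=va, coagulation_width=cw,
                         coagulation_depth=cd, coagulation_area=ca)


def rmspe(simulated, measured) -> float:
    """Root mean square percentage error, in percent.

    ``100 * sqrt(mean(((sim - meas) / meas)^2))``; every measured entry
    must be non-zero.
    """
    sim = np.asarray(simulated, dtype=np.float64)
    meas = np.asarray(measured, dtype=np.float64)
    if sim.shape != meas.shape:
        raise DomainError("series must have equal length")
    if np.any(meas == 0.0):
        raise DomainError("measured series contains a zero entry")
    return float(100.0 * np.sqrt(np.mean(((sim - meas) / meas) ** 2)))


def relative_difference(sim: float, ref: float) -> float:
    """Absolute relative difference 100*|sim - ref|/ref, in percent."""
    if ref <= 0:
        raise DomainError("reference value must be positive")
    return float(100.0 * abs(sim - ref) / ref)


def axial_absorption_profile(S: np.ndarray, grid: VoxelGrid):
    """Absorbed power density along z through (x, y) = (0, 0).

    Sampled from the *current* surface: the first tissue voxel of the
    central column (below any crater).  Returns ``(depth_mm, S_column)``
    with depth measured from that surface voxel's top face.
    """
    if S.shape != grid.shape:
        raise DomainError("S does not match the grid")
    ix = grid.shape[0] // 2
    iy = grid.shape[1] // 2
    column_mat = grid.material_id[ix, iy, :]
    tissue_idx = np.nonzero(column_mat == TISSUE)[0]
    start = int(tissue_idx[0]) if tissue_idx.size else grid.surface_index
    col = S[ix, iy, start:]
    depth = (np.arange(col.size) + 0.5) * grid.voxel_size
    return depth, col
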