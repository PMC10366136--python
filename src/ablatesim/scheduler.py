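"""Two-timescale coupling loop for the transient ablation simulation.

Light transport is far cheaper to refresh sparsely than heat and damage are
to integrate: the damage parameter barely changes over one transport
snapshot, so the absorbed-power field is recomputed only every ``t_heat``
seconds while the enthalpy and damage fields advance with the (much
smaller) explicit thermal step ``dt``.  One irradiation window j is:

    (a) update the per-voxel optics from the current damage-ratio field
        (the dynamic-optical-properties update) and the current structure;
    (b) Monte Carlo transport with the beam at its position at the start of
        the window, giving S;
    (c) n_sub = t_heat/dt explicit enthalpy + Arrhenius steps with S fixed;
    (d) vaporization check: tissue voxels whose enthalpy reached
        H_th = rho (c_p T_v + L_v) are removed and become air.

After the laser switches off the thermal/damage stepping continues with
S = 0 for ``t_laser_off`` — the stored heat keeps coagulating tissue while
the sample cools.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import thermal
from .damage import ArrheniusParams, alpha_from_omega
from .errors import ConfigurationError, DomainError
from .thermal import FieldState
from .tissue import (TISSUE, VoxelGrid, update_optical_field,
                     vaporize_voxels)
from .transport import BeamConfig, compute_absorption


@dataclass(frozen=True)
class ScheduleConfig:
    """Timing, photon budget and seeding of the coupling loop.

    ``t_laser_on`` is normally derived from the scan geometry
    (path length / speed) and may be left ``None``; ``t_heat`` must be an
    integer multiple of ``dt`` and must divide the irradiation time.
    """

    dt: float                    # thermal step, s
    t_heat: float                # transport refresh interval, s
    t_laser_off: float           # post-irradiation cooling time, s
    n_photons: int
    seed: int = 0
    t_laser_on: float | None = None
    snapshot_interval: float | None = None

    def resolve_t_on(self, beam: BeamConfig) -> float:
        return self.t_laser_on if self.t_laser_on is not None \
            else beam.duration

    def validate(self, beam: BeamConfig) -> None:
        if self.dt <= 0 or self.t_heat <= 0 or self.t_laser_off < 0:
            raise ConfigurationError("dt, t_heat must be > 0, t_off >= 0")
        t_on = self.resolve_t_on(beam)
        if not (self.dt <= self.t_heat <= t_on):
            raise ConfigurationError("need dt <= t_heat <= t_laser_on")
        n_sub = self.t_heat / self.dt
        if abs(n_sub - round(n_sub)) > 1e-9:
            raise ConfigurationError("t_heat must be a multiple of dt")
        if self.n_photons < 1:
            raise ConfigurationError("n_photons must be >= 1")


@dataclass
class SimulationResult:
    """Final fields, lesion masks and per-window time series of one run."""

    state: FieldState
    grid: VoxelGrid
    removed: np.ndarray          # vaporized-voxel mask
    coagulated: np.ndarray       # Omega >= 1 on remaining tissue
    series: pd.DataFrame         # one row per t_heat window
    last_absorption: np.ndarray  # S of the final irradiation window, W/mm^3
    snapshots: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)


def beam_position(t: float, beam: BeamConfig) -> tuple[float, float]:
    """Beam center at time t: linear motion along the scan segment.

    Times outside [0, path_length/speed] are clamped to the endpoints.
    """
    length = beam.path_length
    if length == 0.0:
        return beam.start_xy
    s = min(max(t * beam.speed, 0.0), length) / length
    return (beam.start_xy[0] + s * (beam.end_xy[0] - beam.start_xy[0]),
            beam.start_xy[1] + s * (beam.end_xy[1] - beam.start_xy[1]))


def _transport_seed(seed: int, j_light: int) -> int:
    """Independent, reproducible stream per transport call."""
    return int(np.random.SeedSequence([seed, j_light])
               .generate_state(1, np.uint32)[0])


def _config_hash(grid: VoxelGrid, beam: BeamConfig, schedule: ScheduleConfig,
                 arrhenius: ArrheniusParams, use_dop: bool) -> str:
    blob = json.dumps({
        "shape": grid.shape, "voxel": grid.voxel_size,
        "surface_z": grid.surface_z,
        "materials": {k: vars(v) for k, v in sorted(grid.materials.items())},
        "beam": vars(beam), "schedule": vars(schedule),
        "arrhenius": vars(arrhenius), "use_dop": use_dop,
    }, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_simulation(grid: VoxelGrid, beam: BeamConfig,
                   schedule: ScheduleConfig, arrhenius: ArrheniusParams,
                   use_dop: bool = True,
                   initial_temperature_c: float = 22.0,
                   arrhenius_cutoff_c: float = 35.0) -> SimulationResult:
    """Run the full irradiation + cooling simulation.

    ``use_dop=False`` freezes the optics at the native state (the
    static-optical-properties baseline the dynamic model is compared
    against); structure updates (vaporization) still occur.

    The run is deterministic for a fixed ``schedule.seed``: each transport
    window draws from its own stream derived from (seed, j_light).
    """
    schedule.validate(beam)
    grid = grid.copy()
    t_on = schedule.resolve_t_on(beam)
    n_sub = int(round(schedule.t_heat / schedule.dt))
    # irradiation windows cover [0, t_on]; the last one may be truncated
    n_windows = int(math.ceil(t_on / schedule.t_heat - 1e-9))
    n_cool_windows = int(math.ceil(schedule.t_laser_off / schedule.t_heat
                                   - 1e-9)) if schedule.t_laser_off > 0 else 0
    h_th = thermal.threshold_enthalpy(grid.tissue)
    air_rho_cp = grid.air.rho_cp
    t_v = grid.tissue.T_v

    state = thermal.initial_state(grid, initial_temperature_c)
    rows = []
    snapshots = []
    tallies = []
    next_snapshot = (schedule.snapshot_interval
                     if schedule.snapshot_interval is not None else np.inf)
    last_s = np.zeros(grid.shape)

    def _record(j, phase, absorbed):
        tissue_now = grid.material_id == TISSUE
        msp = np.nan
        if tissue_now.any():
            # mean reduced scattering actually used for this window
            msp = float(np.mean(
                _current_mu_s_prime(grid, state, use_dop)[tissue_now]))
        rows.append({
            "time": state.time, "phase": phase, "window": j,
            "absorbed_fraction": absorbed,
            "max_T": float(state.T.max()),
            "total_H": float(state.H.sum()) * grid.voxel_size ** 3,
            "n_coagulated": int(((state.Omega >= 1.0) & tissue_now).sum()),
            "n_removed": int(grid.removed.sum()),
            "mu_s_prime_mean": msp,
        })

    for j in range(n_windows):
        alpha = alpha_from_omega(state.Omega) if use_dop \
            else np.zeros(grid.shape)
        optics = update_optical_field(grid, alpha)
        center = beam_position(j * schedule.t_heat, beam)
        if beam.power > 0:
            field_s = compute_absorption(
                grid, optics, beam, center, schedule.n_photons,
                _transport_seed(schedule.seed, j))
            state.S = field_s.S
            absorbed = field_s.absorbed
            tallies.append({"window": j, "absorbed": field_s.absorbed,
                            "escaped": field_s.escaped,
                            "specular": field_s.specular})
            last_s = field_s.S
        else:
            state.S = np.zeros(grid.shape)
            absorbed = 0.0
        remaining = t_on - j * schedule.t_heat
        n_sub_j = n_sub if remaining >= schedule.t_heat - 1e-12 \
            else max(1, int(round(remaining / schedule.dt)))
        thermal.advance(state, grid, schedule.dt, n_sub_j, arrhenius,
                        arrhenius_cutoff_c)
        if not np.isfinite(state.H).all():
            raise DomainError(f"non-finite enthalpy at window {j}")
        _vaporize_and_reset(grid, state, h_th, air_rho_cp, t_v)
        _record(j, "on", absorbed)
        if state.time >= next_snapshot - 1e-12:
            snapshots.append((state.time, state.T.astype(np.float32),
                              state.Omega.astype(np.float32)))
            next_snapshot += schedule.snapshot_interval

    state.S = np.zeros(grid.shape)
    for j in range(n_cool_windows):
        remaining = schedule.t_laser_off - j * schedule.t_heat
        n_sub_j = n_sub if remaining >= schedule.t_heat - 1e-12 \
            else max(1, int(round(remaining / schedule.dt)))
        thermal.advance(state, grid, schedule.dt, n_sub_j, arrhenius,
                        arrhenius_cutoff_c)
        _vaporize_and_reset(grid, state, h_th, air_rho_cp, t_v)
        _record(n_windows + j, "off", 0.0)
        if state.time >= next_snapshot - 1e-12:
            snapshots.append((state.time, state.T.astype(np.float32),
                              state.Omega.astype(np.float32)))
            next_snapshot += schedule.snapshot_interval

    coagulated = (state.Omega >= 1.0) & (grid.material_id == TISSUE)
    return SimulationResult(
        state=state, grid=grid, removed=grid.removed.copy(),
        coagulated=coagulated, series=pd.DataFrame(rows),
        last_absorption=last_s, snapshots=snapshots,
        metadata={
            "seed": schedule.seed, "use_dop": use_dop,
            "config_hash": _config_hash(grid, beam, schedule, arrhenius,
                                        use_dop),
            "n_windows": n_windows, "n_cool_windows": n_cool_windows,
            "tallies": tallies,
        })


def _current_mu_s_prime(grid: VoxelGrid, state: FieldState,
                        use_dop: bool) -> np.ndarray:
    tis = grid.tissue
    if not use_dop:
        return np.full(grid.shape, tis.mu_s_prime_native)
    a = alpha_from_omega(state.Omega)
    return (1.0 - a) * tis.mu_s_prime_native + a * tis.mu_s_prime_coagulated


def _vaporize_and_reset(grid: VoxelGrid, state: FieldState, h_th: float,
                        air_rho_cp: float, t_v: float) -> None:
    before = grid.removed.copy()
    vaporize_voxels(grid, state.H, h_th)
    newly = grid.removed & ~before
    if newly.any():
        # the removed mass carries its enthalpy away; the new air voxel
        # starts at the local pre-removal temperature (the plateau T_v)
        state.H[newly] = air_rho_cp * t_v
        state.T[newly] = t_v
        state.S[newly] = 0.0
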