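"""Voxel Monte Carlo photon-packet transport.

Computes the volumetric absorbed power density S(r) (W/mm^3) for a
collimated Gaussian beam incident normally (+z) on the voxel model.  The
implementation follows standard tissue-optics photon-packet rules:

* free paths sampled as ``s = -ln(xi)/mu_t`` with ``mu_t = mu_a + mu_s``;
  at each interaction the packet deposits the fraction ``mu_a/mu_t`` of its
  weight in the current voxel (albedo weighting) and scatters into a new
  direction drawn from the Henyey-Greenstein phase function;
* unpolarized Fresnel reflection/refraction at any voxel face where the
  refractive index changes (the air-tissue surface and crater walls), with
  total internal reflection handled; the reflect/refract choice is made
  probabilistically per packet;
* Russian roulette below weight 1e-4 with survival probability 0.1
  (survivors multiplied by 10) — unbiased termination;
* packets leaving the lattice are terminated and tallied as escaped, or as
  specularly reflected if they never reached a scattering/absorbing voxel.

Energy bookkeeping: absorbed + escaped + specular equals the launched
weight up to the (zero-mean) Russian-roulette residual, which is negligible
whenever packets rarely survive to the roulette threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .errors import ConfigurationError, DomainError
from .tissue import OpticalField, VoxelGrid

WEIGHT_MIN = 1e-4
ROULETTE_SURVIVAL = 0.1


@dataclass(frozen=True)
class BeamConfig:
    """Scanned collimated Gaussian beam, normally incident on the surface.

    ``diameter_1e2`` is the 1/e^2 intensity diameter; the radial profile is
    a 2D Gaussian with standard deviation ``diameter_1e2 / 4`` (the 1/e^2
    radius equals two standard deviations).  The beam center moves at
    constant ``speed`` along the segment ``start_xy -> end_xy`` on the
    tissue surface plane.
    """

    power: float                     # W
    diameter_1e2: float              # mm
    start_xy: tuple[float, float]    # mm
    end_xy: tuple[float, float]      # mm
    speed: float                     # mm/s

    def __post_init__(self) -> None:
        if self.power < 0:
            raise ConfigurationError("beam power must be >= 0")
        if self.diameter_1e2 < 0:
            raise ConfigurationError("beam diameter must be >= 0")
        if self.speed <= 0:
            raise ConfigurationError("scan speed must be positive")

    @property
    def sigma(self) -> float:
        return self.diameter_1e2 / 4.0

    @property
    def path_length(self) -> float:
        dx = self.end_xy[0] - self.start_xy[0]
        dy = self.end_xy[1] - self.start_xy[1]
        return math.hypot(dx, dy)

    @property
    def duration(self) -> float:
        """Irradiation time implied by the scan: path length / speed."""
        return self.path_length / self.speed


@dataclass
class AbsorbedPowerField:
    """Absorbed power density plus the energy-balance tallies.

    Tallies are fractions of the launched weight (launched == 1):
    ``absorbed + escaped + specular`` equals 1 up to the Russian-roulette
    residual.  ``specular`` is the weight that exited the lattice without
    ever occupying an absorbing/scattering voxel.
    """

    S: np.ndarray          # W/mm^3
    launched: float
    absorbed: float
    escaped: float
    specular: float


def sample_beam_photon(beam: BeamConfig, center_xy: tuple[float, float],
                       rng: np.random.Generator):
    """Draw one photon packet: Gaussian radial launch offset, +z direction,
    unit weight.  Launch plane is the top of the lattice (z = 0)."""
    x, y = _sample_launch_positions(beam, center_xy, 1, rng)
    return (float(x[0]), float(y[0]), 0.0), (0.0, 0.0, 1.0), 1.0


def _sample_launch_positions(beam: BeamConfig, center_xy, n: int,
                             rng: np.random.Generator):
    offsets = rng.normal(0.0, beam.sigma, size=(2, n)) if beam.sigma > 0 \
        else np.zeros((2, n))
    return center_xy[0] + offsets[0], center_xy[1] + offsets[1]


@njit(cache=True)
def _transport_kernel(mu_a, mu_s, g_vox, n_vox, dx, x0, y0, seed,
                      w_min, p_survive):  # pragma: no cover - via wrapper
    nx, ny, nz = mu_a.shape
    half_x = nx * dx / 2.0
    half_y = ny * dx / 2.0
    s_w = np.zeros(mu_a.shape)
    absorbed = 0.0
    escaped = 0.0
    specular = 0.0
    np.random.seed(seed)

    for p in range(x0.size):
        x = x0[p]
        y = y0[p]
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        ix = int(math.floor((x + half_x) / dx))
        iy = int(math.floor((y + half_y) / dx))
        iz = 0
        if ix < 0 or ix >= nx or iy < 0 or iy >= ny:
            specular += w  # launched outside the lattice footprint
            continue
        entered = mu_a[ix, iy, iz] + mu_s[ix, iy, iz] > 0.0
        tau = -math.log(np.random.random())
        alive = True
        while alive:
            mt = mu_a[ix, iy, iz] + mu_s[ix, iy, iz]
            # distance to the nearest voxel face along the direction
            db = 1e30
            axis = -1
            step = 0
            if ux > 0.0:
                t = ((ix + 1) * dx - half_x - x) / ux
                if t < db:
                    db, axis, step = t, 0, 1
            elif ux < 0.0:
                t = (ix * dx - half_x - x) / ux
                if t < db:
                    db, axis, step = t, 0, -1
            if uy > 0.0:
                t = ((iy + 1) * dx - half_y - y) / uy
                if t < db:
                    db, axis, step = t, 1, 1
            elif uy < 0.0:
                t = (iy * dx - half_y - y) / uy
                if t < db:
                    db, axis, step = t, 1, -1
            if uz > 0.0:
                t = ((iz + 1) * dx - z) / uz
                if t < db:
                    db, axis, step = t, 2, 1
            elif uz < 0.0:
                t = (iz * dx - z) / uz
                if t < db:
                    db, axis, step = t, 2, -1
            if db < 0.0:
                db = 0.0

            ds = tau / mt if mt > 0.0 else 1e30
            if ds <= db:
                # interaction inside the current voxel
                x += ux * ds
                y += uy * ds
                z += uz * ds
                dep = w * mu_a[ix, iy, iz] / mt
                s_w[ix, iy, iz] += dep
                absorbed += dep
                w -= dep
                entered = True
                if w <= 0.0:
                    break
                if w < w_min:
                    if np.random.random() < p_survive:
                        w /= p_survive
                    else:
                        break  # roulette kill: weight lost (zero-mean)
                # Henyey-Greenstein scatter
                g = g_vox[ix, iy, iz]
                if g != 0.0:
                    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * np.random.random())
                    ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                else:
                    ct = 2.0 * np.random.random() - 1.0
                if ct > 1.0:
                    ct = 1.0
                elif ct < -1.0:
                    ct = -1.0
                st = math.sqrt(1.0 - ct * ct)
                phi = 2.0 * math.pi * np.random.random()
                cp = math.cos(phi)
                sp = math.sin(phi)
                if abs(uz) > 0.99999:
                    ux = st * cp
                    uy = st * sp
                    uz = ct if uz > 0.0 else -ct
                else:
                    den = math.sqrt(1.0 - uz * uz)
                    nux = st * (ux * uz * cp - uy * sp) / den + ux * ct
                    nuy = st * (uy * uz * cp + ux * sp) / den + uy * ct
                    nuz = -den * st * cp + uz * ct
                    ux, uy, uz = nux, nuy, nuz
                norm = math.sqrt(ux * ux + uy * uy + uz * uz)
                ux /= norm
                uy /= norm
                uz /= norm
                tau = -math.log(np.random.random())
            else:
                # advance to the face and cross (or reflect/refract)
                x += ux * db
                y += uy * db
                z += uz * db
                if mt > 0.0:
                    tau -= db * mt
                    if tau < 0.0:
                        tau = 0.0
                jx, jy, jz = ix, iy, iz
                if axis == 0:
                    jx += step
                elif axis == 1:
                    jy += step
                else:
                    jz += step
                if jx < 0 or jx >= nx or jy < 0 or jy >= ny \
                        or jz < 0 or jz >= nz:
                    # open lattice boundary: terminate
                    if entered:
                        escaped += w
                    else:
                        specular += w
                    break
                n1 = n_vox[ix, iy, iz]
                n2 = n_vox[jx, jy, jz]
                if n1 != n2:
                    if axis == 0:
                        ci = abs(ux)
                    elif axis == 1:
                        ci = abs(uy)
                    else:
                        ci = abs(uz)
                    eta = n1 / n2
                    st2 = eta * eta * (1.0 - ci * ci)
                    if st2 >= 1.0:
                        refl = 1.0  # total internal reflection
                        ct2 = 0.0
                    else:
                        ct2 = math.sqrt(1.0 - st2)
                        rs = (n1 * ci - n2 * ct2) / (n1 * ci + n2 * ct2)
                        rp = (n1 * ct2 - n2 * ci) / (n1 * ct2 + n2 * ci)
                        refl = 0.5 * (rs * rs + rp * rp)
                    if np.random.random() < refl:
                        if axis == 0:
                            ux = -ux
                        elif axis == 1:
                            uy = -uy
                        else:
                            uz = -uz
                    else:
                        # refract: scale tangential components, keep sign
                        if axis == 0:
                            uy *= eta
                            uz *= eta
                            ux = ct2 if ux > 0.0 else -ct2
                        elif axis == 1:
                            ux *= eta
                            uz *= eta
                            uy = ct2 if uy > 0.0 else -ct2
                        else:
                            ux *= eta
                            uy *= eta
                            uz = ct2 if uz > 0.0 else -ct2
                        norm = math.sqrt(ux * ux + uy * uy + uz * uz)
                        ux /= norm
                        uy /= norm
                        uz /= norm
                        ix, iy, iz = jx, jy, jz
                        if mu_a[ix, iy, iz] + mu_s[ix, iy, iz] > 0.0:
                            entered = True
                else:
                    ix, iy, iz = jx, jy, jz
                    if mu_a[ix, iy, iz] + mu_s[ix, iy, iz] > 0.0:
                        entered = True
    return s_w, absorbed, escaped, specular


def compute_absorption(grid: VoxelGrid, optics: OpticalField,
                       beam: BeamConfig, center_xy: tuple[float, float],
                       n_photons: int, seed: int) -> AbsorbedPowerField:
    """Monte Carlo estimate of the absorbed power density field.

    The returned ``S`` is scaled so that ``sum(S) * voxel_volume`` equals
    ``beam.power`` times the absorbed fraction of the launched weight.
    Deterministic for a fixed seed.
    """
    if n_photons < 1:
        raise DomainError("n_photons must be >= 1")
    if any(s <= 0 for s in grid.shape):
        raise ConfigurationError("zero-size grid")
    if optics.mu_a.shape != grid.shape:
        raise ConfigurationError("optical field does not match the grid")

    reach = 2.0 * beam.sigma * 2.0  # 2x the 1/e^2 radius
    if (abs(center_xy[0]) - reach > grid.half_extent(0)
            or abs(center_xy[1]) - reach > grid.half_extent(1)):
        warnings.warn("beam footprint lies entirely outside the grid; S = 0",
                      stacklevel=2)
        return AbsorbedPowerField(S=np.zeros(grid.shape), launched=1.0,
                                  absorbed=0.0, escaped=0.0, specular=1.0)

    ss = np.random.SeedSequence(seed)
    launch_ss, kernel_ss = ss.spawn(2)
    rng = np.random.default_rng(launch_ss)
    x0, y0 = _sample_launch_positions(beam, center_xy, n_photons, rng)
    kernel_seed = int(kernel_ss.generate_state(1, np.uint32)[0])

    s_w, absorbed, escaped, specular = _transport_kernel(
        np.ascontiguousarray(optics.mu_a), np.ascontiguousarray(optics.mu_s),
        np.ascontiguousarray(optics.g), np.ascontiguousarray(optics.n),
        grid.voxel_size, np.ascontiguousarray(x0), np.ascontiguousarray(y0),
        kernel_seed, WEIGHT_MIN, ROULETTE_SURVIVAL)

    voxel_volume = grid.voxel_size ** 3
    scale = beam.power / (n_photons * voxel_volume)
    return AbsorbedPowerField(S=s_w * scale, launched=1.0,
                              absorbed=absorbed / n_photons,
                              escaped=escaped / n_photons,
                              specular=specular / n_photons)
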