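"""Self-contained simulation scenarios and synthetic reference data.

Two families are provided:

* the six full-scale study conditions — a 980 nm collimated Gaussian beam
  (1/e^2 diameter 2.8 mm) scanned 20 mm across porcine-liver-like tissue on
  the 300 x 300 x 150 grid of 0.1 mm voxels, at 50 W x {0.5, 0.75, 1.0}
  mm/s (coagulation + vaporization expected) and 10 W x {1.0, 1.25, 1.5}
  mm/s (coagulation only);
* scaled twins of each, sized for desk runtimes: the same power, beam
  diameter and scan speed (hence the same fluence per unit area), but a
  shortened 3 mm scan on a small 0.2 mm-voxel grid with a coarser
  transport-refresh interval.  The twins preserve the qualitative
  with/without-DOP contrast, not absolute lesion sizes.

All property values are literature-style placeholders (see
:func:`ablatesim.tissue.liver_properties`) and every scenario passes full
configuration validation at construction.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .damage import ArrheniusParams, alpha_from_omega, penetration_depth
from .errors import ConfigurationError
from .scheduler import ScheduleConfig, SimulationResult, run_simulation
from .tissue import (MaterialProperties, VoxelGrid, air_properties,
                     build_grid, liver_properties)
from .thermal import grid_stability_limit
from .transport import BeamConfig

#: Henriques-style liver placeholder kinetics (A in 1/s, Ea in J/mol)
DEFAULT_ARRHENIUS = ArrheniusParams(A=7.39e39, E_a=2.577e5)

OUTCOME_NONE = "none"
OUTCOME_COAGULATION = "coagulation_only"
OUTCOME_BOTH = "coagulation_and_vaporization"


@dataclass(frozen=True)
class Scenario:
    """A complete, validated simulation configuration."""

    name: str
    shape: tuple[int, int, int]
    voxel_size: float
    air_thickness: float
    tissue_thickness: float
    air: MaterialProperties
    tissue: MaterialProperties
    beam: BeamConfig
    schedule: ScheduleConfig
    arrhenius: ArrheniusParams
    expected_outcome: str = OUTCOME_NONE
    scale: str = "full"          # "full" | "scaled" | "mini"

    def __post_init__(self) -> None:
        grid = self.build_grid()
        self.schedule.validate(self.beam)
        limit = grid_stability_limit(grid)
        if self.schedule.dt > limit:
            raise ConfigurationError(
                f"{self.name}: dt {self.schedule.dt:g}s exceeds the "
                f"stability limit {limit:g}s")
        # the tissue slab must stay optically semi-infinite with respect to
        # the coagulated-state penetration depth, like the full-scale model
        delta = penetration_depth(self.tissue.mu_a,
                                  self.tissue.mu_s_prime_coagulated)
        if self.tissue_thickness < 2.0 * delta:
            raise ConfigurationError(
                f"{self.name}: tissue slab thinner than 2 penetration depths")

    def build_grid(self) -> VoxelGrid:
        return build_grid(self.shape, self.voxel_size, self.air_thickness,
                          self.tissue_thickness, air=self.air,
                          tissue=self.tissue)

    def run(self, use_dop: bool = True, seed: int | None = None,
            n_photons: int | None = None) -> SimulationResult:
        schedule = self.schedule
        if seed is not None or n_photons is not None:
            schedule = dataclasses.replace(
                schedule,
                seed=schedule.seed if seed is None else seed,
                n_photons=schedule.n_photons if n_photons is None
                else n_photons)
        return run_simulation(self.build_grid(), self.beam, schedule,
                              self.arrhenius, use_dop=use_dop)


def _full_scenario(power: float, speed: float, outcome: str,
                   t_laser_off: float) -> Scenario:
    return Scenario(
        name=f"full_{power:g}W_{speed:g}mmps",
        shape=(300, 300, 150), voxel_size=0.1,
        air_thickness=5.0, tissue_thickness=10.0,
        air=air_properties(), tissue=liver_properties(),
        beam=BeamConfig(power=power, diameter_1e2=2.8,
                        start_xy=(0.0, -10.0), end_xy=(0.0, 10.0),
                        speed=speed),
        schedule=ScheduleConfig(dt=1.0e-5, t_heat=2.0e-3,
                                t_laser_off=t_laser_off,
                                n_photons=10_000_000, seed=0),
        arrhenius=DEFAULT_ARRHENIUS,
        expected_outcome=outcome, scale="full")


def _scaled_twin(power: float, speed: float, outcome: str,
                 t_laser_off: float) -> Scenario:
    # 5.6 x 5.6 x 4.4 mm at 0.2 mm voxels: 1 mm air over a 3.4 mm slab
    # (still > 2 coagulated penetration depths deep); 3 mm scan centered on
    # the surface; coarser transport refresh keeps the beam motion per
    # window well below the beam diameter.
    return Scenario(
        name=f"scaled_{power:g}W_{speed:g}mmps",
        shape=(28, 28, 22), voxel_size=0.2,
        air_thickness=1.0, tissue_thickness=3.4,
        air=air_properties(), tissue=liver_properties(),
        beam=BeamConfig(power=power, diameter_1e2=2.8,
                        start_xy=(0.0, -1.5), end_xy=(0.0, 1.5),
                        speed=speed),
        schedule=ScheduleConfig(dt=2.0e-4, t_heat=0.1,
                                t_laser_off=t_laser_off,
                                n_photons=10_000, seed=0),
        arrhenius=DEFAULT_ARRHENIUS,
        expected_outcome=outcome, scale="scaled")


def make_paper_scenarios() -> list[Scenario]:
    """The six full-scale study conditions plus their scaled twins.

    High power (50 W, speeds 0.5/0.75/1.0 mm/s) is expected to produce both
    coagulation and vaporization; low power (10 W, speeds 1.0/1.25/1.5
    mm/s) coagulation only.  Cooling phases are 30 s (high) and 10 s (low)
    full scale, shortened proportionally on the twins.
    """
    scenarios: list[Scenario] = []
    for speed in (0.5, 0.75, 1.0):
        scenarios.append(_full_scenario(50.0, speed, OUTCOME_BOTH, 30.0))
    for speed in (1.0, 1.25, 1.5):
        scenarios.append(_full_scenario(10.0, speed, OUTCOME_COAGULATION,
                                        10.0))
    for speed in (0.5, 0.75, 1.0):
        scenarios.append(_scaled_twin(50.0, speed, OUTCOME_BOTH, 3.0))
    for speed in (1.0, 1.25, 1.5):
        scenarios.append(_scaled_twin(10.0, speed, OUTCOME_COAGULATION, 1.5))
    return scenarios


def get_scenario(name: str) -> Scenario:
    for sc in make_paper_scenarios():
        if sc.name == name:
            return sc
    raise KeyError(name)


def make_mini_scenario(power: float = 30.0, speed: float = 1.0,
                       seed: int = 0) -> Scenario:
    """A seconds-scale smoke scenario for tests and CLI examples."""
    return Scenario(
        name=f"mini_{power:g}W_{speed:g}mmps",
        shape=(16, 16, 18), voxel_size=0.2,
        air_thickness=0.6, tissue_thickness=3.0,
        air=air_properties(), tissue=liver_properties(),
        beam=BeamConfig(power=power, diameter_1e2=1.4,
                        start_xy=(0.0, -0.2), end_xy=(0.0, 0.2),
                        speed=speed),
        schedule=ScheduleConfig(dt=2.0e-4, t_heat=0.1, t_laser_off=0.2,
                                n_photons=2000, seed=seed),
        arrhenius=DEFAULT_ARRHENIUS,
        expected_outcome=OUTCOME_NONE, scale="mini")


def make_dop_reference_curve(
    native: float, coagulated: float,
    omegas=(0, 1, 2, 3, 4, 5),
) -> pd.DataFrame:
    """Reduced scattering versus damage parameter under the mixing model.

    Evaluates ``mu_s'(Omega) = (1-alpha) native + alpha coagulated`` with
    ``alpha = 1 - exp(-Omega)`` — the regression fixture for the
    damage-vs-optics validation curve.  The increment between successive
    Omega rows shrinks as Omega grows (exponential saturation).
    """
    if coagulated < native:
        raise ConfigurationError("coagulated mu_s' must be >= native")
    om = np.asarray(omegas, dtype=np.float64)
    alpha = alpha_from_omega(om)
    msp = (1.0 - alpha) * native + alpha * coagulated
    return pd.DataFrame({"omega": om, "alpha": alpha, "mu_s_prime": msp})


# ---------------------------------------------------------------------------
# YAML serialization (the config documents the CLI consumes)
# ---------------------------------------------------------------------------

def scenario_to_yaml(scenario: Scenario) -> str:
    def clean(d):
        return {k: (None if isinstance(v, float) and math.isinf(v) else v)
                for k, v in d.items()}

    doc = {
        "name": scenario.name,
        "grid": {"shape": list(scenario.shape),
                 "voxel_size": scenario.voxel_size,
                 "air_thickness": scenario.air_thickness,
                 "tissue_thickness": scenario.tissue_thickness},
        "air": clean(dataclasses.asdict(scenario.air)),
        "tissue": clean(dataclasses.asdict(scenario.tissue)),
        "beam": {**dataclasses.asdict(scenario.beam),
                 "start_xy": list(scenario.beam.start_xy),
                 "end_xy": list(scenario.beam.end_xy)},
        "schedule": dataclasses.asdict(scenario.schedule),
        "arrhenius": dataclasses.asdict(scenario.arrhenius),
        "expected_outcome": scenario.expected_outcome,
        "scale": scenario.scale,
    }
    return yaml.safe_dump(doc, sort_keys=False)


def scenario_from_yaml(text: str) -> Scenario:
    doc = yaml.safe_load(text)

    def mat(d):
        d = dict(d)
        if d.get("T_v") is None:
            d["T_v"] = math.inf
        return MaterialProperties(**d)

    return Scenario(
        name=doc["name"],
        shape=tuple(doc["grid"]["shape"]),
        voxel_size=doc["grid"]["voxel_size"],
        air_thickness=doc["grid"]["air_thickness"],
        tissue_thickness=doc["grid"]["tissue_thickness"],
        air=mat(doc["air"]),
        tissue=mat(doc["tissue"]),
        beam=BeamConfig(**{**doc["beam"],
                           "start_xy": tuple(doc["beam"]["start_xy"]),
                           "end_xy": tuple(doc["beam"]["end_xy"])}),
        schedule=ScheduleConfig(**doc["schedule"]),
        arrhenius=ArrheniusParams(**doc["arrhenius"]),
        expected_outcome=doc.get("expected_outcome", OUTCOME_NONE),
        scale=doc.get("scale", "full"))
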