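import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ablatesim as ab

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def liver():
    return ab.liver_properties()


@pytest.fixture(scope="session")
def air():
    return ab.air_properties()


@pytest.fixture()
def small_grid():
    """20x20x20 grid of 0.2 mm voxels: 1 mm air over 3 mm tissue."""
    return ab.build_grid((20, 20, 20), 0.2, 1.0, 3.0)


@pytest.fixture(scope="session")
def mini_result():
    """One completed mini-scenario run shared by read-only tests."""
    return ab.make_mini_scenario().run(seed=7)


def pure_absorber(mu_a=1.0, n=1.0):
    """Scattering-free tissue for Beer-Lambert style checks."""
    return ab.liver_properties(mu_a=mu_a, mu_s_prime_native=0.0,
                               mu_s_prime_coagulated=0.0, n=n)


def make_result(grid, removed=None, coagulated=None):
    """Assemble a SimulationResult around hand-built masks."""
    import pandas as pd

    from ablatesim.scheduler import SimulationResult
    from ablatesim.thermal import initial_state

    state = initial_state(grid)
    if removed is None:
        removed = np.zeros(grid.shape, dtype=bool)
    if coagulated is None:
        coagulated = np.zeros(grid.shape, dtype=bool)
    return SimulationResult(state=state, grid=grid, removed=removed,
                            coagulated=coagulated, series=pd.DataFrame(),
                            last_absorption=state.S)
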