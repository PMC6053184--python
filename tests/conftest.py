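import numpy as np
import pytest

from daphnia_hybrids import (
    ModelParameters,
    SeasonCalendar,
    annual_statistics,
    build_scenario,
    integrate,
)


@pytest.fixture(scope="session")
def params():
    return ModelParameters()

@pytest.fixture(scope="session")
def calendar():
    return SeasonCalendar()


@pytest.fixture(scope="session")
def baseline_run():
    """Scenario A, reference parameters, no winter advantage, 100 years.

    Shared across tests: the baseline competition outcome between the two
    parental species and F1-hybrids.
    """
    traj = integrate(build_scenario("A"))
    return traj, annual_statistics(traj)


def constant_trajectory(active_per_class, years=2, samples_per_year=366):
    """Synthetic trajectory with constant per-class active densities.

    Splits each class's active density equally between A and S so that
    summary statistics on A+S see exactly the requested constants.
    """
    from daphnia_hybrids.simulate import SolverSettings, Trajectory

    active = np.asarray(active_per_class, dtype=float)
    t = np.linspace(0.0, years * 365.0, years * samples_per_year + 1)
    states = np.zeros((len(t), 18))
    states[:, 0:6] = 0.5 * active
    states[:, 6:12] = 0.5 * active
    spec = build_scenario("A", horizon_years=years)
    return Trajectory(times=t, states=states, spec=spec, settings=SolverSettings())
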