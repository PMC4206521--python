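import numpy as np
import pytest
from hypothesis import settings

import hifshuttle as hs

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params():
    return hs.KineticParameters()


@pytest.fixture(scope="session")
def normoxic_eq(default_params):
    """Normoxic stationary state under default parameters."""
    return hs.steady_state(default_params, hs.NORMOXIC_K_FORM)


@pytest.fixture(scope="session")
def chase_traj(default_params):
    """Default cycloheximide chase: 6 h at 1-min sampling."""
    return hs.cycloheximide_chase(default_params)


@pytest.fixture(scope="session")
def reox_traj(default_params):
    """Default reoxygenation run: 30 h hypoxia (k_form = 1), 30 h reoxygenation."""
    return hs.reoxygenation_protocol(default_params, k_form_hypoxic=1.0)


def synthetic_trajectory(times, series, params=None):
    """A Trajectory whose nuclear free HiF-1α carries an arbitrary series."""
    times = np.asarray(times, dtype=float)
    series = np.asarray(series, dtype=float)
    states = np.zeros((times.size, 7))
    states[:, 0] = series
    return hs.Trajectory(
        times, states, hs.OxygenSchedule.constant(hs.NORMOXIC_K_FORM),
        params or hs.KineticParameters(),
    )
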