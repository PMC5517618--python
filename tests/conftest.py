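import numpy as np
import pytest

from myoburst import StimulusProtocol, make_parameters, run_simulation
from myoburst.model import find_resting_state


@pytest.fixture(scope="session")
def wt_params():
    return make_parameters("wt")


@pytest.fixture(scope="session")
def tg_params():
    return make_parameters("tg")


@pytest.fixture(scope="session")
def wt_rest(wt_params):
    return find_resting_state(wt_params)


@pytest.fixture(scope="session")
def tg_rest(tg_params):
    return find_resting_state(tg_params)


@pytest.fixture(scope="session")
def wt_paced_2s(wt_params, wt_rest):
    """2-s WT pacing at BCL 100 ms (20 beats); the workhorse short trace."""
    protocol = StimulusProtocol.pulsed(bcl=100.0, total_duration=2.0,
                                       analysis_window=(0.5, 2.0))
    return run_simulation(wt_params, protocol, initial=wt_rest)


def synthetic_square_train(period_ms=100.0, high_ms=2.0, duration_ms=2000.0,
                           dt=0.05, low=-80.0, high=20.0):
    """Square-wave spike train with crossings known in closed form."""
    t = np.arange(0.0, duration_ms, dt)
    v = np.where((t % period_ms) < high_ms, high, low).astype(float)
    return t, v
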