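import numpy as np
import pytest

from polopulse import default_parameters, run_two_cycle


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def imposed_cycle(params):
    """Second-cycle trajectory of the two-cycle protocol, imposed pulse."""
    return run_two_cycle(params, mode="imposed")


@pytest.fixture(scope="session")
def coupled_cycle(params):
    """Second-cycle trajectory of the two-cycle protocol, coupled mode."""
    return run_two_cycle(params, mode="coupled")


def end_of_s_index(traj):
    return int(np.argmin(np.abs(traj.times - traj.s_phase_min)))
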