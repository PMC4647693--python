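import numpy as np
import pytest

import apckinetics as ak


@pytest.fixture(scope="session")
def grid():
    return ak.build_grid()


@pytest.fixture(scope="session")
def one_sub_scan(grid):
    """Full 25x25 one-substrate scan at the default conditions.

    k_a = 0.01 /(nM s), linear APC/C input at 0.06 nM/s, S0 = 200 nM,
    e = 1000 /s, 3000-s horizon.
    """
    return ak.scan(grid)


@pytest.fixture(scope="session")
def const_apc_scan(grid):
    """Same scan with constant 100 nM APC/C instead of linear accumulation."""
    base = ak.RateParameters(apc_mode="constant", A_const=100.0)
    return ak.scan(grid, base_params=base)


@pytest.fixture(scope="session")
def catalytic_scan(grid):
    """Full-grid two-substrate scan, catalytic scenario (k_c_C = 10 k_c_S)."""
    return ak.scan_two_substrate(grid, "catalytic")


@pytest.fixture(scope="session")
def affinity_scan(grid):
    """Full-grid two-substrate scan, affinity scenario (k_d_C = k_d_S / 10)."""
    return ak.scan_two_substrate(grid, "affinity")


@pytest.fixture
def exp_decay_timecourse():
    """A fabricated time course whose total substrate decays as 200 e^(-0.01 t)."""
    times = np.arange(0.0, 1001.0)
    states = np.zeros((times.size, len(ak.SPECIES_ONE)))
    states[:, 1] = 200.0 * np.exp(-0.01 * times)  # all mass parked in S0
    params = ak.RateParameters()
    return ak.TimeCourse(times=times, states=states, species=ak.SPECIES_ONE,
                         params=params)
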