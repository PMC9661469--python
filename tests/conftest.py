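import numpy as np
import pytest

from kroghpk import (TransportParameters, build_grid, make_scenario,
                     simulate)


@pytest.fixture(scope="session")
def params():
    return TransportParameters()


@pytest.fixture(scope="session")
def grid(params):
    return build_grid(params.R_c, params.R_k, 200)


@pytest.fixture(scope="session")
def coarse_grid(params):
    return build_grid(params.R_c, params.R_k, 40)


@pytest.fixture(scope="session")
def carrier_rapid(params):
    return make_scenario("carrier_rapid", dose=params.V_sys, f_seq=0.6)


@pytest.fixture(scope="session")
def default_result(params, grid, carrier_rapid):
    """One carrier_rapid run on the default parameters, reused across tests."""
    t_eval = np.arange(0.0, 180.5, 0.5)
    return simulate(params, carrier_rapid, grid, t_eval)
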