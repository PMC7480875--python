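import numpy as np
import pytest

import gridbandits as gb


@pytest.fixture(scope="session")
def smooth_envs():
    return gb.generate_environment_set(4.0, 40, seed=101)


@pytest.fixture(scope="session")
def rough_envs():
    return gb.generate_environment_set(2.0, 40, seed=102)


@pytest.fixture(scope="session")
def gp_params():
    return gb.ParamSet(model="gp", lambda_=1.0, beta=0.5, tau=0.05)


@pytest.fixture(scope="session")
def bmt_params():
    return gb.ParamSet(model="bmt", theta_eps2=16.0, beta=0.01, tau=0.03)


@pytest.fixture(scope="session")
def gp_dataset(gp_params, smooth_envs):
    return gb.simulate_agent(gp_params, smooth_envs, seed=11,
                             participant_id="gp-agent")


@pytest.fixture(scope="session")
def bmt_dataset(bmt_params, smooth_envs):
    return gb.simulate_agent(bmt_params, smooth_envs, seed=12,
                             participant_id="bmt-agent")
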