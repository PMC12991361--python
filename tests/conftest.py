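import numpy as np
import pytest

import gazerl as g


@pytest.fixture(scope="session")
def exp1_design():
    return g.build_design("exp1", seed=11)


@pytest.fixture(scope="session")
def exp2_design():
    return g.build_design("exp2", seed=11)


@pytest.fixture(scope="session")
def exp2_agent(exp2_design):
    """One simulated participant on the two-option task (model 8)."""
    params = g.Params(
        alpha=0.15, wrel=0.66, beta_q=0.47, beta_gaze=0.28, theta=8.82,
        A=562.17, b_sep=431.47, t0=139.61,
    )
    outcomes = g.generate_outcomes(exp2_design, seed=21)
    trials = g.simulate_agent(exp2_design, outcomes, params, 8, seed=22)
    return params, trials


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
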