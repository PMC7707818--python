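import numpy as np
import pytest

import rsgp_timing as rt
from rsgp_timing import rsgp


@pytest.fixture(scope="session")
def ground_truth() -> rt.RSGPParams:
    return rt.RSGPParams(*rt.TABLE_GROUND_TRUTH)


@pytest.fixture(scope="session")
def rsgp_sessions(ground_truth):
    """Four staircase sessions of the RSGP agent, one context, 1500 trials.

    Shared by the statistics and acceptance tests; generating these dominates
    the suite's runtime, so they are built once.
    """
    return [
        rt.simulate_session(
            lambda c: rsgp.RSGPAgent(c, ground_truth),
            contexts=[rt.MONKEY_CONTEXTS[0]],
            n_trials=1500,
            seed=300 + k,
        )
        for k in range(4)
    ]


@pytest.fixture(scope="session")
def rsgp_session(rsgp_sessions):
    return rsgp_sessions[0]


@pytest.fixture(scope="session")
def interleaved_session(ground_truth):
    """Eye-Short and Hand-Short randomly interleaved (independent agents)."""
    return rt.simulate_session(
        lambda c: rsgp.RSGPAgent(c, ground_truth),
        contexts=[rt.MONKEY_CONTEXTS[0], rt.MONKEY_CONTEXTS[2]],
        n_trials=2000,
        seed=5,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
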