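import numpy as np
import pytest

from pppgame import StrategyState, baseline_parameters
from pppgame.synthetic import RegimeSpec, sample_parameters


@pytest.fixture(scope="session")
def baseline():
    return baseline_parameters()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_params(seed: int):
    """An unconstrained-but-valid random parameter set (helper, not fixture)."""
    return sample_parameters(RegimeSpec(regime="unconstrained", seed=seed))


def random_state(rng) -> StrategyState:
    return StrategyState(*rng.uniform(0.0, 1.0, size=3))
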