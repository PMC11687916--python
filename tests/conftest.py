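import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from matchmomentum.momentum import MomentumParams
from matchmomentum.simulate import SimulationConfig, simulate_corpus, simulate_match


@pytest.fixture(scope="session")
def params() -> MomentumParams:
    return MomentumParams.default()


@pytest.fixture(scope="session")
def sim_match():
    """One deterministic best-of-3 simulated match with ground truth."""
    return simulate_match(SimulationConfig(seed=123, best_of=3))


@pytest.fixture(scope="session")
def sim_match_bo5():
    return simulate_match(SimulationConfig(seed=321, best_of=5))


@pytest.fixture(scope="session")
def sim_corpus():
    """Twenty deterministic matches (match, ground truth) pairs."""
    return simulate_corpus(20, seed=11)
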