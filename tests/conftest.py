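import numpy as np
import pytest

from cgpval.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_sim():
    """Small decoy count keeps table-level tests quick."""
    return SimulationConfig(seed=7, n_decoy_loci=50)
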