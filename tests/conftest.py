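import numpy as np
import pytest

from brasskit.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def genome():
    """One moderately sized simulated genome shared across tests."""
    return simulate_all(SimulationConfig(seed=11, n_scaffolds=40), n_pairs=2000, n_cds=40)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
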