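import numpy as np
import pytest

from vagv6 import synthetic


@pytest.fixture(scope="session")
def panel():
    return synthetic.default_panel()


@pytest.fixture(scope="session")
def archetypes(panel):
    return synthetic.default_archetypes(panel)


@pytest.fixture(scope="session")
def default_cohort(panel):
    """Full-size synthetic cohort at a fixed seed (count level, no reads)."""
    cfg = synthetic.SimulationConfig(seed=11)
    return synthetic.simulate_cohort(cfg, panel=panel)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
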