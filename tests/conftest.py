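import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def standard_fixture():
    """The standard synthetic benchmark genome: 300 kb, 20 LTR elements at
    ages 0.5/1/2/3 Myr, 10 tandem arrays, 5 LINE and 5 DNA decoys."""
    from gsevol.simulate import SimulationConfig, simulate_genome

    config = SimulationConfig(seed=7)
    genome, truth, library = simulate_genome(config)
    return config, genome, truth, library
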