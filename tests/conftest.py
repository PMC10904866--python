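import numpy as np
import pytest

from drscreen import PopulationSpec, generate_population
from drscreen.fuzzy import build_default_components


@pytest.fixture(scope="session")
def components():
    return build_default_components()


@pytest.fixture(scope="session")
def small_roster():
    """A 2,000-agent roster shared by the simulation-level tests."""
    rng = np.random.default_rng(42)
    return generate_population(PopulationSpec(total_size=2000), rng)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
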