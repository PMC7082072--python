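import warnings

import numpy as np
import pytest

from conefate.simconfig import SimConfig
from conefate.synthetic import GeneratorParams, generate_cell_table

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def default_table():
    """Full default synthetic mean-retina table (fixed seed)."""
    return generate_cell_table(GeneratorParams(seed=11))


@pytest.fixture(scope="session")
def small_table():
    """Small, fast synthetic table for plumbing tests."""
    return generate_cell_table(GeneratorParams(seed=3, strip_length_um=1200.0, strip_width_um=200.0))


@pytest.fixture()
def tiny_sim_config():
    """Narrow-strip simulation configuration for fast end-to-end runs."""
    return SimConfig(domain_width_um=100.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
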