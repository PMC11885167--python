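import numpy as np
import pytest

from ptjpl import ForcingConfig, generate_grid_forcing


@pytest.fixture(scope="session")
def tiny_config():
    """4x4 grid over three non-leap years: fast, no Feb-29 edge cases."""
    return ForcingConfig(rows=4, cols=4, start_year=2001, end_year=2003, seed=7)


@pytest.fixture(scope="session")
def tiny_cube(tiny_config):
    return generate_grid_forcing(tiny_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
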