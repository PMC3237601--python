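import numpy as np
import pytest

from pairface.simulate import FixtureConfig, generate_fixture_set


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def small_fixture_set():
    """Six default-condition synthetic complexes with truth tables and PSSMs."""
    config = FixtureConfig(seed=7, n_complexes=6)
    structures, tables, pssms = generate_fixture_set(config)
    return config, structures, tables, pssms
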