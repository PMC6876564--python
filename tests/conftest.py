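import numpy as np
import pytest
from hypothesis import settings

from paiso.synthetic import SimConfig, generate_dataset

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def sim_small(tmp_path_factory):
    """A small simulated dataset with files on disk, shared across tests."""
    out = tmp_path_factory.mktemp("sim_small")
    config = SimConfig(seed=42, n_reads=300, n_genes=12)
    return generate_dataset(config, out)


@pytest.fixture(scope="session")
def sim_clean(tmp_path_factory):
    """Error-free, modification-free dataset: every tail is pure A."""
    out = tmp_path_factory.mktemp("sim_clean")
    config = SimConfig(
        seed=7,
        n_reads=200,
        n_genes=10,
        mod_rate=0.0,
        terminal_mod_rate=0.0,
        concatemer_rate=0.0,
    )
    return generate_dataset(config, out)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
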