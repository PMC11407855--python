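import numpy as np
import pytest

from asecross.synthetic_data import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=11, n_genes=150, n_crosses=4, n_unphased=1)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    """A small but complete synthetic cohort shared across test modules."""
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_bundle_dir(small_bundle, tmp_path_factory):
    from asecross.synthetic_data import write_bundle

    out = tmp_path_factory.mktemp("bundle")
    write_bundle(small_bundle, out)
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
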