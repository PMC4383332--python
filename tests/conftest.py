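import numpy as np
import pytest

from wildqtl.synthetic_data import generate_dataset, preset_config


@pytest.fixture(scope="session")
def small_dataset():
    """A small baboon-like dataset shared across read-only tests."""
    cfg = preset_config("baboon", seed=11, n_genes=40)
    return generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
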