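import numpy as np
import pytest

from promobind import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_peaks_dataset():
    """Full-size dataset with peaks/expression only (no tracks/sequence);
    shared across tests that check sampling-level parameter recovery."""
    cfg = SyntheticConfig(seed=11, include_signal=False, include_sequence=False)
    return cfg, generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_genome_dataset():
    """Mid-size dataset including genome sequence for motif tests."""
    cfg = SyntheticConfig(n_promoters=2000, seed=7, include_signal=False)
    return cfg, generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
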