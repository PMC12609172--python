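import numpy as np
import pytest

from dsadeepfm import ModelConfig, SyntheticConfig, generate_dataset

SMALL_MODEL = dict(E=8, K=12, dnn_widths=(10, 12), hidden_pred=16,
                   dropout=0.1, max_epochs=3, patience=5, batch_size=64, seed=0)


@pytest.fixture(scope="session")
def small_dataset():
    """A quick, fully synthetic triplet dataset (12 drugs, 6 cell lines)."""
    cfg = SyntheticConfig(m_drugs=12, n_cell_lines=6, n_tissues=3, g_genes=20,
                          n_triplets=300, seed=1)
    ds, truth = generate_dataset(cfg, augment_order=True)
    return ds, truth


@pytest.fixture(scope="session")
def smoke_dataset():
    """Tiny smoke dataset for constructability tests (6 drugs, 2 cell lines)."""
    cfg = SyntheticConfig(m_drugs=6, n_cell_lines=2, n_tissues=1, g_genes=10,
                          n_triplets=50, seed=3)
    ds, _ = generate_dataset(cfg)
    return ds


@pytest.fixture
def small_config():
    return ModelConfig(**SMALL_MODEL)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
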