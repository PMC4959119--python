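import numpy as np
import pytest

from paraica.synthetic import SyntheticConfig, generate_linked_dataset


@pytest.fixture(scope="session")
def latent_dataset():
    """Small latent-mode (continuous) linked dataset with known truth."""
    cfg = SyntheticConfig(
        n_subjects=150,
        n_snps=600,
        grid_dims=(10, 10, 10),
        k_gene=3,
        k_brain=3,
        linked_pairs=[(0, 0, 0.6)],
        discretize=False,
        noise_sd_gene=0.4,
        noise_sd_brain=0.4,
        blob_radius_vox=1.5,
        seed=42,
    )
    return cfg, generate_linked_dataset(cfg)


@pytest.fixture(scope="session")
def dosage_dataset():
    """Two-subpopulation {0,1,2} dosage dataset with FST 0.1."""
    cfg = SyntheticConfig(
        n_subjects=200,
        n_snps=400,
        grid_dims=(8, 8, 8),
        k_gene=3,
        k_brain=2,
        fst=0.1,
        ld_within_r=0.3,
        ld_block_size=8,
        blob_radius_vox=1.2,
        seed=7,
    )
    return cfg, generate_linked_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
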