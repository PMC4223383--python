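import numpy as np
import pytest

from chimera_lse.simulate import SimConfig, make_true_genes, simulate_parental_genomes


@pytest.fixture(scope="session")
def small_world():
    """A small simulated universe shared by read-only tests."""
    config = SimConfig(
        n_genes=12,
        gene_length=300,
        snp_rate=0.02,
        frac_l1_specific=0.25,
        frac_l2l3_specific=0.25,
        frac_l1_related=0.0,
        frac_l2l3_related=0.0,
        seed=42,
    )
    genes = make_true_genes(config)
    lyc, penn, truth = simulate_parental_genomes(config, genes)
    return {"config": config, "genes": genes, "lyc": lyc, "penn": penn, "truth": truth}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
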