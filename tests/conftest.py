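import numpy as np
import pytest

from vitephylo import synthetic_data as sd


@pytest.fixture(scope="session")
def species_tree():
    return sd.simulate_species_tree(8, birth_rate=1.0, root_age=1.0, seed=11)


@pytest.fixture(scope="session")
def small_families(species_tree):
    """Five single-copy families with sequences on an 8-taxon tree."""
    fams = sd.simulate_gene_families(species_tree, 5, dup_rate=0.0,
                                     loss_rate=0.0, seed=3)
    sd.simulate_family_sequences(fams, n_codons=120,
                                 model=sd.GTRModel(rate_multiplier=0.3), seed=4)
    return fams


@pytest.fixture(scope="session")
def mixed_families(species_tree):
    """Families with duplications and losses, with sequences."""
    fams = sd.simulate_gene_families(species_tree, 30, dup_rate=0.15,
                                     loss_rate=0.05, seed=7)
    sd.simulate_family_sequences(fams, n_codons=100,
                                 model=sd.GTRModel(rate_multiplier=0.3), seed=8)
    return fams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
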