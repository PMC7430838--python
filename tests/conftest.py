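import numpy as np
import pytest

from wblup.grm import build_design
from wblup.simdata import SimConfig, TraitSpec, make_dataset


@pytest.fixture(scope="session")
def bundle():
    """Shared small dataset: one 15%-variance QTL trait and a polygenic trait."""
    cfg = SimConfig(
        seed=42, n_individuals=400, n_chromosomes=2, snps_per_chrom=150,
        chrom_length_bp=10_000_000,
        traits=[TraitSpec(name="qtl", h2=0.4, region_fractions=(0.15,)),
                TraitSpec(name="poly", h2=0.4)])
    return make_dataset(cfg)


@pytest.fixture(scope="session")
def design(bundle):
    return build_design(bundle.genotypes)


@pytest.fixture(scope="session")
def split(bundle):
    ids = list(bundle.genotypes.samples)
    index = {s: i for i, s in enumerate(ids)}
    tr = np.array([index[s] for s in bundle.train_ids])
    va = np.array([index[s] for s in bundle.val_ids])
    return tr, va


def trait_vector(bundle, trait, idx):
    ids = list(bundle.genotypes.samples)
    y = bundle.phenotypes.trait(trait)
    return y.reindex([ids[i] for i in idx]).to_numpy()
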