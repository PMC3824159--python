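import numpy as np
import pytest

import genebin as gb


@pytest.fixture(scope="session")
def pool():
    """A seeded synthetic gene panel: 12 SNPs, one LD bin with >= 3
    low-frequency members, moderate mean |r|."""
    return gb.generate_pool(gb.GenePanelSpec(n_snps=12, seed=1))


@pytest.fixture(scope="session")
def genotypes(pool):
    """2000 diploid individuals drawn from the session pool."""
    return gb.generate_genotypes(pool, 2000, seed=7)


@pytest.fixture(scope="session")
def null_phenotype(genotypes):
    rng = np.random.default_rng(11)
    return gb.Phenotype(list(genotypes.samples), rng.standard_normal(genotypes.n_samples))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_genotype_matrix(rng, n=300, K=6, maf_low=0.05, maf_high=0.45):
    """Independent-SNP genotype matrix with HW sampling (helper, not a
    fixture, so tests can vary the shape)."""
    mafs = rng.uniform(maf_low, maf_high, size=K)
    G = rng.binomial(2, mafs, size=(n, K)).astype(float)
    ids = [f"s{j}" for j in range(K)]
    return gb.GenotypeMatrix.from_raw([f"i{i}" for i in range(n)], ids, range(1, K + 1), G)
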