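import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from skewscape.io import OrientedGene
from skewscape.synthetic import SyntheticSpec, generate_genes, generate_null_genes


@pytest.fixture(scope="session")
def small_orf_genes():
    """300 codon-structured synthetic ORFs with the default skew profile."""
    spec = SyntheticSpec(n_genes=300, length=900, seed=11, orf_mode=True)
    genes, _ = generate_genes(spec)
    return genes


@pytest.fixture(scope="session")
def null_genes():
    """Position-homogeneous genes (no embedded skew structure)."""
    return generate_null_genes(300, length=600, gc_content=0.40, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_gene(rng, length=300, gc=0.5, gene_id="g"):
    bases = rng.choice(list("ACGT"), size=length,
                       p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return OrientedGene(gene_id=gene_id, cds="".join(bases))
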