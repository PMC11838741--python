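import numpy as np
import pytest

from cmmosaic.genes import GeneModel, GeneModelSet
from cmmosaic.signatures import synthetic_catalog
from cmmosaic.synth import ToyReference, generate_gene_models, generate_reference


@pytest.fixture(scope="session")
def toy_ref() -> ToyReference:
    return generate_reference(200_000, gc_fraction=0.41, seed=7)


@pytest.fixture(scope="session")
def toy_genes(toy_ref) -> GeneModelSet:
    return generate_gene_models(toy_ref, n_genes=10, seed=7, gene_length=6000, flank=1500)


@pytest.fixture(scope="session")
def catalog4():
    return synthetic_catalog(4, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


@pytest.fixture()
def hand_gene() -> GeneModelSet:
    """One + and one - strand gene with known anatomy on a hand-built contig.

    Plus gene: span 101-220, exons (101,140) and (181,220), CDS 111-210
    (spliced length 70+... trimmed to multiple of 3 by construction below).
    """
    plus = GeneModel(
        "gplus", "chrH", "+", 101, 220,
        exons=[(101, 140), (181, 220)], cds_start=111, cds_end=212,
    )
    # spliced CDS: (111-140)=30 + (181-212)=32 -> 62; trim to 60
    plus.cds_end = 210
    minus = GeneModel(
        "gminus", "chrH", "-", 2401, 2520,
        exons=[(2401, 2440), (2481, 2520)], cds_start=2411, cds_end=2510,
    )
    return GeneModelSet([plus, minus])
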