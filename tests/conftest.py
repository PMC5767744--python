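import numpy as np
import pandas as pd
import pytest

from assoctx.calling import call_snps
from assoctx.io import GeneOrder
from assoctx.simulate import PanelConfig, simulate_panel
from assoctx.structure import encode_genotypes, estimate_q, kinship


@pytest.fixture(scope="session")
def small_panel():
    """Moderate synthetic panel shared across test modules."""
    return simulate_panel(
        PanelConfig(n_accessions=120, n_models_per_genome=60, seed=3)
    )


@pytest.fixture(scope="session")
def called_small(small_panel):
    matrix, annotations, log = call_snps(
        small_panel.pileup, small_panel.gene_order,
        small_panel.linkage_evidence,
    )
    return matrix, annotations, log


@pytest.fixture(scope="session")
def structured_small(called_small):
    matrix, annotations, _ = called_small
    geno = encode_genotypes(matrix)
    q = estimate_q(geno, 2, seed=3)
    k = kinship(geno)
    return geno, q, k


@pytest.fixture(scope="session")
def default_panel():
    """Full-size default panel (383 accessions) for recovery properties."""
    return simulate_panel(PanelConfig(seed=1))


@pytest.fixture(scope="session")
def called_default(default_panel):
    matrix, annotations, log = call_snps(
        default_panel.pileup, default_panel.gene_order,
        default_panel.linkage_evidence,
    )
    return matrix, annotations, log


@pytest.fixture(scope="session")
def structured_default(called_default):
    matrix, annotations, _ = called_default
    geno = encode_genotypes(matrix)
    q = estimate_q(geno, 2, seed=1)
    k = kinship(geno)
    return geno, q, k


@pytest.fixture()
def toy_gene_order():
    return GeneOrder(pd.DataFrame({
        "model": ["gA1", "gA2", "gC1", "gC2"],
        "chromosome": ["A1", "A8", "C1", "C3"],
        "order_index": [1, 1, 1, 1],
        "cds_length": [1200, 900, 1500, 600],
        "homoeologue": ["gC1", "", "gA1", ""],
    }))
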