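import numpy as np
import pandas as pd
import pytest

from pathherit.io import GenotypeMatrix
from pathherit.synthetic import SimConfig


def make_geno(dosages, iids=None, chrom="1", positions=None) -> GenotypeMatrix:
    """Small GenotypeMatrix from a literal dosage array."""
    X = np.asarray(dosages, dtype=float)
    n, m = X.shape
    if iids is None:
        iids = [f"i{k}" for k in range(n)]
    if positions is None:
        positions = np.arange(m) * 1000 + 1
    snps = pd.DataFrame(
        {
            "snp_id": [f"s{k}" for k in range(m)],
            "chrom": chrom,
            "pos": positions,
            "a1": "A",
            "a2": "G",
        }
    )
    return GenotypeMatrix(X, list(iids), snps)


@pytest.fixture
def tiny_geno():
    rng = np.random.default_rng(0)
    return make_geno(rng.integers(0, 3, size=(5, 10)).astype(float))


@pytest.fixture
def small_config():
    return SimConfig(
        n_target=300,
        n_discovery=600,
        m_snps=400,
        block_size=20,
        rho=0.3,
        n_genes=20,
        gene_span_snps=10,
        pathways={"causal": 3, "nullA": 3, "nullB": 3},
        h2_pathway=0.05,
        h2_background=0.20,
        prevalence_K=0.15,
        case_fraction=0.5,
        seed=7,
    )
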