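import numpy as np
import pytest

from grnmap.datatypes import GenotypeMatrix, SNPRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_genotype_matrix(calls, positions=None, genes=None, ids=None):
    """Small GenotypeMatrix from a raw call matrix (no reorientation)."""
    calls = np.asarray(calls, dtype=float)
    n, m = calls.shape
    positions = positions or [1 + 24 * j for j in range(m)]
    genes = genes or [""] * m
    ids = ids or [f"ind{i}" for i in range(n)]
    snps = [
        SNPRecord(f"s{j}", "chr1", positions[j], "A", "G", gene_id=genes[j])
        for j in range(m)
    ]
    return GenotypeMatrix(ids, snps, calls)


@pytest.fixture
def genotypes_factory():
    return make_genotype_matrix
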