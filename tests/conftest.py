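import numpy as np
import pandas as pd
import pytest

from cfchip.enrichment import CountMatrix
from cfchip.panel import GenePanel, GeneRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20230305)


def make_panel(ks, name="test-panel"):
    """Panel of bare genes (no capture geometry) with the given coverage factors."""
    genes = [
        GeneRecord(
            gene_id=f"G{i + 1}",
            chrom="chr1",
            strand="+",
            tss=1_000_000 * (i + 1),
            gene_length=50_000,
            coverage_factor_k=int(k),
        )
        for i, k in enumerate(ks)
    ]
    return GenePanel(genes=genes, name=name)


def make_counts(array, conditions=None, assay="chip", gene_ids=None):
    """CountMatrix from a genes x samples array with default metadata."""
    arr = np.atleast_2d(np.asarray(array))
    if arr.shape[0] == 1 and arr.ndim == 2 and np.asarray(array).ndim == 1:
        arr = arr.T
    n_genes, n_samples = arr.shape
    gene_ids = gene_ids or [f"G{i + 1}" for i in range(n_genes)]
    sample_ids = [f"S{j + 1}" for j in range(n_samples)]
    conditions = conditions or ["case"] * n_samples
    counts = pd.DataFrame(arr, index=gene_ids, columns=sample_ids)
    samples = pd.DataFrame(
        {"sample_id": sample_ids, "condition": conditions, "assay": assay}
    )
    return CountMatrix(counts=counts, samples=samples)
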