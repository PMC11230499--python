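import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from lactsig import SimulationConfig, default_registry, simulate_cells


def make_adata(counts, barcodes=None, genes=None) -> ad.AnnData:
    """Small dense cells x genes AnnData for hand-built examples."""
    counts = np.asarray(counts)
    n, g = counts.shape
    barcodes = barcodes or [f"cell{i}" for i in range(n)]
    genes = genes or [f"Gene{j}" for j in range(g)]
    return ad.AnnData(
        X=sp.csr_matrix(counts.astype(np.int64)),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def small_sim():
    """One moderately sized planted simulation shared across tests."""
    cfg = SimulationConfig(n_cells_per_sample=400, n_genes=300, seed=20240621)
    adata, meta, truth = simulate_cells(cfg)
    return cfg, adata, meta, truth
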