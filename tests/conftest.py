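import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData

from gliakit import preprocess, synthgen


@pytest.fixture(scope="session")
def small_atlas():
    """Default-condition synthetic atlas (4 types x 200 cells, 500 genes)."""
    cfg = synthgen.SimConfig(seed=11)
    return synthgen.simulate_atlas(cfg)


@pytest.fixture(scope="session")
def small_norm(small_atlas):
    adata, _ = small_atlas
    return preprocess.lognormalize(adata)


@pytest.fixture(scope="session")
def two_type_atlas():
    """Two well-separated types for clustering/DE tests."""
    cfg = synthgen.SimConfig(
        n_types=2,
        cells_per_type=(100, 100),
        n_genes=300,
        n_markers_per_type=30,
        marker_fold=20.0,
        contamination_fraction=0.0,
        hemocyte_fraction=0.0,
        seed=7,
    )
    return synthgen.simulate_atlas(cfg)


def counts_adata(counts, cell_ids=None, gene_ids=None, is_mito=None):
    """Small dense-count AnnData helper for hand-built fixtures."""
    counts = np.asarray(counts)
    n, g = counts.shape
    adata = AnnData(X=sp.csr_matrix(counts))
    adata.obs_names = cell_ids or [f"c{i}" for i in range(n)]
    adata.var_names = gene_ids or [f"g{j}" for j in range(g)]
    if is_mito is not None:
        adata.var["is_mito"] = np.asarray(is_mito, dtype=bool)
    return adata


def values_adata(values, cell_ids=None, gene_ids=None):
    """AnnData holding already-normalized values (dense float)."""
    values = np.asarray(values, dtype=float)
    adata = AnnData(X=values)
    adata.obs_names = cell_ids or [f"c{i}" for i in range(values.shape[0])]
    adata.var_names = gene_ids or [f"g{j}" for j in range(values.shape[1])]
    return adata


@pytest.fixture
def make_counts_adata():
    return counts_adata


@pytest.fixture
def make_values_adata():
    return values_adata
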