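"""Plain-text readers/writers for the pipeline's external formats.

Count matrices travel as a CellRanger-style directory: ``matrix.mtx``
(Matrix Market coordinate, genes stored column-wise, 1-based indices),
``barcodes.tsv``, ``features.tsv`` (feature id, name, type) plus the
package's own ``cell_meta.tsv`` / ``gene_meta.tsv`` / ``truth.tsv`` side
tables. Bulk profiles, ROI tables and clone tables are CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.io import mmread, mmwrite

from .annotate import BulkProfileSet

__all__ = [
    "write_atlas_dir",
    "read_atlas_dir",
    "write_bulk_csv",
    "read_bulk_csv",
    "write_roi_csv",
    "read_roi_csv",
    "write_clone_csv",
    "read_clone_csv",
]


def write_atlas_dir(adata: AnnData, outdir, truth: pd.DataFrame | None = None) -> None:
    """Write counts + metadata as a CellRanger-dialect text directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sp.issparse(X):
        X = sp.csr_matrix(np.asarray(X))
    # CellRanger stores genes x cells
    mmwrite(outdir / "matrix.mtx", X.T.tocoo(), field="integer")
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    feats = pd.DataFrame(
        {
            "feature_id": adata.var_names,
            "feature_name": adata.var_names,
            "feature_type": "Gene Expression",
        }
    )
    feats.to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    adata.obs.to_csv(outdir / "cell_meta.tsv", sep="\t", index_label="cell_id")
    adata.var.to_csv(outdir / "gene_meta.tsv", sep="\t", index_label="gene_id")
    if truth is not None:
        truth.to_csv(outdir / "truth.tsv", sep="\t", index_label="cell_id")


def read_atlas_dir(indir) -> tuple[AnnData, pd.DataFrame | None]:
    """Read a directory written by :func:`write_atlas_dir`.

    Returns the count matrix (cells x genes) and the ground-truth table if
    present.
    """
    indir = Path(indir)
    X = sp.csr_matrix(mmread(indir / "matrix.mtx").T)
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    features = pd.read_csv(indir / "features.tsv", sep="\t", header=None)
    adata = AnnData(X=X)
    adata.obs_names = list(barcodes)
    adata.var_names = list(features[0].astype(str))
    meta_path = indir / "cell_meta.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col="cell_id")
        adata.obs = adata.obs.join(meta)
    gene_path = indir / "gene_meta.tsv"
    if gene_path.exists():
        gmeta = pd.read_csv(gene_path, sep="\t", index_col="gene_id")
        adata.var = adata.var.join(gmeta)
    truth = None
    truth_path = indir / "truth.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t", index_col="cell_id")
    return adata, truth


def write_bulk_csv(bulk: BulkProfileSet, path) -> None:
    bulk.to_csv(path)


def read_bulk_csv(path) -> BulkProfileSet:
    return BulkProfileSet.from_csv(path)


def write_roi_csv(rois: pd.DataFrame, path) -> None:
    rois.to_csv(path, index_label="roi_id")


def read_roi_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="roi_id")


def write_clone_csv(counts: pd.Series, path) -> None:
    counts.to_csv(path, index_label="category")


def read_clone_csv(path) -> pd.Series:
    df = pd.read_csv(path, index_col="category")
    return df.iloc[:, 0]
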