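"""Cluster annotation by bulk-transcriptome label transfer and marker summaries.

Deep bulk RNA-seq profiles of purified cell types (TPM vectors) are made
comparable to a shallow single-cell dataset by *pseudo-cell simulation*: for
each bulk type, reads are allocated to many synthetic cells multinomially
with per-gene probability TPM_g / sum(TPM), at per-cell depths drawn from a
normal distribution matched to the real dataset. The pseudo-cells are
log-normalized with the same scale factor as the single-cell data, averaged
per gene, and each bulk type is assigned to the cluster whose average
expression it correlates with best (Pearson, over the shared gene set).

Also provides dot-plot style marker summaries (fraction of expressing cells
and mean normalized expression per cluster) and a cluster-average dendrogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .preprocess import NormalizationParams, lognormalize

__all__ = [
    "BulkProfileSet",
    "PseudoCellParams",
    "CorrelationAssignment",
    "estimate_depth_params",
    "simulate_pseudo_cells",
    "match_bulk_to_clusters",
    "marker_summary",
    "cluster_dendrogram",
]

TPM_TOTAL = 1_000_000.0


@dataclass(frozen=True)
class BulkProfileSet:
    """Per-cell-type TPM vectors: a (types x genes) table, rows summing to 1e6."""

    tpm: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.tpm.to_numpy(dtype=float)
        if (vals < 0).any():
            raise ValueError("TPM values must be nonnegative")
        sums = vals.sum(axis=1)
        if not np.allclose(sums, TPM_TOTAL, rtol=1e-6):
            bad = list(self.tpm.index[~np.isclose(sums, TPM_TOTAL, rtol=1e-6)])
            raise ValueError(f"TPM rows must sum to 1e6; offending types: {bad}")

    @property
    def types(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def genes(self) -> list[str]:
        return list(self.tpm.columns)

    @classmethod
    def from_csv(cls, path) -> "BulkProfileSet":
        """Read a CSV with gene ids in the first column and one column per type."""
        df = pd.read_csv(path, index_col=0)
        tpm = df.T
        tpm.index.name = None
        tpm.columns.name = None
        return cls(tpm=tpm)

    def to_csv(self, path) -> None:
        self.tpm.T.to_csv(path, index_label="gene")


@dataclass(frozen=True)
class PseudoCellParams:
    """Pseudo-cell simulation settings.

    n_cells defaults to 900 simulated cells per bulk type; depth_mean/depth_sd
    are matched to the per-cell total counts of the reference single-cell
    dataset (see :func:`estimate_depth_params`).
    """

    depth_mean: float
    depth_sd: float = 0.0
    n_cells: int = 900
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.depth_mean <= 0:
            raise ValueError(f"depth_mean must be > 0, got {self.depth_mean}")
        if self.depth_sd < 0:
            raise ValueError(f"depth_sd must be >= 0, got {self.depth_sd}")


@dataclass(frozen=True)
class CorrelationAssignment:
    """Pearson correlations of bulk types against cluster averages.

    matrix
        (types x clusters) Pearson r over shared genes; NaN marks an
        undefined correlation (zero-variance average vector).
    best_match / runner_up
        Per-type highest- and second-highest-correlated cluster ids.
    """

    matrix: pd.DataFrame
    best_match: pd.Series
    runner_up: pd.Series


def estimate_depth_params(adata: AnnData) -> tuple[float, float]:
    """Mean and sample SD of per-cell total raw counts."""
    if adata.n_obs < 2:
        raise ValueError("need at least 2 cells to estimate depth parameters")
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    return float(totals.mean()), float(totals.std(ddof=1))


def simulate_pseudo_cells(
    tpm: pd.Series, params: PseudoCellParams, rng: np.random.Generator | None = None
) -> AnnData:
    """Expand one bulk TPM vector into ``n_cells`` synthetic shallow cells.

    Depths are Normal(depth_mean, depth_sd) rounded to the nearest integer and
    truncated to >= 1; reads are allocated multinomially with
    ``p_g = TPM_g / sum(TPM)``.
    """
    tpm = pd.Series(tpm, dtype=float)
    if (tpm < 0).any():
        raise ValueError("TPM values must be nonnegative")
    total = tpm.sum()
    if total <= 0:
        raise ValueError("all-zero TPM vector cannot seed pseudo-cells")
    p = (tpm / total).to_numpy()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    depths = np.rint(rng.normal(params.depth_mean, params.depth_sd, params.n_cells))
    depths = np.maximum(depths, 1).astype(np.int64)
    counts = rng.multinomial(depths, p)
    adata = AnnData(X=sp.csr_matrix(counts))
    adata.obs_names = [f"pseudo_{i:04d}" for i in range(params.n_cells)]
    adata.var_names = list(tpm.index)
    adata.obs["total_counts"] = depths
    return adata


def _cluster_averages(norm: AnnData, labels: pd.Series) -> pd.DataFrame:
    labels = pd.Series(labels).reindex(norm.obs_names)
    if labels.isna().any():
        raise ValueError("cluster labels missing for some cells")
    X = norm.X
    if sp.issparse(X):
        X = X.toarray()
    df = pd.DataFrame(np.asarray(X), index=norm.obs_names, columns=norm.var_names)
    return df.groupby(labels, observed=True).mean()


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def match_bulk_to_clusters(
    bulk: BulkProfileSet,
    params: PseudoCellParams,
    norm: AnnData,
    labels: pd.Series,
) -> CorrelationAssignment:
    """Assign each bulk type to the single-cell cluster it best correlates with.

    Pseudo-cells are simulated per type (one generator seeded once, types
    processed in table order), log-normalized with the same scale factor as
    ``norm``, averaged per gene, and correlated (Pearson) against per-cluster
    average expression over the shared gene set. Undefined correlations
    (zero-variance averages) are reported as NaN, never as 0. Best-match ties
    are broken toward the cluster with more cells, then lexically.
    """
    shared = [g for g in bulk.genes if g in set(norm.var_names)]
    if len(shared) < 2:
        raise ValueError(
            f"need >= 2 shared genes between bulk and single-cell data, got {len(shared)}"
        )
    scale = float(norm.uns.get("normalization", {}).get("scale_factor", 10_000.0))
    cluster_avg = _cluster_averages(norm, labels)[shared]
    cluster_sizes = pd.Series(labels).value_counts()

    rng = np.random.default_rng(params.seed)
    rows = {}
    for t in bulk.types:
        pseudo = simulate_pseudo_cells(bulk.tpm.loc[t], params, rng=rng)
        pseudo_norm = lognormalize(pseudo, NormalizationParams(scale_factor=scale))
        avg = np.asarray(pseudo_norm.X.mean(axis=0)).ravel()
        avg = pd.Series(avg, index=pseudo_norm.var_names)[shared].to_numpy()
        rows[t] = {
            c: _pearson(avg, cluster_avg.loc[c].to_numpy()) for c in cluster_avg.index
        }
    matrix = pd.DataFrame.from_dict(rows, orient="index").loc[bulk.types]

    best, runner = {}, {}
    for t in bulk.types:
        row = matrix.loc[t].dropna()
        if row.empty:
            best[t] = None
            runner[t] = None
            continue
        # sort: r desc, cluster size desc, lexical cluster id
        ranked = sorted(
            row.items(),
            key=lambda kv: (-kv[1], -cluster_sizes.get(kv[0], 0), str(kv[0])),
        )
        best[t] = ranked[0][0]
        runner[t] = ranked[1][0] if len(ranked) > 1 else None
    return CorrelationAssignment(
        matrix=matrix,
        best_match=pd.Series(best, name="best_match"),
        runner_up=pd.Series(runner, name="runner_up"),
    )


def marker_summary(norm: AnnData, labels: pd.Series, genes: list[str]) -> pd.DataFrame:
    """Dot-plot statistics: per (cluster, gene), the fraction of cells with
    nonzero normalized expression and the arithmetic mean of normalized values."""
    missing = [g for g in genes if g not in set(norm.var_names)]
    if missing:
        raise KeyError(f"genes not found in matrix: {missing}")
    labels = pd.Series(labels).reindex(norm.obs_names)
    if labels.isna().any():
        raise ValueError("cluster labels missing for some cells")
    counts = labels.value_counts()
    if (counts == 0).any():
        raise ValueError("empty cluster in labels")
    X = norm[:, genes].X
    if sp.issparse(X):
        X = X.toarray()
    df = pd.DataFrame(np.asarray(X), index=norm.obs_names, columns=genes)
    grouped = df.groupby(labels, observed=True)
    mean = grouped.mean()
    pct = grouped.agg(lambda s: float((s > 0).mean()))
    out = pd.concat(
        {"pct_expressing": pct.stack(), "mean_expression": mean.stack()}, axis=1
    )
    out.index.names = ["cluster", "gene"]
    return out


def cluster_dendrogram(
    norm: AnnData, labels: pd.Series, method: str = "complete"
) -> tuple[np.ndarray, list[str]]:
    """Agglomerate clusters on Euclidean distance between average expression.

    Returns a SciPy linkage matrix and the leaf names in lexical order (the
    deterministic tie-break). Complete linkage by default; configurable.
    """
    avg = _cluster_averages(norm, labels)
    if avg.shape[0] < 2:
        raise ValueError("need >= 2 clusters to build a dendrogram")
    avg = avg.sort_index(key=lambda ix: ix.map(str))
    Z = linkage(pdist(avg.to_numpy(), metric="euclidean"), method=method)
    return Z, [str(c) for c in avg.index]
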