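"""Subclustering and the DEG-count over-clustering criterion.

A cluster is subclustered in isolation and the number of genes differentially
expressed between its two largest subclusters (at a fold-change of 4 or more,
BH-adjusted p < 0.05) decides whether the subdivision reflects real
heterogeneity: more than 20 such genes supports a split, fewer than 15 marks
an over-clustering artifact, and counts in between are left indeterminate
rather than guessed.

Clustering is deterministic: PCA on per-gene z-scores (capped at +/-10), a
k-nearest-neighbour graph (k = 20, Euclidean in PC space), and greedy
modularity community detection with a resolution parameter. Differential
expression uses the Wilcoxon rank-sum test on normalized values with the
usual back-transformed fold change, ``log2((mean(expm1 x_A) + 1) /
(mean(expm1 x_B) + 1))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .preprocess import select_hvgs

__all__ = [
    "SplitCriterion",
    "SplitDecision",
    "cluster_cells",
    "differential_expression",
    "overclustering_check",
    "split_cluster",
]


@dataclass(frozen=True)
class SplitCriterion:
    """DEG-count bounds for the over-clustering verdict.

    A subdivision with at least ``split_min_genes`` genes at
    >= ``fold_threshold``-fold change (default 4-fold, i.e. |log2FC| >= 2) is
    a genuine split; one with at most ``artifact_max_genes`` is an artifact;
    anything in the gap is indeterminate.
    """

    fold_threshold: float = 4.0
    split_min_genes: int = 21  # "greater than 20"
    artifact_max_genes: int = 14  # "fewer than 15"
    adj_p_max: float | None = 0.05  # None disables the significance gate

    def __post_init__(self) -> None:
        if self.fold_threshold <= 0:
            raise ValueError(f"fold_threshold must be > 0, got {self.fold_threshold}")
        if self.artifact_max_genes >= self.split_min_genes:
            raise ValueError(
                f"artifact_max_genes ({self.artifact_max_genes}) must be below "
                f"split_min_genes ({self.split_min_genes})"
            )

    def verdict(self, n_deg: int) -> str:
        if n_deg >= self.split_min_genes:
            return "split"
        if n_deg <= self.artifact_max_genes:
            return "artifact"
        return "indeterminate"


@dataclass(frozen=True)
class SplitDecision:
    """Outcome of an over-clustering check on one cluster."""

    n_deg: int
    verdict: str
    subassignments: pd.Series


def _dense(X) -> np.ndarray:
    if sp.issparse(X):
        return X.toarray()
    return np.asarray(X)


def cluster_cells(
    norm: AnnData,
    hvgs: list[str] | None = None,
    n_pcs: int = 10,
    resolution: float = 1.0,
    seed: int = 0,
    k: int = 20,
) -> pd.Series:
    """Graph-based clustering of cells on normalized expression.

    Per-gene z-scores (capped at +/-10) of the HVG submatrix are reduced to
    ``n_pcs`` principal components; a k-NN graph is built on Euclidean
    distances in PC space and partitioned by greedy modularity maximization
    at the given resolution. Cluster ids are integers ordered by decreasing
    cluster size. Deterministic given the seed.
    """
    if norm.n_obs < 2:
        raise ValueError("need at least 2 cells to cluster")
    sub = norm[:, hvgs] if hvgs is not None else norm
    if n_pcs >= min(sub.n_obs, sub.n_vars):
        raise ValueError(
            f"n_pcs={n_pcs} must be below min(n_cells, n_genes)={min(sub.n_obs, sub.n_vars)}"
        )
    X = _dense(sub.X).astype(np.float64)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = np.clip((X - mu) / sd, -10, 10)
    pcs = PCA(n_components=n_pcs, svd_solver="full", random_state=seed).fit_transform(Z)

    n_neighbors = min(k, norm.n_obs - 1)
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    G = nx.Graph()
    G.add_nodes_from(range(norm.n_obs))
    for i, row in enumerate(idx):
        for j in row[1:]:
            G.add_edge(i, int(j))
    communities = nx.community.greedy_modularity_communities(G, resolution=resolution)
    communities = sorted(communities, key=lambda c: (-len(c), min(c)))
    labels = np.empty(norm.n_obs, dtype=np.int64)
    for lab, members in enumerate(communities):
        labels[list(members)] = lab
    return pd.Series(labels, index=norm.obs_names, name="cluster")


def _tie_term(column: np.ndarray) -> float:
    _, counts = np.unique(column, return_counts=True)
    t = counts[counts > 1]
    return float((t**3 - t).sum())


def differential_expression(
    norm: AnnData,
    group_a,
    group_b,
    min_pct: float = 0.1,
) -> pd.DataFrame:
    """Wilcoxon rank-sum differential expression between two cell sets.

    Genes expressed (value > 0) in at least ``min_pct`` of either group are
    tested; p-values use the tie-corrected normal approximation of the
    rank-sum statistic, BH-adjusted over the tested genes. Fold changes are
    ``log2((mean(expm1 x_A) + 1) / (mean(expm1 x_B) + 1))``.
    """
    group_a = pd.Index(group_a)
    group_b = pd.Index(group_b)
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")
    overlap = group_a.intersection(group_b)
    if len(overlap) > 0:
        raise ValueError(f"groups overlap on {len(overlap)} cells, e.g. {list(overlap[:3])}")

    Xa = _dense(norm[group_a].X).astype(np.float64)
    Xb = _dense(norm[group_b].X).astype(np.float64)
    n_a, n_b = Xa.shape[0], Xb.shape[0]

    pct_a = (Xa > 0).mean(axis=0)
    pct_b = (Xb > 0).mean(axis=0)
    tested = (pct_a >= min_pct) | (pct_b >= min_pct)
    genes = np.asarray(norm.var_names)[tested]
    Xa, Xb = Xa[:, tested], Xb[:, tested]
    pct_a, pct_b = pct_a[tested], pct_b[tested]
    if len(genes) == 0:
        return pd.DataFrame(
            columns=["gene", "log2_fold_change", "p_value", "adj_p", "pct_a", "pct_b"]
        ).set_index("gene")

    data = np.vstack([Xa, Xb])
    n = n_a + n_b
    ranks = stats.rankdata(data, axis=0)
    R_a = ranks[:n_a].sum(axis=0)
    U = R_a - n_a * (n_a + 1) / 2.0
    mu = n_a * n_b / 2.0
    ties = np.array([_tie_term(data[:, g]) for g in range(data.shape[1])])
    sigma2 = n_a * n_b / 12.0 * ((n + 1) - ties / (n * (n - 1)))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sigma2 > 0, (U - mu) / np.sqrt(np.maximum(sigma2, 1e-300)), 0.0)
    p = np.where(sigma2 > 0, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    adj_p = stats.false_discovery_control(p, method="bh")

    mean_a = np.expm1(Xa).mean(axis=0)
    mean_b = np.expm1(Xb).mean(axis=0)
    log2fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))

    out = pd.DataFrame(
        {
            "log2_fold_change": log2fc,
            "p_value": p,
            "adj_p": adj_p,
            "pct_a": pct_a,
            "pct_b": pct_b,
        },
        index=pd.Index(genes, name="gene"),
    )
    return out.sort_values(["adj_p", "p_value"], kind="stable")


def overclustering_check(
    norm: AnnData,
    labels: pd.Series,
    cluster_id,
    sub_resolution: float = 0.5,
    criterion: SplitCriterion = SplitCriterion(),
    seed: int = 0,
    n_pcs: int = 10,
    n_hvgs: int = 2000,
) -> SplitDecision:
    """Subcluster one cluster in isolation and judge the subdivision.

    The cluster's cells are re-clustered on their own HVGs; the number of
    genes differing by at least ``criterion.fold_threshold``-fold (and
    BH-adjusted p below ``criterion.adj_p_max``, if enabled) between the two
    largest subclusters yields the verdict. A cluster that does not
    subdivide is an artifact with ``n_deg = 0`` by convention.
    """
    labels = pd.Series(labels).reindex(norm.obs_names)
    cells = labels.index[labels == cluster_id]
    if len(cells) < 4:
        raise ValueError(f"cluster {cluster_id!r} has {len(cells)} cells; need >= 4")
    sub = norm[cells].copy()
    hvgs = select_hvgs(sub, min(n_hvgs, sub.n_vars))
    eff_pcs = min(n_pcs, len(cells) - 1, len(hvgs) - 1)
    sublabels = cluster_cells(
        sub, hvgs=hvgs, n_pcs=eff_pcs, resolution=sub_resolution, seed=seed
    )
    sizes = sublabels.value_counts()
    if len(sizes) < 2:
        return SplitDecision(n_deg=0, verdict="artifact", subassignments=sublabels)
    top_two = list(sizes.index[:2])
    de = differential_expression(
        sub,
        sublabels.index[sublabels == top_two[0]],
        sublabels.index[sublabels == top_two[1]],
    )
    hits = np.abs(de["log2_fold_change"]) >= np.log2(criterion.fold_threshold)
    if criterion.adj_p_max is not None:
        hits &= de["adj_p"] < criterion.adj_p_max
    n_deg = int(hits.sum())
    return SplitDecision(
        n_deg=n_deg, verdict=criterion.verdict(n_deg), subassignments=sublabels
    )


def split_cluster(labels: pd.Series, cluster_id, subassignments: pd.Series) -> pd.Series:
    """Divide one cluster along subcluster assignments.

    The largest subcluster keeps the original cluster id; every other
    subcluster receives a fresh id, allocated from (max numeric id + 1)
    upward. Cell count is conserved and the mapping is invertible.
    """
    labels = pd.Series(labels).copy()
    cluster_cells_idx = labels.index[labels == cluster_id]
    sub = pd.Series(subassignments)
    if not set(sub.index) == set(cluster_cells_idx):
        extra = set(sub.index) - set(cluster_cells_idx)
        missing = set(cluster_cells_idx) - set(sub.index)
        raise ValueError(
            f"subassignments must cover exactly the cells of cluster {cluster_id!r} "
            f"(extra: {len(extra)}, missing: {len(missing)})"
        )
    sizes = sub.value_counts()
    keep_label = sizes.index[0]
    numeric = []
    for lab in labels.unique():
        try:
            numeric.append(int(str(lab)))
        except ValueError:
            continue
    next_id = (max(numeric) + 1) if numeric else 0
    int_labels = pd.api.types.is_integer_dtype(labels)
    for sublab in sizes.index[1:]:
        new_id = next_id if int_labels else str(next_id)
        labels.loc[sub.index[sub == sublab]] = new_id
        next_id += 1
    return labels
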