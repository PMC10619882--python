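"""Quality control, normalization and marker-threshold gating for count matrices.

The operations here reproduce the standard single-cell clean-up sequence used
for glial atlas construction: per-cell QC on mitochondrial read fraction and
detected-gene count, library-size log-normalization, variable-gene ranking,
threshold gating on marker genes (to remove neuronal-contaminated cells and
stray hemocytes, or to positively select populations such as midline glia),
and a batch-contribution filter that drops clusters dominated by a single
dataset.

Boundary semantics are deliberately literal and documented per operation:
mitochondrial fraction is a strict ``<`` cut, the detected-gene band is
inclusive, gating comparators are applied exactly as written, and the batch
filter drops clusters where the minority batch contributes strictly fewer
than ``min_frac`` of the cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "QCThresholds",
    "NormalizationParams",
    "GatingRule",
    "qc_filter",
    "lognormalize",
    "select_hvgs",
    "gate_cells",
    "batch_contribution_filter",
]


@dataclass(frozen=True)
class QCThresholds:
    """Per-cell QC cutoffs.

    mito_max
        Maximum tolerated mitochondrial read fraction; cells at or above this
        value are removed (strict ``<`` keeps).
    min_genes, max_genes
        Inclusive band of detected-gene counts (genes with at least one read).
    """

    mito_max: float = 0.10
    min_genes: int = 50
    max_genes: int = 3000

    def __post_init__(self) -> None:
        if not 0.0 <= self.mito_max <= 1.0:
            raise ValueError(f"mito_max must be in [0, 1], got {self.mito_max}")
        if self.min_genes < 0:
            raise ValueError(f"min_genes must be >= 0, got {self.min_genes}")
        if self.min_genes > self.max_genes:
            raise ValueError(
                f"min_genes ({self.min_genes}) must not exceed max_genes ({self.max_genes})"
            )


@dataclass(frozen=True)
class NormalizationParams:
    """Library-size normalization settings (scale factor then log1p)."""

    scale_factor: float = 10_000.0

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError(f"scale_factor must be > 0, got {self.scale_factor}")


_COMPARATORS = {
    "<=": np.less_equal,
    "≤": np.less_equal,
    "<": np.less,
    ">=": np.greater_equal,
    "≥": np.greater_equal,
    ">": np.greater,
    "=": np.equal,
    "==": np.equal,
}


@dataclass(frozen=True)
class GatingRule:
    """A single-gene threshold predicate, e.g. ``Rdl <= 1`` on normalized values."""

    gene: str
    comparator: str
    threshold: float
    space: Literal["normalized", "raw"] = "normalized"

    def __post_init__(self) -> None:
        if self.comparator not in _COMPARATORS:
            raise ValueError(
                f"comparator must be one of {sorted(set(_COMPARATORS))}, got {self.comparator!r}"
            )

    def holds(self, values: np.ndarray) -> np.ndarray:
        return _COMPARATORS[self.comparator](values, self.threshold)


def _dense_column(adata: AnnData, gene: str) -> np.ndarray:
    col = adata[:, gene].X
    if sp.issparse(col):
        col = col.toarray()
    return np.asarray(col).ravel()


def _row_sums(X) -> np.ndarray:
    return np.asarray(X.sum(axis=1)).ravel()


def qc_filter(
    adata: AnnData, thresholds: QCThresholds = QCThresholds()
) -> tuple[AnnData, dict]:
    """Keep cells with mito fraction < ``mito_max`` and detected genes in the band.

    Requires a boolean ``is_mito`` column in ``adata.var`` unless ``mito_max >= 1``
    (in which case the mitochondrial criterion is vacuous). Returns the kept
    subset (a copy) and a report of cells removed per criterion; a cell failing
    several criteria is counted under each.
    """
    X = adata.X
    totals = _row_sums(X)
    if sp.issparse(X):
        n_detected = np.asarray((X > 0).sum(axis=1)).ravel()
    else:
        n_detected = (np.asarray(X) > 0).sum(axis=1)

    if thresholds.mito_max < 1.0:
        if "is_mito" not in adata.var:
            raise ValueError(
                "adata.var lacks an 'is_mito' flag; cannot apply the mitochondrial "
                f"fraction cutoff mito_max={thresholds.mito_max}"
            )
        mito_mask = np.asarray(adata.var["is_mito"], dtype=bool)
        mito_counts = _row_sums(X[:, mito_mask]) if mito_mask.any() else np.zeros_like(totals)
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)
        pass_mito = mito_frac < thresholds.mito_max
    else:
        mito_frac = np.zeros_like(totals, dtype=float)
        pass_mito = np.ones(adata.n_obs, dtype=bool)

    pass_low = n_detected >= thresholds.min_genes
    pass_high = n_detected <= thresholds.max_genes
    keep = pass_mito & pass_low & pass_high

    report = {
        "n_input": int(adata.n_obs),
        "removed_mito": int((~pass_mito).sum()),
        "removed_low_genes": int((~pass_low).sum()),
        "removed_high_genes": int((~pass_high).sum()),
        "n_kept": int(keep.sum()),
        "n_removed": int((~keep).sum()),
    }
    kept = adata[keep].copy()
    kept.obs["mito_frac"] = mito_frac[keep]
    kept.obs["n_genes_detected"] = n_detected[keep]
    return kept, report


def lognormalize(
    adata: AnnData, params: NormalizationParams = NormalizationParams()
) -> AnnData:
    """Library-size normalize and log-transform raw counts.

    Each cell's counts are divided by its total, multiplied by
    ``params.scale_factor`` and transformed as ``ln(1 + x)``, so that for every
    cell ``sum(exp(value) - 1) == scale_factor`` exactly (up to float error).
    """
    X = adata.X
    totals = _row_sums(X)
    if np.any(totals <= 0):
        bad = list(np.asarray(adata.obs_names)[totals <= 0][:10])
        raise ValueError(f"cells with zero total counts cannot be normalized: {bad}")

    if sp.issparse(X):
        norm = X.astype(np.float64).tocsr(copy=True)
        scale = params.scale_factor / totals
        norm = sp.diags(scale) @ norm
        norm.data = np.log1p(norm.data)
    else:
        norm = np.log1p(np.asarray(X, dtype=np.float64) / totals[:, None] * params.scale_factor)

    out = AnnData(X=norm, obs=adata.obs.copy(), var=adata.var.copy())
    out.uns["normalization"] = {"scale_factor": float(params.scale_factor)}
    return out


def select_hvgs(norm: AnnData, n: int) -> list[str]:
    """Rank genes by descending variance of normalized values; return the top ``n``.

    Ties are broken by lexical gene id. ``n`` larger than the gene count
    returns all genes.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    X = norm.X
    n_obs = norm.n_obs
    if sp.issparse(X):
        mean = np.asarray(X.mean(axis=0)).ravel()
        sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    else:
        X = np.asarray(X)
        mean = X.mean(axis=0)
        sq = (X**2).mean(axis=0)
    var = sq - mean**2
    if n_obs > 1:  # sample variance
        var = var * n_obs / (n_obs - 1)
    # stable sort on lexically pre-sorted index realises the lexical tie-break
    order = (
        pd.DataFrame({"var": var}, index=norm.var_names)
        .sort_index()
        .sort_values("var", ascending=False, kind="stable")
    )
    return list(order.index[: min(n, norm.n_vars)])


def gate_cells(
    norm: AnnData,
    rules: Sequence[GatingRule],
    mode: Literal["keep_if_all", "remove_if_any"] = "remove_if_any",
) -> tuple[pd.Index, pd.Index]:
    """Partition cells by threshold rules on single genes.

    In ``remove_if_any`` mode a cell is removed as soon as any rule fails for
    it (e.g. rule ``Rdl <= 1`` removes cells with Rdl > 1); in ``keep_if_all``
    mode a cell is kept only when every rule holds. The two modes induce the
    same partition; both are provided to make call sites read naturally.
    Returns ``(kept, removed)`` cell indexes forming an exact partition.
    """
    if mode not in ("keep_if_all", "remove_if_any"):
        raise ValueError(f"unknown mode {mode!r}")
    missing = [r.gene for r in rules if r.gene not in norm.var_names]
    if missing:
        raise KeyError(f"gating genes not found in matrix: {missing}")
    all_hold = np.ones(norm.n_obs, dtype=bool)
    for rule in rules:
        all_hold &= rule.holds(_dense_column(norm, rule.gene))
    kept = norm.obs_names[all_hold]
    removed = norm.obs_names[~all_hold]
    return kept, removed


def batch_contribution_filter(
    labels: pd.Series,
    batch: pd.Series,
    minority_batch: str,
    min_frac: float = 0.01,
) -> tuple[set, pd.DataFrame]:
    """Drop clusters to which the designated batch contributes < ``min_frac`` of cells.

    The cut is strict: a cluster at exactly ``min_frac`` is kept ("fewer than
    1%" reads as strictly below). Returns the dropped cluster ids and a
    per-cluster report.
    """
    labels = pd.Series(labels)
    batch = pd.Series(batch)
    if not labels.index.equals(batch.index):
        batch = batch.reindex(labels.index)
        if batch.isna().any():
            raise ValueError("labels and batch must be aligned on the same cells")
    if minority_batch not in set(batch):
        raise ValueError(f"designated batch {minority_batch!r} not present in batch labels")

    rows = []
    dropped: set = set()
    for cluster, idx in labels.groupby(labels).groups.items():
        size = len(idx)
        n_minority = int((batch.loc[idx] == minority_batch).sum())
        frac = n_minority / size
        drop = frac < min_frac
        if drop:
            dropped.add(cluster)
        rows.append(
            {
                "cluster": cluster,
                "n_cells": size,
                "n_minority": n_minority,
                "minority_frac": frac,
                "dropped": drop,
            }
        )
    report = pd.DataFrame(rows).set_index("cluster").sort_index()
    return dropped, report
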