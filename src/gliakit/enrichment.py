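"""Gene-set over-representation with redundancy reduction and term grouping.

The test is the one-sided (upper tail) hypergeometric: for a selected gene
list of size n drawn from a universe of N genes, a term annotating K genes
and hitting k of the selection scores P(X >= k), BH-adjusted across all
tested terms. Redundant terms are pruned greedily ("simplify"): processing
rows from most to least significant, a term is dropped when its gene-set
similarity to an already-kept term exceeds the cutoff (default 0.7).
Surviving terms are grouped by Ward agglomeration on distance
``1 - similarity`` for heat-map style summaries.

Term similarity defaults to the Jaccard index of annotated gene sets and is
pluggable; no ontology graph is required.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage

__all__ = [
    "TermCollection",
    "SimplifyParams",
    "jaccard_similarity",
    "read_gmt",
    "hypergeom_enrich",
    "simplify_terms",
    "group_terms",
]


@dataclass(frozen=True)
class TermCollection:
    """Named gene sets over a declared gene universe."""

    terms: Mapping[str, tuple[str, frozenset]]
    universe: frozenset

    def __post_init__(self) -> None:
        for term_id, (_, genes) in self.terms.items():
            stray = genes - self.universe
            if stray:
                raise ValueError(
                    f"term {term_id!r} annotates genes outside the universe: {sorted(stray)[:5]}"
                )

    def genes_of(self, term_id: str) -> frozenset:
        return self.terms[term_id][1]

    @classmethod
    def from_sets(cls, sets: Mapping[str, Iterable[str]], universe: Iterable[str]):
        universe = frozenset(universe)
        terms = {tid: (tid, frozenset(g)) for tid, g in sets.items()}
        return cls(terms=terms, universe=universe)


@dataclass(frozen=True)
class SimplifyParams:
    """Redundancy-reduction settings: similarity cutoff (strict >) and the
    number of top terms carried into grouping."""

    similarity_cutoff: float = 0.7
    top_n: int = 20

    def __post_init__(self) -> None:
        if not 0.0 <= self.similarity_cutoff <= 1.0:
            raise ValueError(f"similarity_cutoff must be in [0, 1], got {self.similarity_cutoff}")
        if self.top_n < 1:
            raise ValueError(f"top_n must be >= 1, got {self.top_n}")


def jaccard_similarity(a: frozenset, b: frozenset) -> float:
    """|A∩B| / |A∪B|; 0 for two empty sets."""
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def read_gmt(path, universe: Iterable[str] | None = None) -> TermCollection:
    """Parse a GMT file (term id, description, then tab-separated genes).

    If no universe is given, the union of all annotated genes is used.
    """
    terms = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line (needs id, description, genes): {line[:60]!r}")
            tid, desc, genes = parts[0], parts[1], frozenset(g for g in parts[2:] if g)
            terms[tid] = (desc or tid, genes)
    if universe is None:
        universe = frozenset().union(*(g for _, g in terms.values())) if terms else frozenset()
    return TermCollection(terms=terms, universe=frozenset(universe))


def hypergeom_enrich(
    selected: Iterable[str],
    terms: TermCollection,
    min_adj_p: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation, BH-adjusted.

    Returns rows with ``adj_p < min_adj_p`` sorted by adjusted p (columns:
    name, k, K, n, N, p_value, adj_p, indexed by term id). Pass
    ``min_adj_p=1.01`` to keep every tested term.
    """
    selected = frozenset(selected)
    stray = selected - terms.universe
    if stray:
        raise ValueError(f"selected genes outside the universe: {sorted(stray)[:10]}")
    N = len(terms.universe)
    n = len(selected)
    rows = []
    for tid, (name, genes) in terms.terms.items():
        K = len(genes)
        k = len(genes & selected)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": tid, "name": name, "k": k, "K": K, "n": n, "N": N, "p_value": p})
    if not rows:
        return pd.DataFrame(
            columns=["name", "k", "K", "n", "N", "p_value", "adj_p"],
            index=pd.Index([], name="term_id"),
        )
    df = pd.DataFrame(rows).set_index("term_id")
    df["adj_p"] = stats.false_discovery_control(df["p_value"].to_numpy(), method="bh")
    df = df.assign(_tid=df.index.astype(str)).sort_values(
        ["adj_p", "p_value", "_tid"], kind="stable"
    ).drop(columns="_tid")
    return df[df["adj_p"] < min_adj_p]


def simplify_terms(
    rows: pd.DataFrame,
    terms: TermCollection,
    params: SimplifyParams = SimplifyParams(),
    similarity: Callable[[frozenset, frozenset], float] = jaccard_similarity,
) -> pd.DataFrame:
    """Greedy redundancy pruning of enriched terms.

    Rows are visited in ascending ``adj_p`` (ties: raw p, then term id); a
    term is kept unless its similarity to an already-kept term is strictly
    above the cutoff. Output is a subset of the input, in the input's columns;
    the operation is idempotent.
    """
    if rows.empty:
        return rows.copy()
    order = rows.assign(_tid=rows.index.astype(str)).sort_values(
        ["adj_p", "p_value", "_tid"], kind="stable"
    )
    kept: list[str] = []
    for tid in order.index:
        genes = terms.genes_of(tid)
        if all(similarity(genes, terms.genes_of(other)) <= params.similarity_cutoff for other in kept):
            kept.append(tid)
    return rows.loc[[tid for tid in rows.index if tid in set(kept)]]


def group_terms(
    rows: pd.DataFrame,
    terms: TermCollection,
    params: SimplifyParams = SimplifyParams(),
    similarity: Callable[[frozenset, frozenset], float] = jaccard_similarity,
) -> tuple[np.ndarray | None, pd.DataFrame]:
    """Ward-group the top-n enriched terms on 1 - similarity.

    Returns the SciPy linkage matrix (None when fewer than 2 rows survive)
    and the heat-table: the top-n rows, in dendrogram leaf order, with a
    ``neg_log10_fdr`` column.
    """
    if rows.empty:
        return None, rows.copy()
    top = rows.assign(_tid=rows.index.astype(str)).sort_values(
        ["adj_p", "p_value", "_tid"], kind="stable"
    )
    top = top.drop(columns="_tid").head(params.top_n)
    table = top.copy()
    with np.errstate(divide="ignore"):
        table["neg_log10_fdr"] = -np.log10(table["adj_p"])
    if len(top) < 2:
        return None, table
    tids = list(top.index)
    m = len(tids)
    dist = np.zeros(m * (m - 1) // 2)
    pos = 0
    for i in range(m):
        gi = terms.genes_of(tids[i])
        for j in range(i + 1, m):
            dist[pos] = 1.0 - similarity(gi, terms.genes_of(tids[j]))
            pos += 1
    Z = linkage(dist, method="ward")
    from scipy.cluster.hierarchy import leaves_list

    order = leaves_list(Z)
    table = table.iloc[list(order)]
    return Z, table
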