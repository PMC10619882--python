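"""Newick export for SciPy hierarchical-clustering linkage matrices."""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import to_tree

__all__ = ["linkage_to_newick"]


def linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Serialize a linkage matrix as a Newick string with branch lengths.

    Branch lengths are the differences in merge heights between a node and
    its parent (leaves hang from their first merge height).
    """
    root = to_tree(Z)

    def build(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    left = build(root.left, root.dist)
    right = build(root.right, root.dist)
    return f"({left},{right});"
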