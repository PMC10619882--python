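"""Gene-set over-representation with redundancy reduction.

Runs the hypergeometric test over a toy term collection, BH-adjusts,
prunes redundant terms (Jaccard similarity > 0.7) and Ward-groups the
survivors.
"""

from gliakit.enrichment import (
    SimplifyParams,
    TermCollection,
    group_terms,
    hypergeom_enrich,
    simplify_terms,
)

universe = [f"g{i}" for i in range(40)]
terms = TermCollection.from_sets(
    {
        "axon_guidance": universe[:8],
        "axon_guidance_dup": universe[:7],       # near-duplicate of the first
        "glial_migration": universe[10:18],
        "metabolism": universe[20:30],
    },
    universe,
)
selected = universe[:8] + universe[10:14]  # saturates the two axon terms, grazes migration

rows = hypergeom_enrich(selected, terms, min_adj_p=0.05)
print("enriched terms (adj p < 0.05):")
print(rows[["k", "K", "n", "N", "p_value", "adj_p"]].to_string())

kept = simplify_terms(rows, terms, SimplifyParams(similarity_cutoff=0.7))
print(f"\nafter simplify (Jaccard > 0.7 pruned): {list(kept.index)}")

Z, table = group_terms(kept, terms)
print("\ngrouped heat-table (-log10 FDR):")
print(table[["adj_p", "neg_log10_fdr"]].round(4).to_string())
# The near-duplicate term is dropped by simplify; the heat-table orders the
# survivors by dendrogram leaf position for plotting.
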