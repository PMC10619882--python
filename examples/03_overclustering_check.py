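"""Judge whether subclusters reflect real heterogeneity or over-clustering.

A merged cluster holding two genuinely distinct rare types should exceed 20
genes at >= 4-fold differential expression between its subclusters ("split"),
while a homogeneous cluster should stay under 15 ("artifact").
"""

import pandas as pd

from gliakit import preprocess, synthgen
from gliakit.heterogeneity import overclustering_check

# two distinct types forced into one cluster label
mixed_cfg = synthgen.SimConfig(
    n_types=2, cells_per_type=(100, 100), n_genes=300, n_markers_per_type=30,
    marker_fold=20.0, contamination_fraction=0.0, hemocyte_fraction=0.0, seed=2,
)
adata, _ = synthgen.simulate_atlas(mixed_cfg)
norm = preprocess.lognormalize(adata)
labels = pd.Series(["cluster9"] * norm.n_obs, index=norm.obs_names)
decision = overclustering_check(norm, labels, "cluster9", sub_resolution=0.5, seed=0)
print(f"merged rare pair: {decision.n_deg} genes >= 4-fold DE -> verdict '{decision.verdict}'")

# one homogeneous type
homog_cfg = synthgen.SimConfig(
    n_types=1, cells_per_type=(200,), n_genes=300, n_markers_per_type=0,
    contamination_fraction=0.0, hemocyte_fraction=0.0, seed=3,
)
adata, _ = synthgen.simulate_atlas(homog_cfg)
norm = preprocess.lognormalize(adata)
labels = pd.Series(["cluster0"] * norm.n_obs, index=norm.obs_names)
decision = overclustering_check(norm, labels, "cluster0", sub_resolution=0.5, seed=0)
print(f"homogeneous cluster: {decision.n_deg} genes >= 4-fold DE -> verdict '{decision.verdict}'")
# More than 20 strongly differential genes justifies a manual split; fewer
# than 15 marks the subdivision as a clustering artifact.
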