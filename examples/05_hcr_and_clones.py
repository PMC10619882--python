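"""HCR positivity scoring, regional distribution test and clone statistics.

Scores per-nucleus probe intensities against the 2.25 scaled-intensity
threshold, asks whether positive nuclei distribute like all nuclei across
neuropil regions, and summarizes clone-category tables.
"""

import numpy as np
import pandas as pd

from gliakit import synthgen
from gliakit.quantify import (
    PositivityParams,
    clone_proportions,
    compute_normalization_value,
    fisher_exact_2x2,
    regional_distribution_test,
    score_hcr_positivity,
)

# per-sample normalization value from an average-intensity projection
projection = np.random.default_rng(0).uniform(80, 120, (64, 64))
norm_value = compute_normalization_value(projection)
print(f"normalization value (mean projection intensity): {norm_value:.2f}")

params = synthgen.RoiIntensityParams(normalization_value=norm_value)
rois, truth = synthgen.simulate_roi_table(
    500, [0.5, 0.3, 0.2], [0.3, 0.3, 0.3], intensity_params=params, seed=4,
    region_names=["medulla", "lobula", "lobula_plate"],
)
scored, summary = score_hcr_positivity(rois, PositivityParams(norm_value))
print(f"positive nuclei: {summary['n_positive']}/{summary['n_nuclei']} "
      f"({100 * summary['positive_frac']:.1f}%), planted 30% per region")

positives = scored[scored["positive"]].groupby("region", observed=True).size()
all_nuclei = scored.groupby("region", observed=True).size()
chi2, df, p = regional_distribution_test(positives, all_nuclei)
print(f"regional distribution: chi2 = {chi2:.2f}, df = {df}, p = {p:.3f}")
# A large p means positive nuclei follow the overall nuclear distribution,
# i.e. expression is not regionally biased.

counts = pd.Series({"VNC": 528, "brain_lobes": 188})
props = clone_proportions(counts)
print(f"\nglia counts {counts.to_dict()} -> proportions {props.to_dict()} "
      f"(VNC share rounds to {round(props['VNC'])}%)")

table = [[30, 8], [10, 25]]  # e.g. morphology type by nucleus position
odds, p = fisher_exact_2x2(table)
print(f"Fisher's exact on {table}: odds ratio {odds:.2f}, p = {p:.2e}")
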