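"""Synthetic single-cell atlases with planted ground truth.

Generates the inputs every downstream stage assumes, with known answers:

* multiple cell types, each with an exclusive marker program up-weighted by a
  configurable fold over baseline genes, and lognormally skewed library sizes;
* a designated "neuronal" gene program co-expressed by a planted fraction of
  contaminated cells, constructed so that after log-normalization their
  program values clear the standard ``<= 1`` gating threshold with margin
  while unflagged cells sit exactly at zero;
* a hemocyte-marker gene (``Hml-like``) expressed only by planted hemocytes;
* mitochondrial genes (``mt-*``) contributing a baseline read fraction;
* two batches with unequal proportions;
* matched per-type bulk TPM profiles, ROI intensity tables with known
  positive fractions, and clone-category tables with known proportions.

Counts are allocated multinomially over a per-type gene-probability vector,
the same read-allocation model the pseudo-cell annotation step assumes, which
keeps the oracle arithmetic exact. The contamination/hemocyte read mass is
placed deterministically (``ceil(strength * depth)`` reads per program gene)
so the planted gating ground truth is exact rather than merely likely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .annotate import TPM_TOTAL, BulkProfileSet

__all__ = [
    "SimConfig",
    "RoiIntensityParams",
    "NEURONAL_GENES",
    "HEMOCYTE_GENE",
    "gate_strength_for_value",
    "neuronal_contamination_rules",
    "simulate_atlas",
    "simulate_bulk_profiles",
    "simulate_roi_table",
    "simulate_clone_table",
]

#: Reserved gene names for the planted neuronal-contamination program.
NEURONAL_GENES = ("neu-1", "neu-2", "neu-3")
#: Reserved gene name for the planted hemocyte marker.
HEMOCYTE_GENE = "Hml-like"
BATCH_NAMES = ("batchA", "batchB")  # batchB is the minority by default


def gate_strength_for_value(target_value: float, scale_factor: float = 10_000.0) -> float:
    """Per-gene read fraction whose log-normalized value equals ``target_value``.

    Solves ``ln(1 + f * scale_factor) = target_value`` for f. Used to plant
    contaminated cells that clear the 1.0 gating threshold with margin.
    """
    return math.expm1(target_value) / scale_factor


@dataclass(frozen=True)
class SimConfig:
    """Atlas simulation settings; defaults are the standard study conditions.

    Four cell types of 200 cells each with 20 exclusive markers up-weighted
    8-fold, ~2,000-read lognormal library sizes, 5% mitochondrial genes, 10%
    neuronal-contaminated cells, 2% hemocytes, and a 95/5 batch split.
    """

    n_types: int = 4
    cells_per_type: tuple[int, ...] = (200, 200, 200, 200)
    n_genes: int = 500
    n_markers_per_type: int = 20
    marker_fold: float = 8.0
    baseline_mean: float = 1.0
    depth_lognormal_mu: float = 7.6  # median library size ~2,000 reads
    depth_lognormal_sigma: float = 0.35
    mito_gene_fraction: float = 0.05
    contamination_fraction: float = 0.10
    contamination_strength: float | None = None  # None -> solved for value 1.5
    hemocyte_fraction: float = 0.02
    rare_pair: tuple[int, int] | None = None
    batch_proportions: tuple[float, float] = (0.95, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 1:
            raise ValueError(f"n_types must be >= 1, got {self.n_types}")
        if len(self.cells_per_type) != self.n_types:
            raise ValueError(
                f"cells_per_type has length {len(self.cells_per_type)}, expected n_types={self.n_types}"
            )
        if any(c < 1 for c in self.cells_per_type):
            raise ValueError(f"cells_per_type entries must all be >= 1, got {self.cells_per_type}")
        if self.marker_fold < 1:
            raise ValueError(f"marker_fold must be >= 1, got {self.marker_fold}")
        if self.baseline_mean <= 0:
            raise ValueError(f"baseline_mean must be > 0, got {self.baseline_mean}")
        for name in ("mito_gene_fraction", "contamination_fraction", "hemocyte_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.contamination_strength is not None and self.contamination_strength < 0:
            raise ValueError(
                f"contamination_strength must be >= 0, got {self.contamination_strength}"
            )
        if not math.isclose(sum(self.batch_proportions), 1.0, rel_tol=1e-9):
            raise ValueError(f"batch_proportions must sum to 1, got {self.batch_proportions}")
        if self.rare_pair is not None:
            a, b = self.rare_pair
            if not (0 <= a < self.n_types and 0 <= b < self.n_types and a != b):
                raise ValueError(f"rare_pair must name two distinct type indices, got {self.rare_pair}")
        n_special = self._n_mito + len(NEURONAL_GENES) + 1
        n_generic = self.n_genes - n_special
        if n_generic < self.n_types * self.n_markers_per_type:
            raise ValueError(
                f"n_genes={self.n_genes} leaves only {n_generic} generic genes, fewer than the "
                f"{self.n_types * self.n_markers_per_type} marker genes requested"
            )

    @property
    def _n_mito(self) -> int:
        return int(round(self.mito_gene_fraction * self.n_genes))

    @property
    def resolved_contamination_strength(self) -> float:
        """Per-gene read fraction for planted contaminated cells (value 1.5, 50% over the gate)."""
        if self.contamination_strength is not None:
            return self.contamination_strength
        return gate_strength_for_value(1.5)


def neuronal_contamination_rules():
    """The standard clean-up gating rules on synthetic gene names:
    every neuronal program gene <= 1 and the hemocyte marker <= 0 (normalized)."""
    from .preprocess import GatingRule

    rules = [GatingRule(g, "<=", 1.0) for g in NEURONAL_GENES]
    rules.append(GatingRule(HEMOCYTE_GENE, "<=", 0.0))
    return rules


def _gene_table(config: SimConfig) -> pd.DataFrame:
    n_mito = config._n_mito
    n_generic = config.n_genes - n_mito - len(NEURONAL_GENES) - 1
    width = max(4, len(str(n_generic)))
    names = [f"g{i + 1:0{width}d}" for i in range(n_generic)]
    names += [f"mt-{i + 1:02d}" for i in range(n_mito)]
    names += list(NEURONAL_GENES)
    names += [HEMOCYTE_GENE]
    program = (
        ["generic"] * n_generic
        + ["mito"] * n_mito
        + ["neuronal"] * len(NEURONAL_GENES)
        + ["hemocyte"]
    )
    var = pd.DataFrame({"program": program}, index=pd.Index(names, name="gene_id"))
    var["is_mito"] = var["program"] == "mito"
    var["marker_of"] = pd.array([pd.NA] * config.n_genes, dtype="Int64")
    # exclusive marker blocks at the head of the generic pool
    for t in range(config.n_types):
        lo = t * config.n_markers_per_type
        var.iloc[lo : lo + config.n_markers_per_type, var.columns.get_loc("marker_of")] = t
    return var


def simulate_atlas(config: SimConfig = SimConfig()) -> tuple[AnnData, pd.DataFrame]:
    """Draw a synthetic atlas and its ground truth.

    Returns an AnnData of raw counts (cells x genes) with per-cell metadata
    (batch, total_counts, n_genes_detected, mito_frac) and per-gene metadata
    (program, is_mito, marker_of), plus a ground-truth table (true_type,
    contaminated, hemocyte, rare_pair_member). Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed)
    var = _gene_table(config)
    n_cells = int(sum(config.cells_per_type))
    n_genes = config.n_genes

    true_type = np.repeat(np.arange(config.n_types), config.cells_per_type)

    depths = np.rint(
        rng.lognormal(config.depth_lognormal_mu, config.depth_lognormal_sigma, n_cells)
    )
    depths = np.maximum(depths, 1).astype(np.int64)

    # disjoint contaminated / hemocyte cell sets
    n_contam = int(round(config.contamination_fraction * n_cells))
    n_hemo = int(round(config.hemocyte_fraction * n_cells))
    if n_contam + n_hemo > n_cells:
        raise ValueError("contamination_fraction + hemocyte_fraction exceed the cell count")
    perm = rng.permutation(n_cells)
    contaminated = np.zeros(n_cells, dtype=bool)
    hemocyte = np.zeros(n_cells, dtype=bool)
    contaminated[perm[:n_contam]] = True
    hemocyte[perm[n_contam : n_contam + n_hemo]] = True

    batch = np.asarray(BATCH_NAMES)[
        rng.choice(2, size=n_cells, p=list(config.batch_proportions))
    ]

    # per-type probability vectors over non-program genes
    marker_of = var["marker_of"].to_numpy()
    program = var["program"].to_numpy()
    allocatable = (program == "generic") | (program == "mito")
    neu_cols = np.flatnonzero(program == "neuronal")
    hml_col = int(np.flatnonzero(program == "hemocyte")[0])

    strength = config.resolved_contamination_strength
    extra = np.zeros((n_cells, n_genes), dtype=np.int64)
    if strength > 0:
        per_gene = np.ceil(strength * depths[contaminated]).astype(np.int64)
        for c in neu_cols:
            extra[contaminated, c] = per_gene
    hemo_reads = np.ceil(gate_strength_for_value(1.5) * depths[hemocyte]).astype(np.int64)
    extra[hemocyte, hml_col] = np.maximum(hemo_reads, 1)

    remaining = depths - extra.sum(axis=1)
    if np.any(remaining < 0):
        raise ValueError(
            "contamination_strength too large for the drawn library sizes "
            "(program reads exceed cell depth)"
        )

    counts = np.zeros((n_cells, n_genes), dtype=np.int64)
    for t in range(config.n_types):
        weights = np.where(allocatable, config.baseline_mean, 0.0)
        own = allocatable & (marker_of == t)
        weights[own] *= config.marker_fold
        p = weights / weights.sum()
        cells_t = np.flatnonzero(true_type == t)
        counts[cells_t] = rng.multinomial(remaining[cells_t], p)
    counts += extra

    cell_ids = [f"cell_{i + 1:05d}" for i in range(n_cells)]
    mito_counts = counts[:, var["is_mito"].to_numpy()].sum(axis=1)
    obs = pd.DataFrame(
        {
            "batch": batch,
            "total_counts": counts.sum(axis=1),
            "n_genes_detected": (counts > 0).sum(axis=1),
            "mito_frac": mito_counts / counts.sum(axis=1),
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    adata = AnnData(X=sp.csr_matrix(counts), obs=obs, var=var.copy())

    rare_member = np.zeros(n_cells, dtype=bool)
    if config.rare_pair is not None:
        rare_member = np.isin(true_type, list(config.rare_pair))
    truth = pd.DataFrame(
        {
            "true_type": true_type,
            "contaminated": contaminated,
            "hemocyte": hemocyte,
            "rare_pair_member": rare_member,
        },
        index=adata.obs_names,
    )
    return adata, truth


def simulate_bulk_profiles(adata: AnnData, truth: pd.DataFrame) -> BulkProfileSet:
    """Matched bulk TPM profiles: per true type, the per-gene mean count scaled
    to sum to one million."""
    if not adata.obs_names.equals(truth.index):
        raise ValueError("matrix and ground truth are not paired (cell ids differ)")
    X = adata.X
    if sp.issparse(X):
        X = X.toarray()
    df = pd.DataFrame(np.asarray(X, dtype=float), index=adata.obs_names, columns=adata.var_names)
    means = df.groupby(truth["true_type"], observed=True).mean()
    totals = means.sum(axis=1)
    if (totals <= 0).any():
        bad = list(means.index[totals <= 0])
        raise ValueError(f"cell types with zero total mean counts: {bad}")
    tpm = means.div(totals, axis=0) * TPM_TOTAL
    tpm.index = [f"type_{t}" for t in tpm.index]
    return BulkProfileSet(tpm=tpm)


@dataclass(frozen=True)
class RoiIntensityParams:
    """Intensity model for simulated HCR ROI tables.

    Scaled intensities (intensity / normalization_value) are drawn uniformly
    from ``negative_range`` for planted negatives and ``positive_range`` for
    planted positives; the ranges must clear the positivity threshold with
    margin on both sides so the planted flags are exactly recoverable.
    """

    normalization_value: float = 100.0
    threshold: float = 2.25
    negative_range: tuple[float, float] = (0.2, 1.8)
    positive_range: tuple[float, float] = (2.9, 6.0)

    def __post_init__(self) -> None:
        if self.normalization_value <= 0:
            raise ValueError("normalization_value must be > 0")
        if self.negative_range[1] >= self.threshold:
            raise ValueError("negative_range must lie strictly below the threshold")
        if self.positive_range[0] <= self.threshold:
            raise ValueError("positive_range must lie strictly above the threshold")


def simulate_roi_table(
    n_nuclei: int,
    region_props: Sequence[float],
    positive_frac_per_region: Sequence[float],
    intensity_params: RoiIntensityParams = RoiIntensityParams(),
    seed: int = 0,
    region_names: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-nucleus region labels and mean intensities with planted positives.

    Returns the ROI table (roi_id, region, mean_intensity) and the planted
    per-nucleus positivity flags. ``round(frac * n_region)`` nuclei per region
    are planted positive, at randomized positions.
    """
    region_props = np.asarray(region_props, dtype=float)
    positive_frac = np.asarray(positive_frac_per_region, dtype=float)
    if len(region_props) != len(positive_frac):
        raise ValueError(
            f"region_props (len {len(region_props)}) and positive_frac_per_region "
            f"(len {len(positive_frac)}) must have equal length"
        )
    if not math.isclose(region_props.sum(), 1.0, rel_tol=1e-9):
        raise ValueError(f"region_props must sum to 1, got {region_props.sum()}")
    if ((positive_frac < 0) | (positive_frac > 1)).any():
        raise ValueError("positive_frac_per_region entries must be in [0, 1]")
    if region_names is None:
        region_names = [f"region_{i + 1}" for i in range(len(region_props))]

    rng = np.random.default_rng(seed)
    region_counts = rng.multinomial(n_nuclei, region_props)
    rows = []
    flags = []
    roi = 0
    for r, (name, n_r, frac) in enumerate(zip(region_names, region_counts, positive_frac)):
        n_pos = int(round(frac * n_r))
        is_pos = np.zeros(n_r, dtype=bool)
        is_pos[rng.permutation(n_r)[:n_pos]] = True
        lo_n, hi_n = intensity_params.negative_range
        lo_p, hi_p = intensity_params.positive_range
        scaled = np.where(
            is_pos,
            rng.uniform(lo_p, hi_p, n_r),
            rng.uniform(lo_n, hi_n, n_r),
        )
        for i in range(n_r):
            rows.append(
                {
                    "roi_id": f"roi_{roi + 1:05d}",
                    "region": name,
                    "mean_intensity": scaled[i] * intensity_params.normalization_value,
                }
            )
            flags.append(bool(is_pos[i]))
            roi += 1
    table = pd.DataFrame(rows).set_index("roi_id")
    truth = pd.Series(flags, index=table.index, name="positive")
    return table, truth


def simulate_clone_table(
    category_probs: Sequence[float],
    n_clones: int,
    seed: int = 0,
    categories: Sequence[str] | None = None,
) -> pd.Series:
    """Multinomial clone-category counts totalling ``n_clones``."""
    probs = np.asarray(category_probs, dtype=float)
    if (probs < 0).any():
        raise ValueError(f"category probabilities must be nonnegative, got {list(probs)}")
    if not math.isclose(probs.sum(), 1.0, rel_tol=1e-9):
        raise ValueError(f"category probabilities must sum to 1, got {probs.sum()}")
    if n_clones < 1:
        raise ValueError(f"n_clones must be >= 1, got {n_clones}")
    if categories is None:
        categories = [f"category_{i + 1}" for i in range(len(probs))]
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_clones, probs)
    return pd.Series(counts, index=pd.Index(categories, name="category"), name="n_clones")
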