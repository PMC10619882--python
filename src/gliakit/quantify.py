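"""Imaging and morphology statistics for in-situ validation experiments.

Covers the quantification steps that accompany HCR (hybridization chain
reaction) stainings and clonal morphology data:

* per-nucleus positivity scoring: mean probe intensities are scaled by a
  per-sample normalization value (the mean intensity of an average-intensity
  projection of the probe channel) and called positive strictly above a
  threshold of 2.25;
* a goodness-of-fit chi-square comparing the regional distribution of
  positive nuclei to the distribution of all nuclei;
* Laplacian-of-Gaussian nuclei detection in image stacks;
* layer-binned volume measurements of masked cells;
* clone-category proportions with Fisher's exact, Mann-Whitney U and
  chi-square tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage.feature import blob_log
from skimage.restoration import rolling_ball

__all__ = [
    "PositivityParams",
    "LayerMask",
    "compute_normalization_value",
    "subtract_background",
    "score_hcr_positivity",
    "regional_distribution_test",
    "detect_nuclei",
    "layer_binned_volume",
    "clone_proportions",
    "fisher_exact_2x2",
    "mann_whitney_u",
    "chi_square_gof",
    "clone_proportion_stats",
]


@dataclass(frozen=True)
class PositivityParams:
    """HCR positivity settings: the per-sample normalization value and the
    scaled-intensity threshold (strictly above = positive)."""

    normalization_value: float
    threshold: float = 2.25

    def __post_init__(self) -> None:
        if self.normalization_value <= 0:
            raise ValueError(
                f"normalization_value must be > 0, got {self.normalization_value}"
            )


def subtract_background(image: np.ndarray, radius: int = 50) -> np.ndarray:
    """Rolling-ball background subtraction (optional pre-projection step)."""
    return image - rolling_ball(image, radius=radius)


def compute_normalization_value(projection: np.ndarray) -> float:
    """Mean pixel intensity of an average-intensity projection.

    Accepts a 2-D projection or a 3-D stack (averaged over the first axis
    first, which by linearity gives the same grand mean).
    """
    img = np.asarray(projection, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim == 3:
        img = img.mean(axis=0)
    value = float(img.mean())
    if value <= 0:
        raise ValueError(f"normalization value must be > 0, got {value}")
    return value


def score_hcr_positivity(
    rois: pd.DataFrame,
    params: PositivityParams,
    regions: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Scale per-nucleus mean intensities and call positives.

    ``rois`` needs ``region`` and ``mean_intensity`` columns. A nucleus is
    positive iff ``mean_intensity / normalization_value`` is strictly above
    the threshold. Returns the table with ``scaled`` and ``positive`` columns
    plus a summary of overall and per-region positive fractions.
    """
    required = {"region", "mean_intensity"}
    missing = required - set(rois.columns)
    if missing:
        raise ValueError(f"ROI table lacks required columns: {sorted(missing)}")
    if regions is not None:
        unknown = set(rois["region"]) - set(regions)
        if unknown:
            raise ValueError(f"unknown region labels: {sorted(unknown)}")
    out = rois.copy()
    out["scaled"] = out["mean_intensity"] / params.normalization_value
    out["positive"] = out["scaled"] > params.threshold
    summary = {
        "n_nuclei": int(len(out)),
        "n_positive": int(out["positive"].sum()),
        "positive_frac": float(out["positive"].mean()) if len(out) else float("nan"),
        "per_region": out.groupby("region", observed=True)["positive"].mean().to_dict(),
    }
    return out, summary


def regional_distribution_test(
    positives: pd.Series, all_nuclei: pd.Series
) -> tuple[float, int, float]:
    """Chi-square goodness of fit of positive-nucleus counts against the
    regional distribution of all nuclei.

    Expected counts are ``total positives x region share of all nuclei``;
    degrees of freedom = regions - 1.
    """
    positives = pd.Series(positives, dtype=float)
    all_nuclei = pd.Series(all_nuclei, dtype=float).reindex(positives.index)
    if all_nuclei.isna().any():
        raise ValueError("positives and all_nuclei must share the same regions")
    if len(positives) < 2:
        raise ValueError("need at least 2 regions (df would be 0)")
    if (all_nuclei <= 0).any():
        bad = list(all_nuclei.index[all_nuclei <= 0])
        raise ValueError(
            f"regions with zero nuclei give zero expected counts; merge regions: {bad}"
        )
    expected = positives.sum() * all_nuclei / all_nuclei.sum()
    chi2, p = stats.chisquare(positives.to_numpy(), expected.to_numpy())
    return float(chi2), len(positives) - 1, float(p)


def detect_nuclei(
    stack: np.ndarray, scale_px: float = 13, sensitivity: float = 70.0
) -> np.ndarray:
    """Laplacian-of-Gaussian blob detection of nuclei.

    ``scale_px`` is the approximate nucleus diameter in pixels; sensitivity
    (0-100) maps linearly to a relative peak threshold (1.0 at 0 down to 0.0
    at 100). Returns centroid coordinates, one row per detection.
    """
    img = np.asarray(stack, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    peak = img.max()
    if peak <= 0:
        return np.empty((0, img.ndim))
    # blob radius ~ sigma * sqrt(ndim); scale_px is a diameter
    sigma = scale_px / (2.0 * math.sqrt(img.ndim))
    threshold_rel = 1.0 - np.clip(sensitivity, 0.0, 100.0) / 100.0
    blobs = blob_log(
        img / peak,
        min_sigma=sigma * 0.75,
        max_sigma=sigma * 1.25,
        num_sigma=5,
        threshold=None,
        threshold_rel=max(threshold_rel, 1e-6),
    )
    return blobs[:, : img.ndim]


@dataclass(frozen=True)
class LayerMask:
    """A binary cell mask with neuropil-layer geometry.

    ``boundaries`` are the strictly increasing layer boundary positions (in
    micrometres) along ``axis``; consecutive layers are combined
    ``bin_width`` at a time. Voxels are assigned to layers by the half-open
    interval [lower, upper) containing their centre.
    """

    mask: np.ndarray
    voxel_size: tuple[float, ...]
    boundaries: tuple[float, ...]
    bin_width: int = 2
    axis: int = 0

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if len(b) < 2:
            raise ValueError("need at least 2 boundary planes (one layer)")
        if not (np.diff(b) > 0).all():
            raise ValueError(f"boundaries must be strictly increasing, got {self.boundaries}")
        if self.bin_width < 1:
            raise ValueError(f"bin_width must be >= 1, got {self.bin_width}")
        if len(self.voxel_size) != np.ndim(self.mask):
            raise ValueError("voxel_size must give one spacing per mask axis")


def layer_binned_volume(layer_mask: LayerMask) -> pd.Series:
    """Volume of the masked object per layer bin (plus an ``outside`` bin).

    Voxel centres at ``(index + 0.5) * voxel_size[axis]`` are binned into
    half-open layer intervals; ``bin_width`` consecutive layers share a bin.
    The sum over all bins equals the total mask volume exactly.
    """
    mask = np.asarray(layer_mask.mask).astype(bool)
    voxel_volume = float(np.prod(layer_mask.voxel_size))
    b = np.asarray(layer_mask.boundaries, dtype=float)
    n_layers = len(b) - 1
    n_bins = math.ceil(n_layers / layer_mask.bin_width)

    coords = (np.arange(mask.shape[layer_mask.axis]) + 0.5) * layer_mask.voxel_size[
        layer_mask.axis
    ]
    # layer index per slice along the axis; -1 = outside
    layer_idx = np.searchsorted(b, coords, side="right") - 1
    layer_idx[(coords < b[0]) | (coords >= b[-1])] = -1

    # voxels per slice along the layer axis
    per_slice = mask.sum(axis=tuple(i for i in range(mask.ndim) if i != layer_mask.axis))

    labels = [f"bin_{i + 1}" for i in range(n_bins)] + ["outside"]
    volumes = pd.Series(0.0, index=pd.Index(labels, name="layer_bin"))
    for sl, n_vox in enumerate(per_slice):
        if n_vox == 0:
            continue
        li = layer_idx[sl]
        key = "outside" if li < 0 else f"bin_{li // layer_mask.bin_width + 1}"
        volumes[key] += float(n_vox) * voxel_volume
    return volumes


def clone_proportions(counts: pd.Series, decimals: int = 1) -> pd.Series:
    """Category proportions as percentages, rounded to ``decimals`` places."""
    counts = pd.Series(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("counts sum to zero")
    return (100.0 * counts / total).round(decimals)


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test; p sums table probabilities <= observed."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError(f"Fisher's exact test needs a 2x2 table, got shape {table.shape}")
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact enumeration when both samples have <= 20 observations and no ties;
    otherwise the tie-corrected normal approximation (mid-ranks). Returns
    (U of the first sample, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(x), len(y)) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def chi_square_gof(observed, expected=None) -> tuple[float, int, float]:
    """Goodness-of-fit chi-square of a 1 x k count vector (no continuity
    correction); uniform expectation when ``expected`` is omitted."""
    observed = np.asarray(observed, dtype=float)
    if (observed < 0).any():
        raise ValueError("counts must be nonnegative")
    if len(observed) < 2:
        raise ValueError("need at least 2 categories")
    chi2, p = stats.chisquare(observed, expected)
    return float(chi2), len(observed) - 1, float(p)


def clone_proportion_stats(table: pd.DataFrame, test: str = "fisher") -> dict:
    """Proportions plus one requested test on a clone-category table.

    ``table`` is categories x groups (integer counts). Tests: ``fisher``
    (2x2), ``chi2`` (first column observed vs second as expected proportions),
    or ``none``.
    """
    table = pd.DataFrame(table)
    if (table.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    out = {
        "proportions_pct": {
            col: clone_proportions(table[col]).to_dict() for col in table.columns
        }
    }
    if test == "fisher":
        odds, p = fisher_exact_2x2(table.to_numpy())
        out["fisher"] = {"odds_ratio": odds, "p_value": p}
    elif test == "chi2":
        obs = table.iloc[:, 0].to_numpy(dtype=float)
        ref = table.iloc[:, 1].to_numpy(dtype=float)
        expected = obs.sum() * ref / ref.sum()
        chi2, df, p = chi_square_gof(obs, expected)
        out["chi2"] = {"statistic": chi2, "df": df, "p_value": p}
    elif test != "none":
        raise ValueError(f"unknown test {test!r}")
    return out
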