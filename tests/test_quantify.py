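import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from gliakit import synthgen
from gliakit.quantify import (
    LayerMask,
    PositivityParams,
    chi_square_gof,
    clone_proportion_stats,
    clone_proportions,
    compute_normalization_value,
    detect_nuclei,
    fisher_exact_2x2,
    layer_binned_volume,
    mann_whitney_u,
    regional_distribution_test,
    score_hcr_positivity,
)


class TestNormalizationValue:
    def test_constant_image(self):
        assert compute_normalization_value(np.full((5, 5), 3.0)) == 3.0

    def test_small_mean(self):
        assert compute_normalization_value(np.array([[0.0, 2.0], [4.0, 6.0]])) == 3.0

    def test_stack_equals_grand_mean(self):
        rng = np.random.default_rng(0)
        stack = rng.uniform(0, 10, (4, 8, 8))
        assert compute_normalization_value(stack) == pytest.approx(stack.mean())

    def test_zero_image_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            compute_normalization_value(np.zeros((3, 3)))


class TestHCRPositivity:
    def _rois(self, intensities, regions=None):
        n = len(intensities)
        return pd.DataFrame(
            {
                "region": regions or ["medulla"] * n,
                "mean_intensity": intensities,
            },
            index=[f"roi_{i}" for i in range(n)],
        )

    def test_scaled_above_threshold_positive(self):
        scored, _ = score_hcr_positivity(self._rois([5.0]), PositivityParams(2.0))
        assert scored["scaled"].iloc[0] == 2.5
        assert scored["positive"].iloc[0]

    def test_boundary_is_strict(self):
        scored, _ = score_hcr_positivity(
            self._rois([2.25, 2.26]), PositivityParams(1.0)
        )
        assert not scored["positive"].iloc[0]  # exactly 2.25 is negative
        assert scored["positive"].iloc[1]

    def test_zero_intensity_negative(self):
        scored, summary = score_hcr_positivity(self._rois([0.0]), PositivityParams(1.0))
        assert not scored["positive"].iloc[0]
        assert summary["positive_frac"] == 0.0

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError, match="unknown region"):
            score_hcr_positivity(
                self._rois([1.0], regions=["lamina"]),
                PositivityParams(1.0),
                regions=["medulla", "lobula"],
            )

    def test_recovers_planted_flags(self):
        params = synthgen.RoiIntensityParams()
        table, truth = synthgen.simulate_roi_table(
            400, [0.4, 0.3, 0.3], [0.2, 0.5, 0.8], intensity_params=params, seed=7
        )
        scored, _ = score_hcr_positivity(
            table, PositivityParams(params.normalization_value)
        )
        assert (scored["positive"] == truth).all()


class TestRegionalDistribution:
    def test_proportional_counts_null(self):
        pos = pd.Series({"med": 10, "lob": 20, "lp": 30})
        allc = pd.Series({"med": 100, "lob": 200, "lp": 300})
        chi2, df, p = regional_distribution_test(pos, allc)
        assert chi2 == pytest.approx(0.0)
        assert df == 2
        assert p == pytest.approx(1.0)

    def test_worked_statistic(self):
        # positives (10, 30) with all-nuclei shares 0.5/0.5 -> expected (20, 20), chi2 = 10
        chi2, df, p = regional_distribution_test(
            pd.Series({"a": 10, "b": 30}), pd.Series({"a": 50, "b": 50})
        )
        assert chi2 == pytest.approx(10.0)
        assert df == 1

    def test_single_region_rejected(self):
        with pytest.raises(ValueError, match="2 regions"):
            regional_distribution_test(pd.Series({"a": 5}), pd.Series({"a": 50}))

    def test_zero_expected_instructs_merge(self):
        with pytest.raises(ValueError, match="merge"):
            regional_distribution_test(
                pd.Series({"a": 5, "b": 1}), pd.Series({"a": 50, "b": 0})
            )


def _gaussian_blob(shape, center, sigma):
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return np.exp(-d2 / (2 * sigma**2))


class TestDetectNuclei:
    def test_blank_image(self):
        assert detect_nuclei(np.zeros((32, 32)), scale_px=5).shape[0] == 0

    def test_single_nucleus_centroid(self):
        img = _gaussian_blob((48, 48), (24.0, 20.0), sigma=3.0)
        centroids = detect_nuclei(img, scale_px=8, sensitivity=60)
        assert centroids.shape[0] == 1
        assert np.abs(centroids[0] - np.array([24.0, 20.0])).max() <= 1.0

    def test_two_separated_nuclei(self):
        img = _gaussian_blob((64, 64), (16.0, 16.0), 3.0) + _gaussian_blob(
            (64, 64), (48.0, 48.0), 3.0
        )
        centroids = detect_nuclei(img, scale_px=8, sensitivity=60)
        assert centroids.shape[0] == 2


class TestLayerVolumes:
    def test_counts_times_voxel_volume(self):
        mask = np.zeros((10, 2, 2), dtype=bool)
        mask[0, :, :] = True  # 4 voxels in the first slice
        mask[1, 0, 0] = True
        mask[1, 0, 1] = True  # 2 voxels in the second slice
        lm = LayerMask(
            mask=mask,
            voxel_size=(1.0, 0.5, 0.5),  # voxel volume 0.25
            boundaries=(0.0, 2.0, 4.0),
            bin_width=1,
            axis=0,
        )
        vols = layer_binned_volume(lm)
        assert vols["bin_1"] == pytest.approx(6 * 0.25)
        assert vols["bin_2"] == 0.0

    def test_empty_mask(self):
        lm = LayerMask(np.zeros((4, 4, 4), bool), (1.0, 1.0, 1.0), (0.0, 4.0))
        assert (layer_binned_volume(lm) == 0).all()

    def test_conservation_with_outside(self):
        rng = np.random.default_rng(1)
        mask = rng.random((20, 5, 5)) > 0.5
        lm = LayerMask(mask, (1.0, 1.0, 1.0), (4.0, 8.0, 12.0), bin_width=2)
        vols = layer_binned_volume(lm)
        assert vols.sum() == pytest.approx(mask.sum() * 1.0)
        assert vols["outside"] > 0  # voxels below 4.0 and at/above 12.0

    def test_bad_boundaries_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            LayerMask(np.zeros((2, 2), bool), (1.0, 1.0), (3.0, 1.0))


def fisher_two_sided_enumeration(a, b, c, d):
    """Independent oracle: sum of hypergeometric table probabilities not
    exceeding the observed table's probability, in exact rational arithmetic."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def prob(x):
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), denom)

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs)
    return float(total)


class TestCloneStats:
    def test_proportions_worked_example(self):
        counts = pd.Series({"type_a": 70, "type_b": 22, "type_c": 9})
        props = clone_proportions(counts)
        assert props.to_dict() == {"type_a": 69.3, "type_b": 21.8, "type_c": 8.9}

    def test_vnc_share_rounds_to_74(self):
        props = clone_proportions(pd.Series({"vnc": 528, "brain": 188}))
        assert props["vnc"] == 73.7
        assert round(props["vnc"]) == 74

    def test_fisher_worked_example(self):
        _, p = fisher_exact_2x2([[10, 0], [0, 10]])
        assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_fisher_exhaustive_small_margins(self):
        """Two-sided Fisher p matches exact enumeration for every 2x2 table
        with all margins <= 12."""
        for a in range(13):
            for b in range(13 - a):
                for c in range(13 - a):
                    for d in range(min(13 - c, 13 - b)):
                        if a + b + c + d == 0:
                            continue
                        _, p = fisher_exact_2x2([[a, b], [c, d]])
                        oracle = fisher_two_sided_enumeration(a, b, c, d)
                        assert p == pytest.approx(oracle, rel=1e-8, abs=1e-12), (
                            a,
                            b,
                            c,
                            d,
                        )

    def test_mann_whitney_identical_samples(self):
        x = np.arange(10, dtype=float)
        U, p = mann_whitney_u(x, x)
        assert U == 10 * 10 / 2
        assert p >= 0.99

    def test_mann_whitney_exact_small_shift(self):
        U, p = mann_whitney_u([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert U == 0.0
        assert p == pytest.approx(0.1, rel=1e-9)  # 2 * 1/C(6,3)

    def test_chi_square_uniform_null(self):
        chi2, df, p = chi_square_gof([25, 25, 25, 25])
        assert chi2 == 0.0 and df == 3 and p == pytest.approx(1.0)

    def test_stats_dispatcher(self):
        table = pd.DataFrame({"g1": [10, 0], "g2": [0, 10]}, index=["t1", "t2"])
        out = clone_proportion_stats(table, test="fisher")
        assert out["fisher"]["p_value"] == pytest.approx(2 / math.comb(20, 10), rel=1e-9)
        assert out["proportions_pct"]["g1"]["t1"] == 100.0
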