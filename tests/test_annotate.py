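import numpy as np
import pandas as pd
import pytest

from gliakit import annotate, preprocess, synthgen
from gliakit.annotate import (
    BulkProfileSet,
    PseudoCellParams,
    cluster_dendrogram,
    estimate_depth_params,
    marker_summary,
    match_bulk_to_clusters,
    simulate_pseudo_cells,
)
from gliakit.trees import linkage_to_newick


class TestDepthParams:
    def test_constant_totals(self, make_counts_adata):
        adata = make_counts_adata(np.full((3, 2), 50))  # totals 100 each
        assert estimate_depth_params(adata) == (100.0, 0.0)

    def test_sample_sd(self, make_counts_adata):
        adata = make_counts_adata([[100, 0], [300, 0]])
        mean, sd = estimate_depth_params(adata)
        assert mean == 200.0
        assert sd == pytest.approx(141.4213562, rel=1e-6)

    def test_single_cell_rejected(self, make_counts_adata):
        with pytest.raises(ValueError, match="2 cells"):
            estimate_depth_params(make_counts_adata([[1, 2]]))


class TestSimulatePseudoCells:
    def test_default_cell_count_is_900(self):
        tpm = pd.Series([5e5, 5e5], index=["a", "b"])
        out = simulate_pseudo_cells(tpm, PseudoCellParams(depth_mean=100, seed=0))
        assert out.n_obs == 900

    def test_one_hot_tpm(self):
        tpm = pd.Series([1e6, 0.0, 0.0], index=["a", "b", "c"])
        out = simulate_pseudo_cells(tpm, PseudoCellParams(depth_mean=500, depth_sd=50, seed=1))
        X = out.X.toarray()
        assert (X[:, 1:] == 0).all()
        assert (X[:, 0] == out.obs["total_counts"].to_numpy()).all()

    def test_reads_conserved_per_cell(self):
        tpm = pd.Series([3e5, 7e5], index=["a", "b"])
        out = simulate_pseudo_cells(tpm, PseudoCellParams(depth_mean=200, depth_sd=40, seed=2))
        totals = np.asarray(out.X.sum(axis=1)).ravel()
        assert (totals == out.obs["total_counts"].to_numpy()).all()
        assert totals.min() >= 1

    def test_even_split_within_binomial_se(self):
        tpm = pd.Series([5e5, 5e5], index=["a", "b"])
        params = PseudoCellParams(depth_mean=2000, depth_sd=0, n_cells=900, seed=3)
        out = simulate_pseudo_cells(tpm, params)
        n_reads = int(out.X.sum())
        frac = out.X.toarray()[:, 0].sum() / n_reads
        se = np.sqrt(0.25 / n_reads)
        assert abs(frac - 0.5) < 3 * se

    def test_deep_pool_converges_to_tpm(self):
        rng = np.random.default_rng(0)
        tpm_vals = rng.uniform(0.5, 1.5, 50)
        tpm_vals[rng.choice(50, 10, replace=False)] = 0.0
        tpm = pd.Series(tpm_vals / tpm_vals.sum() * 1e6, index=[f"g{i}" for i in range(50)])
        params = PseudoCellParams(depth_mean=1e5, depth_sd=0, n_cells=900, seed=4)
        out = simulate_pseudo_cells(tpm, params)
        pooled = np.asarray(out.X.sum(axis=0)).ravel()
        pooled = pooled / pooled.sum()
        expected = (tpm / 1e6).to_numpy()
        expressed = expected > 0
        np.testing.assert_allclose(pooled[expressed], expected[expressed], rtol=0.01)
        assert (pooled[~expressed] == 0).all()

    def test_all_zero_tpm_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            simulate_pseudo_cells(
                pd.Series([0.0, 0.0]), PseudoCellParams(depth_mean=100)
            )


class TestBulkProfileSet:
    def test_row_sum_validation(self):
        with pytest.raises(ValueError, match="1e6"):
            BulkProfileSet(pd.DataFrame([[1.0, 2.0]], index=["t"], columns=["a", "b"]))

    def test_csv_roundtrip(self, tmp_path):
        tpm = pd.DataFrame(
            [[2.5e5, 7.5e5], [5e5, 5e5]], index=["t1", "t2"], columns=["a", "b"]
        )
        bulk = BulkProfileSet(tpm)
        path = tmp_path / "bulk.csv"
        bulk.to_csv(path)
        back = BulkProfileSet.from_csv(path)
        pd.testing.assert_frame_equal(back.tpm, tpm)


@pytest.fixture(scope="module")
def matched(two_type_atlas):
    adata, truth = two_type_atlas
    norm = preprocess.lognormalize(adata)
    labels = pd.Series(truth["true_type"].astype(str).to_numpy(), index=adata.obs_names)
    bulk = synthgen.simulate_bulk_profiles(adata, truth)
    params = PseudoCellParams(depth_mean=2000, depth_sd=0, n_cells=900, seed=0)
    return bulk, params, norm, labels


class TestMatchBulkToClusters:
    def test_self_consistency(self, matched):
        """A bulk profile built from a cluster's own cells matches that cluster."""
        bulk, params, norm, labels = matched
        asn = match_bulk_to_clusters(bulk, params, norm, labels)
        assert asn.best_match["type_0"] == "0"
        assert asn.best_match["type_1"] == "1"
        assert asn.matrix.loc["type_0", "0"] > 0.99
        assert asn.matrix.loc["type_1", "1"] > 0.99

    def test_correlations_bounded(self, matched):
        bulk, params, norm, labels = matched
        asn = match_bulk_to_clusters(bulk, params, norm, labels)
        vals = asn.matrix.to_numpy()
        assert np.nanmin(vals) >= -1.0 and np.nanmax(vals) <= 1.0

    def test_relabeling_invariance(self, matched):
        bulk, params, norm, labels = matched
        renamed = labels.map({"0": "glia_x", "1": "glia_y"})
        asn = match_bulk_to_clusters(bulk, params, norm, renamed)
        assert asn.best_match["type_0"] == "glia_x"
        assert asn.best_match["type_1"] == "glia_y"

    def test_one_hot_orthogonal_signatures(self, make_values_adata):
        # two clusters with disjoint one-hot signatures; matching one-hot bulk
        vals = np.array([[5.0, 0.0], [5.0, 0.0], [0.0, 5.0], [0.0, 5.0]])
        norm = make_values_adata(vals, gene_ids=["a", "b"])
        norm.uns["normalization"] = {"scale_factor": 10_000.0}
        labels = pd.Series(["c1", "c1", "c2", "c2"], index=norm.obs_names)
        bulk = BulkProfileSet(
            pd.DataFrame(
                [[1e6, 0.0], [0.0, 1e6]], index=["t1", "t2"], columns=["a", "b"]
            )
        )
        params = PseudoCellParams(depth_mean=1000, depth_sd=0, n_cells=50, seed=0)
        asn = match_bulk_to_clusters(bulk, params, norm, labels)
        assert asn.best_match["t1"] == "c1"
        assert asn.best_match["t2"] == "c2"

    def test_too_few_shared_genes_rejected(self, matched, make_values_adata):
        bulk, params, _, _ = matched
        norm = make_values_adata([[1.0]], gene_ids=["unshared"])
        labels = pd.Series(["x"], index=norm.obs_names)
        with pytest.raises(ValueError, match="shared genes"):
            match_bulk_to_clusters(bulk, params, norm, labels)


class TestMarkerSummary:
    def test_pct_and_mean(self, make_values_adata):
        vals = np.array([[1.0], [2.0], [0.0], [0.0]])
        norm = make_values_adata(vals, gene_ids=["m"])
        labels = pd.Series(["A"] * 4, index=norm.obs_names)
        stats = marker_summary(norm, labels, ["m"])
        assert stats.loc[("A", "m"), "pct_expressing"] == 0.5
        assert stats.loc[("A", "m"), "mean_expression"] == 0.75

    def test_all_zero_gene(self, make_values_adata):
        norm = make_values_adata(np.zeros((3, 1)), gene_ids=["m"])
        labels = pd.Series(["A"] * 3, index=norm.obs_names)
        stats = marker_summary(norm, labels, ["m"])
        assert stats.loc[("A", "m"), "pct_expressing"] == 0.0
        assert stats.loc[("A", "m"), "mean_expression"] == 0.0

    def test_singleton_cluster(self, make_values_adata):
        norm = make_values_adata([[2.5]], gene_ids=["m"])
        labels = pd.Series(["solo"], index=norm.obs_names)
        stats = marker_summary(norm, labels, ["m"])
        assert stats.loc[("solo", "m"), "mean_expression"] == 2.5
        assert stats.loc[("solo", "m"), "pct_expressing"] == 1.0


class TestClusterDendrogram:
    def test_identical_averages_merge_at_zero(self, make_values_adata):
        vals = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        norm = make_values_adata(vals)
        labels = pd.Series(["a", "b", "c"], index=norm.obs_names)
        Z, leaves = cluster_dendrogram(norm, labels)
        assert Z[0, 2] == 0.0  # first merge at height 0

    def test_one_dimensional_merge_order(self, make_values_adata):
        vals = np.array([[0.0], [1.0], [10.0]])
        norm = make_values_adata(vals)
        labels = pd.Series(["x", "y", "z"], index=norm.obs_names)
        Z, leaves = cluster_dendrogram(norm, labels)
        assert Z[0, 2] == pytest.approx(1.0)  # (0, 1) merge first at height 1
        merged = {leaves[int(Z[0, 0])], leaves[int(Z[0, 1])]}
        assert merged == {"x", "y"}

    def test_merge_count_and_newick(self, small_norm, small_atlas):
        _, truth = small_atlas
        labels = pd.Series(truth["true_type"].astype(str).to_numpy(), index=small_norm.obs_names)
        Z, leaves = cluster_dendrogram(small_norm, labels)
        assert Z.shape[0] == len(leaves) - 1
        nwk = linkage_to_newick(Z, leaves)
        assert nwk.endswith(";") and all(l in nwk for l in leaves)

    def test_single_cluster_rejected(self, make_values_adata):
        norm = make_values_adata([[1.0], [1.0]])
        labels = pd.Series(["only", "only"], index=norm.obs_names)
        with pytest.raises(ValueError, match="2 clusters"):
            cluster_dendrogram(norm, labels)
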