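import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aocluster import (
    agreement_metrics,
    average_cluster_purity,
    baseline_distance_matrix,
    centroid_expression_distance,
    evaluate_labels,
    rank_all_clusters,
    score_marker_set_on_reference,
    stouffer_composite,
)
from aocluster.markers import lognormalize

from conftest import ami_oracle, pair_counting_oracle
from test_markers import make_dataset


class TestAgreementMetrics:
    def test_perfect_prediction(self):
        truth = ["A", "A", "B", "B", "C"]
        pred = ["x", "x", "y", "y", "z"]
        assert agreement_metrics(truth, pred) == (1.0, 1.0, 1.0)

    def test_single_cluster_has_zero_adjusted_index(self):
        truth = ["A"] * 5 + ["B"] * 5
        pred = ["u"] * 10
        ari, ami, fms = agreement_metrics(truth, pred)
        assert ari == pytest.approx(0.0, abs=1e-12)

    def test_toy_matches_exhaustive_pair_counting(self):
        truth = list("AABBBC")
        pred = list("112233")
        ari, ami, fms = agreement_metrics(truth, pred)
        ari_o, fms_o = pair_counting_oracle(truth, pred)
        assert ari == pytest.approx(ari_o, abs=1e-10)
        assert fms == pytest.approx(fms_o, abs=1e-10)
        assert ami == pytest.approx(ami_oracle(truth, pred), abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_small_partitions_match_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 30))
        truth = [str(x) for x in rng.integers(0, 4, n)]
        pred = [str(x) for x in rng.integers(0, 4, n)]
        if len(set(truth)) < 2 or len(set(pred)) < 2:
            truth[0], pred[0] = "zz", "zz"
        ari, ami, fms = agreement_metrics(truth, pred)
        ari_o, fms_o = pair_counting_oracle(truth, pred)
        assert ari == pytest.approx(ari_o, abs=1e-10)
        assert fms == pytest.approx(fms_o, abs=1e-10)
        assert ami == pytest.approx(ami_oracle(truth, pred), abs=1e-10)

    def test_label_permutation_invariance_and_chance_level(self):
        rng = np.random.default_rng(0)
        truth = [str(x) for x in rng.integers(0, 5, 600)]
        pred = [str(x) for x in rng.integers(0, 5, 600)]
        ari, ami, _ = agreement_metrics(truth, pred)
        assert abs(ari) < 0.05 and abs(ami) < 0.05
        relabel = {s: f"new{s}" for s in set(pred)}
        assert agreement_metrics(truth, [relabel[p] for p in pred]) == (
            pytest.approx(ari),
            pytest.approx(ami),
            pytest.approx(agreement_metrics(truth, pred)[2]),
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            agreement_metrics(["A"], ["A", "B"])


class TestPurity:
    def test_examples(self):
        assert average_cluster_purity(list("AABB"), list("xxyy")) == 1.0
        assert average_cluster_purity(list("AAAB"), list("xxxx")) == 0.75
        truth = list("AAAB") + list("CCCCCC")
        pred = ["x"] * 4 + ["y"] * 6
        assert average_cluster_purity(truth, pred) == pytest.approx(0.9)
        assert average_cluster_purity(truth, pred, cell_weighted=False) == (
            pytest.approx((0.75 + 1.0) / 2)
        )

    def test_splitting_never_decreases_purity(self):
        rng = np.random.default_rng(1)
        truth = [str(x) for x in rng.integers(0, 3, 60)]
        pred = [str(x) for x in rng.integers(0, 3, 60)]
        base = average_cluster_purity(truth, pred)
        split = list(pred)
        for i in range(0, 60, 2):  # split cluster "0" arbitrarily
            if split[i] == "0":
                split[i] = "0bis"
        assert average_cluster_purity(truth, split) >= base - 1e-12

    def test_purity_one_iff_refinement(self):
        truth = list("AABBBB")
        refining = ["x", "x", "y", "y", "z", "z"]
        not_refining = ["x", "y", "y", "y", "z", "z"]
        assert average_cluster_purity(truth, refining) == 1.0
        assert average_cluster_purity(truth, not_refining) < 1.0


class TestCentroidDistance:
    def test_zero_when_prediction_equals_truth(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5, (30, 8))
        labels = ["a"] * 15 + ["b"] * 15
        data = make_dataset(counts, labels, truth=labels)
        per_cluster, mean = centroid_expression_distance(data)
        assert np.allclose(per_cluster.to_numpy(), 0.0)
        assert mean == 0.0

    def test_mislabeled_cell_shifts_centroid_by_hand_amount(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson([5, 1, 3], size=(8, 3)) + np.array(
            [[10, 0, 0]] * 4 + [[0, 10, 0]] * 4
        )
        truth = ["A"] * 4 + ["B"] * 4
        pred = ["x"] * 5 + ["y"] * 3  # one B cell mislabeled into x
        data = make_dataset(counts, pred, truth=truth)
        per_cluster, mean = centroid_expression_distance(data, pred)
        # direct arithmetic on the standardized matrix
        X = lognormalize(np.asarray(counts, dtype=float))
        sd = X.std(axis=0)
        keep = sd > 0
        Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
        expect_x = np.linalg.norm(Z[:5].mean(axis=0) - Z[:4].mean(axis=0))
        expect_y = np.linalg.norm(Z[5:].mean(axis=0) - Z[4:].mean(axis=0))
        assert per_cluster["x"] == pytest.approx(expect_x, abs=1e-10)
        assert per_cluster["y"] == pytest.approx(expect_y, abs=1e-10)
        assert mean == pytest.approx((expect_x + expect_y) / 2, abs=1e-10)

    def test_zero_variance_gene_dropped_with_warning(self):
        # the all-zero gene is constant after normalization too
        counts = np.array([[3, 5, 0], [3, 9, 0], [3, 2, 0], [3, 7, 0]])
        data = make_dataset(counts, ["a", "a", "b", "b"], truth=["A", "A", "B", "B"])
        with pytest.warns(UserWarning, match="zero-variance"):
            centroid_expression_distance(data)

    def test_requires_truth(self):
        data = make_dataset(np.ones((4, 2), dtype=int), ["a", "a", "b", "b"])
        with pytest.raises(ValueError):
            centroid_expression_distance(data)


@pytest.fixture(scope="module")
def toy():
    rng = np.random.default_rng(4)
    counts = rng.poisson(4, (40, 30))
    counts[:20, :5] += 20   # cluster a markers
    counts[20:, 5:10] += 20  # cluster b markers
    labels = ["a"] * 20 + ["b"] * 20
    data = make_dataset(counts, labels, truth=labels)
    tables = list(rank_all_clusters(data).values())
    return data, tables


class TestBaselineDistances:
    def test_identical_feature_vectors_have_zero_distance(self, toy):
        data, tables = toy
        t_dup = [tables[0], tables[0].assign(cluster_id="a2")]
        dup = make_dataset(
            np.vstack([data.counts[:20], data.counts[:20]]),
            ["a"] * 20 + ["a2"] * 20,
        )
        for metric in ("pearson", "spearman", "euclidean"):
            D = baseline_distance_matrix(dup, t_dup, metric=metric, n_markers=5)
            assert D.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_direct_overlap_disjoint_sets_distance_one(self, toy):
        data, tables = toy
        D = baseline_distance_matrix(data, tables, metric="direct_overlap", n_markers=5)
        assert D.loc["a", "b"] == 1.0

    def test_matrices_match_per_pair_bruteforce(self, toy):
        data, tables = toy
        from aocluster.evaluation import _cluster_marker_features

        feats = _cluster_marker_features(data, tables, 10).to_numpy()
        for metric, fn in [
            ("pearson", lambda u, v: 1 - stats.pearsonr(u, v)[0]),
            ("spearman", lambda u, v: 1 - stats.spearmanr(u, v)[0]),
            ("kendall", lambda u, v: 1 - stats.kendalltau(u, v)[0]),
            ("euclidean", lambda u, v: np.linalg.norm(u - v)),
        ]:
            D = baseline_distance_matrix(data, tables, metric=metric, n_markers=10)
            assert D.iloc[0, 1] == pytest.approx(fn(feats[0], feats[1]), abs=1e-10)
            assert D.iloc[0, 1] == D.iloc[1, 0]
            assert D.iloc[0, 0] == 0.0

    def test_pc_features_accepted(self, toy):
        data, tables = toy
        D = baseline_distance_matrix(
            data, tables, metric="pearson", features="principal_components", n_pcs=5
        )
        assert D.shape == (2, 2) and D.iloc[0, 1] > 0

    def test_unknown_metric_rejected(self, toy):
        data, tables = toy
        with pytest.raises(ValueError):
            baseline_distance_matrix(data, tables, metric="cosine")
        with pytest.raises(ValueError):
            baseline_distance_matrix(data, tables, features="tsne")


class TestStouffer:
    def test_examples(self):
        assert stouffer_composite([0, 0, 0]) == 0.0
        assert stouffer_composite([1.7]) == pytest.approx(1.7)
        assert stouffer_composite([1, 1, 1, 1]) == pytest.approx(2.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            stouffer_composite([])


class TestReferenceScoring:
    def make_reference(self):
        return pd.DataFrame(
            {
                "DN1": [10.0, 1.0, 5.0],
                "DN2": [2.0, 8.0, 5.0],
                "DP": [3.0, 2.0, 5.0],
                "CD4": [1.0, 1.0, 5.0],
            },
            index=["Cd44", "Cd25", "Flat1"],
        )

    def test_single_gene_profile_is_its_zscored_row(self):
        ref = self.make_reference().drop(index="Flat1")
        profile = score_marker_set_on_reference(["Cd44"], ref)
        row = ref.loc["Cd44"]
        expected = (row - row.mean()) / row.std(ddof=0)
        pd.testing.assert_series_equal(
            profile, expected.rename("composite_z"), atol=1e-12
        )

    def test_constant_rows_dropped_with_warning(self):
        ref = self.make_reference()
        with pytest.warns(UserWarning, match="constant"):
            profile = score_marker_set_on_reference(["Cd44", "Flat1"], ref)
        row = ref.loc["Cd44"]
        expected = (row - row.mean()) / row.std(ddof=0)
        pd.testing.assert_series_equal(
            profile, expected.rename("composite_z"), atol=1e-12
        )

    def test_hand_computed_stouffer_profile(self):
        ref = self.make_reference().drop(index="Flat1")
        profile = score_marker_set_on_reference(["Cd44", "Cd25"], ref)
        z = ref.sub(ref.mean(axis=1), axis=0).div(ref.std(axis=1, ddof=0), axis=0)
        for pop in ref.columns:
            expected = (z.loc["Cd44", pop] + z.loc["Cd25", pop]) / np.sqrt(2)
            assert profile[pop] == pytest.approx(expected, abs=1e-12)

    def test_no_markers_in_reference_rejected(self):
        with pytest.raises(ValueError):
            score_marker_set_on_reference(["Nope"], self.make_reference())


class TestEvaluateLabels:
    def test_report_fields(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(5, (20, 6))
        labels = ["a"] * 10 + ["b"] * 10
        data = make_dataset(counts, labels, truth=labels)
        report = evaluate_labels(data, seed=1)
        assert report.ari == report.ami == report.fms == report.purity == 1.0
        assert report.centroid_distance == pytest.approx(0.0)
        assert report.to_dict()["seed"] == 1
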