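"""Hierarchical / k-means / k-medoid clustering and silhouette selection."""

import numpy as np
import pytest

from clusterkit import fixtures
from clusterkit.attribute import (
    HierarchicalClustering,
    KMeansClustering,
    KMedoidClustering,
    cut_tree,
    hierarchical,
    select_k,
    silhouette,
)
from clusterkit.model import ClusterAssignment, ClusterkitError
from clusterkit.preprocess import compute_distance

from _oracles import (
    dendrogram_as_member_merges,
    exhaustive_kpartition,
    naive_hierarchical,
)

BLOBS_1D = np.array([[0.0], [0.1], [10.0], [10.1]])


class TestHierarchical:
    def test_single_linkage_chain(self):
        X = np.array([[0.0], [1.0], [10.0]])
        est = HierarchicalClustering(linkage="single", metric="euclidean").fit(X)
        heights = [h for _, _, h in est.dendrogram_.merges]
        assert heights == [1.0, 9.0]

    def test_complete_linkage_final_height(self):
        X = np.array([[0.0], [1.0], [10.0]])
        est = HierarchicalClustering(linkage="complete", metric="euclidean").fit(X)
        assert est.dendrogram_.merges[-1][2] == 10.0

    def test_identical_rows_merge_at_height_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 9.0]])
        est = HierarchicalClustering(linkage="average", metric="euclidean").fit(X)
        assert est.dendrogram_.merges[0][2] == 0.0

    def test_fewer_than_two_items_rejected(self):
        with pytest.raises(ClusterkitError):
            HierarchicalClustering().fit(np.array([[1.0, 2.0]]))

    @pytest.mark.parametrize("linkage", ["single", "complete", "average", "centroid"])
    @pytest.mark.parametrize("metric", ["euclidean", "uncentered", "pearson"])
    def test_agrees_with_naive_oracle(self, linkage, metric):
        rng = np.random.default_rng(17)
        for _ in range(5):
            X = rng.normal(size=(8, 3))
            ids = [f"r{i}" for i in range(8)]
            est = HierarchicalClustering(linkage=linkage, metric=metric).fit(X, ids=ids)
            got = [
                (frozenset(l), frozenset(r))
                for l, r, _ in dendrogram_as_member_merges(est.dendrogram_)
            ]
            want_merges = naive_hierarchical(X, ids, metric, linkage)
            want = [(l, r) for l, r, _ in want_merges]
            assert [set(p) for p in got] == [set(p) for p in want]
            np.testing.assert_allclose(
                [h for _, _, h in dendrogram_as_member_merges(est.dendrogram_)],
                [h for _, _, h in want_merges],
                atol=1e-9,
            )

    @pytest.mark.parametrize("linkage", ["single", "complete", "average"])
    def test_monotone_merge_heights(self, linkage):
        rng = np.random.default_rng(23)
        X = rng.normal(size=(10, 4))
        est = HierarchicalClustering(linkage=linkage, metric="euclidean").fit(X)
        heights = [h for _, _, h in est.dendrogram_.merges]
        assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))

    def test_precomputed_distance_entry_point(self):
        X = np.array([[0.0], [1.0], [10.0]])
        dm = compute_distance(X, "euclidean")
        d = hierarchical(dm, "single")
        assert [h for _, _, h in d.merges] == [1.0, 9.0]


class TestCutTree:
    def _tree(self):
        X = np.array([[0.0], [1.0], [10.0]])
        return HierarchicalClustering(linkage="single", metric="euclidean").fit(
            X, ids=["p0", "p1", "p9"]
        ).dendrogram_

    def test_cut_above_tallest_merge_one_group(self):
        assert cut_tree(self._tree(), height=100.0).sizes() == [3]

    def test_cut_below_all_merges_singletons(self):
        assert cut_tree(self._tree(), height=0.5).sizes() == [1, 1, 1]

    def test_cut_at_five_splits_outlier(self):
        a = cut_tree(self._tree(), height=5.0)
        assert sorted(sorted(c) for c in a.clusters) == [["p0", "p1"], ["p9"]]

    def test_n_groups_selection(self):
        a = cut_tree(self._tree(), n_groups=2)
        assert sorted(sorted(c) for c in a.clusters) == [["p0", "p1"], ["p9"]]

    def test_n_groups_exceeding_leaves_rejected(self):
        with pytest.raises(ClusterkitError):
            cut_tree(self._tree(), n_groups=4)


class TestKMeans:
    def test_two_blobs_match_exhaustive_partition_search(self):
        est = KMeansClustering(k=2).fit(BLOBS_1D)
        want_cost, want_part = exhaustive_kpartition(BLOBS_1D, 2, center="mean")
        got = sorted(frozenset(int(n) for n in c) for c in est.assignment_.clusters)
        assert got == want_part
        assert est.inertia_ == pytest.approx(want_cost)
        # each blob's within-cluster distance to its centroid is 0.1
        assert est.inertia_ == pytest.approx(0.2)

    def test_k_equals_n_gives_zero_inertia(self):
        est = KMeansClustering(k=4).fit(BLOBS_1D)
        assert est.inertia_ == pytest.approx(0.0)
        assert est.assignment_.sizes() == [1, 1, 1, 1]

    def test_same_seed_reproduces_assignment(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 3))
        one = KMeansClustering(k=3, random_state=9).fit(X)
        two = KMeansClustering(k=3, random_state=9).fit(X)
        assert one.assignment_ == two.assignment_

    def test_objective_non_increasing_within_run(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 4))
        est = KMeansClustering(k=3, n_init=1).fit(X)
        path = est.objective_path_
        assert all(a >= b - 1e-9 for a, b in zip(path, path[1:]))

    def test_k_larger_than_rows_rejected(self):
        with pytest.raises(ClusterkitError):
            KMeansClustering(k=5).fit(BLOBS_1D)

    def test_all_missing_rows_reported_unassigned(self):
        X = np.array([[np.nan, np.nan], [0.0, 0.0], [5.0, 5.0]])
        est = KMeansClustering(k=2).fit(X)
        assert est.assignment_.unassigned == {"0"}


class TestKMedoid:
    def test_medoids_are_blob_members(self):
        est = KMedoidClustering(k=2).fit(BLOBS_1D)
        got = sorted(frozenset(int(n) for n in c) for c in est.assignment_.clusters)
        _, want_part = exhaustive_kpartition(BLOBS_1D, 2, center="medoid")
        assert got == want_part
        assert set(est.medoid_ids_) <= {"0", "1", "2", "3"}

    def test_single_row_is_its_own_medoid(self):
        est = KMedoidClustering(k=1).fit(np.array([[3.0, 4.0]]))
        assert est.medoid_ids_ == ["0"]

    def test_medoid_minimizes_within_cluster_distance_sum(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(12, 3))
        est = KMedoidClustering(k=3, random_state=1).fit(X)
        for cluster, medoid in zip(est.assignment_.clusters, est.medoid_ids_):
            idx = sorted(int(n) for n in cluster)
            m = int(medoid)
            msum = sum(np.linalg.norm(X[j] - X[m]) for j in idx)
            for cand in idx:
                csum = sum(np.linalg.norm(X[j] - X[cand]) for j in idx)
                assert msum <= csum + 1e-9


class TestSilhouette:
    def test_two_blob_value_by_hand(self):
        a = ClusterAssignment.from_clusters([{"0", "1"}, {"2", "3"}])
        dm = compute_distance(BLOBS_1D, "euclidean")
        values, mean = silhouette(a, dm)
        # a = 0.1, b = mean distance to the far blob ~= 10.05
        assert values["0"] == pytest.approx((10.05 - 0.1) / 10.05)
        assert mean == pytest.approx(0.99, abs=0.005)

    def test_identical_points_score_zero(self):
        X = np.zeros((4, 2))
        a = ClusterAssignment.from_clusters([{"0", "1"}, {"2", "3"}])
        values, mean = silhouette(a, compute_distance(X, "euclidean"))
        assert mean == 0.0 and set(values.values()) == {0.0}

    def test_singleton_cluster_scores_zero(self):
        a = ClusterAssignment.from_clusters([{"0", "1", "2"}, {"3"}])
        values, _ = silhouette(a, compute_distance(BLOBS_1D, "euclidean"))
        assert values["3"] == 0.0

    def test_single_cluster_partition_rejected(self):
        a = ClusterAssignment.from_clusters([{"0", "1", "2", "3"}])
        with pytest.raises(ClusterkitError):
            silhouette(a, compute_distance(BLOBS_1D, "euclidean"))

    def test_values_bounded(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(15, 3))
        est = KMeansClustering(k=4, random_state=0).fit(X)
        values, mean = silhouette(est.assignment_, compute_distance(X, "euclidean"))
        assert all(-1.0 <= v <= 1.0 for v in values.values())
        assert -1.0 <= mean <= 1.0


class TestSelectK:
    def test_two_blob_data_selects_two(self):
        res = select_k(BLOBS_1D, k_range=(2, 3), seed=0)
        assert res.k == 2
        assert set(res.silhouettes) == {2, 3}

    def test_three_separated_blobs_select_three(self):
        X = np.concatenate(
            [np.zeros((4, 1)), np.full((4, 1), 10.0), np.full((4, 1), 30.0)]
        ) + np.random.default_rng(3).normal(0, 0.1, size=(12, 1))
        res = select_k(X, k_range=(2, 5), seed=0)
        assert res.k == 3

    def test_degenerate_range_rejected(self):
        with pytest.raises(ClusterkitError):
            select_k(BLOBS_1D, k_range=(1, 2))

    def test_kmedoid_variant_runs(self):
        res = select_k(BLOBS_1D, algorithm="kmedoid", k_range=(2, 3), seed=0)
        assert res.k == 2


class TestEmapStyleWorkflow:
    def test_edge_attribute_adjacency_clusters_like_the_network(self):
        # genetic-interaction style: cluster the symmetric adjacency of a
        # two-module network hierarchically and recover the modules
        from clusterkit.preprocess import adjacency_from_edge_attribute
        from clusterkit import WeightedNetwork

        net = WeightedNetwork()
        for grp in (["g1", "g2", "g3"], ["h1", "h2", "h3"]):
            for i in range(3):
                for j in range(i + 1, 3):
                    net.add_edge(grp[i], grp[j], 5.0)
        net.add_edge("g1", "h1", 0.5)
        ids, A = adjacency_from_edge_attribute(net)
        est = HierarchicalClustering(linkage="average", metric="uncentered").fit(A, ids=ids)
        a = cut_tree(est.dendrogram_, n_groups=2)
        assert sorted(sorted(c) for c in a.clusters) == [
            ["g1", "g2", "g3"], ["h1", "h2", "h3"],
        ]
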