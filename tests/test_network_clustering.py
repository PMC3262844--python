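"""Graph clusterers: worked micro-examples, oracle checks, invariants."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from clusterkit import WeightedNetwork, fixtures
from clusterkit.model import ClusterkitError
from clusterkit.network import (
    MCODE,
    SCPS,
    AffinityPropagationClustering,
    GirvanNewman,
    MarkovClustering,
    TransitivityClustering,
    connected_components,
    modularity,
    transclust,
)

from _oracles import (
    exhaustive_exemplars,
    exhaustive_transclust,
    mcl_fixed_point,
    oracle_editing_cost,
    oracle_modularity,
    set_partitions,
)


def clique(net, names, weight=1.0):
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            net.add_edge(names[i], names[j], weight)


def two_triangles_with_bridge():
    net = WeightedNetwork()
    clique(net, ["a", "b", "c"])
    clique(net, ["x", "y", "z"])
    net.add_edge("c", "x", 1.0)
    return net


class TestMCL:
    def test_disjoint_triangles_two_clusters(self):
        net = WeightedNetwork()
        clique(net, ["a", "b", "c"])
        clique(net, ["x", "y", "z"])
        a = MarkovClustering(inflation=2.0).fit(net).assignment_
        assert [sorted(c) for c in a.clusters] == [["a", "b", "c"], ["x", "y", "z"]]

    def test_weakly_bridged_cliques_match_fixed_point_oracle(self):
        net = WeightedNetwork()
        clique(net, list("abcde"))
        clique(net, list("vwxyz"))
        net.add_edge("a", "v", 0.1)
        est = MarkovClustering(inflation=2.0).fit(net)
        ids = net.nodes
        from clusterkit.preprocess import adjacency_from_edge_attribute

        _, A = adjacency_from_edge_attribute(net)
        want = mcl_fixed_point(A, 2.0)
        got = sorted(
            (frozenset(ids.index(n) for n in c) for c in est.assignment_.clusters),
            key=lambda c: (-len(c), min(c)),
        )
        assert got == want
        assert est.assignment_.sizes() == [5, 5]

    def test_single_isolated_node_is_singleton(self):
        a = MarkovClustering(inflation=2.0).fit(WeightedNetwork(nodes=["solo"])).assignment_
        assert a.sizes() == [1]

    def test_negative_weights_rejected(self):
        net = WeightedNetwork(edges=[("a", "b", -1.0)])
        with pytest.raises(ClusterkitError):
            MarkovClustering().fit(net)

    def test_iterates_column_stochastic(self):
        net, _ = fixtures.planted_partition([6, 6], 0.8, 0.1, seed=3)
        est = MarkovClustering(inflation=1.8, keep_iterates=True).fit(net)
        for M in est.iterates_:
            np.testing.assert_allclose(M.sum(axis=0), 1.0, atol=1e-9)

    def test_clusters_never_span_components(self):
        net = WeightedNetwork()
        clique(net, ["a", "b", "c"])
        clique(net, ["p", "q", "r", "s"])
        a = MarkovClustering(inflation=1.5).fit(net).assignment_
        for c in a.clusters:
            assert c <= {"a", "b", "c"} or c <= {"p", "q", "r", "s"}

    def test_partition_covers_all_nodes(self):
        net, _ = fixtures.planted_partition([5, 5, 5], 0.6, 0.05, seed=2)
        a = MarkovClustering().fit(net).assignment_
        assert a.is_partition_of(net.nodes)


class TestAffinityPropagation:
    def test_single_point_is_own_exemplar(self):
        est = AffinityPropagationClustering().fit(np.zeros((1, 1)))
        assert est.exemplars_ == ["0"]

    def test_two_blobs_match_exhaustive_exemplar_search(self):
        S = np.full((6, 6), -10.0)
        for blk in ([0, 1, 2], [3, 4, 5]):
            for i in blk:
                for j in blk:
                    S[i, j] = -0.1
        est = AffinityPropagationClustering().fit(S)
        _, want = exhaustive_exemplars(S, "median")
        got = sorted(frozenset(int(n) for n in c) for c in est.assignment_.clusters)
        assert got == want

    def test_large_preference_makes_all_singletons(self):
        S = np.full((5, 5), -1.0)
        est = AffinityPropagationClustering(preference=10.0).fit(S)
        assert est.assignment_.sizes() == [1] * 5

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        S = rng.normal(size=(8, 8))
        S = (S + S.T) / 2
        one = AffinityPropagationClustering().fit(S).assignment_
        two = AffinityPropagationClustering().fit(S).assignment_
        assert one == two

    def test_agrees_with_sklearn_on_blobs(self):
        from sklearn.cluster import AffinityPropagation as SkAP

        S = np.full((6, 6), -8.0)
        for blk in ([0, 1, 2], [3, 4, 5]):
            for i in blk:
                for j in blk:
                    S[i, j] = -0.2
        ours = AffinityPropagationClustering().fit(S).labels_
        theirs = SkAP(
            affinity="precomputed", damping=0.9, max_iter=2000, random_state=0
        ).fit(S).labels_
        assert adjusted_rand_score(ours, theirs) == 1.0


class TestMCODE:
    def test_k4_with_pendant_haircut(self):
        net = WeightedNetwork()
        clique(net, ["a", "b", "c", "d"])
        net.add_edge("d", "p", 1.0)
        a = MCODE().fit(net).assignment_
        assert [sorted(c) for c in a.clusters] == [["a", "b", "c", "d"]]
        assert a.unassigned == {"p"}

    def test_edgeless_graph_all_unassigned(self):
        a = MCODE().fit(WeightedNetwork(nodes=["a", "b", "c"])).assignment_
        assert a.n_clusters == 0 and a.unassigned == {"a", "b", "c"}

    def test_bridged_k4s_merge_via_expansion(self):
        # all eight vertices share the same core weight (their closed
        # neighborhood's densest core is a K4), so expansion legitimately
        # crosses the bridge and yields one eight-node complex
        net = WeightedNetwork()
        clique(net, ["a1", "b1", "c1", "d1"])
        clique(net, ["a2", "b2", "c2", "d2"])
        net.add_edge("a1", "a2", 1.0)
        est = MCODE(vertex_weight_percentage=0.2).fit(net)
        assert set(est.vertex_weights_.values()) == {3.0}
        assert est.assignment_.sizes() == [8]

    def test_max_depth_one_limits_expansion(self):
        net = WeightedNetwork()
        clique(net, ["a", "b", "c", "d"])
        a = MCODE(max_depth=1).fit(net).assignment_
        assert a.sizes() == [4]

    def test_fluff_can_overlap(self):
        net = WeightedNetwork()
        clique(net, ["a", "b", "c"])
        clique(net, ["c", "d", "e"])
        est = MCODE(haircut=False, fluff=True, fluff_density_cutoff=0.1).fit(net)
        assert est.assignment_.n_clusters >= 1


class TestGirvanNewman:
    def test_two_triangles_modularity_five_fourteenths(self):
        est = GirvanNewman().fit(two_triangles_with_bridge())
        assert [sorted(c) for c in est.assignment_.clusters] == [
            ["a", "b", "c"], ["x", "y", "z"],
        ]
        assert est.modularity_ == pytest.approx(5 / 14)

    def test_two_triangles_is_best_over_all_partitions(self):
        g = two_triangles_with_bridge().to_networkx()
        best = max(
            oracle_modularity(g, part) for part in set_partitions(list(g.nodes))
        )
        assert GirvanNewman().fit(two_triangles_with_bridge()).modularity_ == pytest.approx(best)

    def test_single_clique_one_community_q_zero(self):
        net = WeightedNetwork()
        clique(net, ["a", "b", "c", "d"])
        est = GirvanNewman().fit(net)
        assert est.assignment_.sizes() == [4]
        assert est.modularity_ == 0.0

    def test_communities_never_span_components(self):
        net = WeightedNetwork()
        clique(net, ["a", "b", "c"])
        clique(net, ["x", "y"])
        a = GirvanNewman().fit(net).assignment_
        for c in a.clusters:
            assert c <= {"a", "b", "c"} or c <= {"x", "y"}

    def test_edgeless_graph_singletons(self):
        est = GirvanNewman().fit(WeightedNetwork(nodes=["a", "b"]))
        assert est.assignment_.sizes() == [1, 1]
        assert est.modularity_ == 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_returned_q_is_max_over_levels_and_matches_oracle(self, seed):
        net, _ = fixtures.planted_partition([4, 4], 0.9, 0.2, seed=seed)
        est = GirvanNewman().fit(net)
        g = net.to_networkx()
        oracle_qs = [oracle_modularity(g, lvl) for lvl in est.levels_]
        assert est.modularity_ == pytest.approx(max(oracle_qs))
        np.testing.assert_allclose(est.level_modularities_, oracle_qs, atol=1e-12)


class TestConnectedComponents:
    def test_isolated_nodes_are_singletons(self):
        a = connected_components(WeightedNetwork(nodes=["a", "b", "c"]))
        assert a.sizes() == [1, 1, 1]

    def test_path_is_one_cluster(self):
        net = WeightedNetwork(edges=[("a", "b"), ("b", "c"), ("c", "d")])
        assert connected_components(net).sizes() == [4]

    def test_invariant_under_relabeling(self):
        net = WeightedNetwork(edges=[("a", "b"), ("c", "d")])
        renamed = WeightedNetwork(edges=[("d", "c"), ("b", "a")])
        assert connected_components(net) == connected_components(renamed)


class TestTransitivityClustering:
    def test_two_cliques_cost_zero(self):
        S = np.full((6, 6), -10.0)
        for blk in ([0, 1, 2], [3, 4, 5]):
            for i in blk:
                for j in blk:
                    if i != j:
                        S[i, j] = 10.0
        np.fill_diagonal(S, 0.0)
        a, cost = transclust(S, threshold=0.0)
        assert cost == 0.0
        assert sorted(sorted(c) for c in a.clusters) == [["0", "1", "2"], ["3", "4", "5"]]

    def test_triple_forced_merge_cost_one(self):
        S = np.array([[0, 2, -1], [2, 0, 2], [-1, 2, 0]], float)
        a, cost = transclust(S, threshold=0.0)
        assert cost == 1.0 and a.sizes() == [3]

    def test_single_element(self):
        a, cost = transclust(np.zeros((1, 1)))
        assert cost == 0.0 and a.sizes() == [1]

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ClusterkitError):
            transclust(np.array([[0.0, 1.0], [2.0, 0.0]]))

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_mode_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        S = rng.normal(size=(n, n))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 0.0)
        est = TransitivityClustering(threshold=0.1, exact_limit=8).fit(S)
        want_cost, _ = exhaustive_transclust(S, 0.1)
        assert est.exact_
        assert est.cost_ == pytest.approx(want_cost)

    @pytest.mark.parametrize("seed", range(5))
    def test_heuristic_cost_at_least_exact(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 7
        S = rng.normal(size=(n, n))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 0.0)
        heur = TransitivityClustering(threshold=0.0, exact_limit=2).fit(S)
        exact_cost, _ = exhaustive_transclust(S, 0.0)
        assert not heur.exact_
        assert heur.cost_ >= exact_cost - 1e-9
        # and the reported cost matches an independent recomputation
        part = [set(int(i) for i in c) for c in heur.assignment_.clusters]
        assert heur.cost_ == pytest.approx(oracle_editing_cost(S, 0.0, part))


class TestSCPS:
    def _blocks(self, sizes, s_in=10.0, jitter=0.0, seed=0):
        labels = {}
        k = 0
        for b, sz in enumerate(sizes):
            for _ in range(sz):
                labels[f"n{k:02d}"] = b
                k += 1
        ids, S = fixtures.similarity_from_labels(labels, s_in, 0.0, jitter, seed)
        np.fill_diagonal(S, 0.0)
        return ids, S

    def test_exact_two_block_diagonal(self):
        _, S = self._blocks([3, 3])
        est = SCPS(n_clusters="auto").fit(S)
        assert est.k_ == 2
        assert sorted(sorted(c) for c in est.assignment_.clusters) == [
            ["0", "1", "2"], ["3", "4", "5"],
        ]

    def test_all_equal_similarity_one_cluster(self):
        S = np.full((6, 6), 3.0)
        np.fill_diagonal(S, 0.0)
        est = SCPS(n_clusters="auto").fit(S)
        assert est.assignment_.sizes() == [6]

    def test_auto_recovers_three_blocks_with_jitter(self):
        _, S = self._blocks([4, 4, 4], jitter=0.5, seed=1)
        S = np.abs(S)
        est = SCPS(n_clusters="auto").fit(S)
        assert est.k_ == 3

    def test_permutation_equivariance(self):
        _, S = self._blocks([3, 4])
        rng = np.random.default_rng(2)
        perm = rng.permutation(7)
        a1 = SCPS(n_clusters=2).fit(S).assignment_
        a2 = SCPS(n_clusters=2).fit(S[np.ix_(perm, perm)]).assignment_
        mapped = [
            frozenset(str(int(np.flatnonzero(perm == int(n))[0])).zfill(1) for n in c)
            for c in a2.clusters
        ]
        assert sorted(sorted(c) for c in a1.clusters) == sorted(sorted(c) for c in mapped)

    def test_zero_degree_nodes_become_singletons(self):
        S = np.zeros((4, 4))
        S[0, 1] = S[1, 0] = 5.0
        est = SCPS(n_clusters="auto").fit(S)
        assert est.assignment_.sizes() == [2, 1, 1]

    def test_deterministic_given_seed(self):
        _, S = self._blocks([4, 4], jitter=1.0, seed=5)
        S = np.abs(S)
        one = SCPS(n_clusters=2, random_state=7).fit(S).assignment_
        two = SCPS(n_clusters=2, random_state=7).fit(S).assignment_
        assert one == two
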