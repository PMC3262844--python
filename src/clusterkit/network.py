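"""Graph-clustering algorithms for weighted similarity networks.

Seven clusterers share a scikit-learn-shaped interface: ``fit`` accepts
either a :class:`~clusterkit.model.WeightedNetwork` or a square symmetric
similarity/adjacency matrix, and exposes ``labels_``, ``assignment_``
(size-ordered :class:`~clusterkit.model.ClusterAssignment`) and
``n_clusters_``.  All tie-breaking is deterministic: lexicographic for
string node ids, input order for plain arrays.

* :class:`MarkovClustering` -- flow simulation by alternating expansion
  (matrix squaring) and inflation (entrywise power), the classic method
  for carving protein-protein interaction networks into complexes.
* :class:`AffinityPropagationClustering` -- exemplar-based message
  passing (responsibilities/availabilities with damping).
* :class:`MCODE` -- local density search: k-core-based vertex weighting,
  seeded greedy expansion, optional haircut/fluff post-processing; the
  only method here that may leave nodes unassigned or overlap clusters.
* :class:`GirvanNewman` -- divisive community detection by iterated
  removal of the highest-betweenness edge, keeping the level of maximum
  modularity Q.
* :class:`ConnectedComponentsClustering` -- one cluster per component.
* :class:`TransitivityClustering` -- weighted cluster editing: find the
  partition minimizing the cost of edge edits relative to a similarity
  threshold (exact by enumeration on tiny instances, greedy single-node
  moves otherwise).
* :class:`SCPS` -- spectral clustering of sequence-similarity networks
  with eigengap selection of the cluster count.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .model import ClusterAssignment, ClusterkitError, WeightedNetwork
from .preprocess import adjacency_from_edge_attribute

logger = logging.getLogger("clusterkit")

__all__ = [
    "MarkovClustering",
    "AffinityPropagationClustering",
    "MCODE",
    "GirvanNewman",
    "ConnectedComponentsClustering",
    "TransitivityClustering",
    "SCPS",
    "mcl",
    "affinity_propagation",
    "mcode",
    "girvan_newman",
    "connected_components",
    "transclust",
    "scps",
    "modularity",
    "cluster_editing_cost",
]


def _as_similarity(X) -> tuple[list[str], np.ndarray]:
    """Coerce input to (ids, square symmetric matrix)."""
    if isinstance(X, WeightedNetwork):
        return adjacency_from_edge_attribute(X)
    A = np.asarray(X, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ClusterkitError("expected a square similarity matrix or a WeightedNetwork")
    if not np.allclose(A, A.T, atol=1e-9, equal_nan=True):
        raise ClusterkitError("similarity matrix must be symmetric")
    # index-order ids: deterministic tie-breaks follow input order
    width = len(str(A.shape[0] - 1))
    return [str(i).zfill(width) for i in range(A.shape[0])], A


class _NetworkClusterer(BaseEstimator, ClusterMixin):
    """Common fitted-attribute bookkeeping for the network clusterers."""

    def _finalize(self, ids: list[str], assignment: ClusterAssignment):
        self.ids_ = ids
        self.assignment_ = assignment
        labels = assignment.labels
        self.labels_ = np.array([labels.get(n, -1) for n in ids])
        self.n_clusters_ = assignment.n_clusters
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


# ---------------------------------------------------------------------------
# MCL
# ---------------------------------------------------------------------------


class MarkovClustering(_NetworkClusterer):
    """Markov clustering by alternating expansion and inflation.

    The adjacency matrix (non-negative similarities) plus self-loops is
    column-normalized to a stochastic flow matrix; each round squares it
    (expansion) then raises entries to the ``inflation`` power and
    renormalizes (inflation), pruning entries below
    ``pruning_threshold``.  Iteration stops when the residual (max over
    columns of the L1 change) drops to ``max_residual`` or after
    ``max_iterations`` rounds.  Clusters are read from the attractor
    structure of the limit matrix: each attractor row's support is a
    cluster, attractors with overlapping supports merge, and any node
    supported by several attractor groups goes to the attractor with the
    largest limit value (ties to the lexicographically smallest id).

    ``inflation`` is the granularity knob: larger values give more,
    smaller clusters.  ``loop_policy`` sets the self-loop weight:
    ``"max_incident"`` (the node's largest incident edge weight, 1 for
    isolated nodes) or ``"unit"``.
    """

    def __init__(
        self,
        inflation: float = 1.8,
        pruning_threshold: float = 0.0,
        max_residual: float = 1e-6,
        max_iterations: int = 16,
        loop_policy: str = "max_incident",
        keep_iterates: bool = False,
    ):
        self.inflation = inflation
        self.pruning_threshold = pruning_threshold
        self.max_residual = max_residual
        self.max_iterations = max_iterations
        self.loop_policy = loop_policy
        self.keep_iterates = keep_iterates

    def fit(self, X, y=None):
        if self.inflation <= 1:
            raise ClusterkitError("inflation must be > 1")
        ids, A = _as_similarity(X)
        n = len(ids)
        if n == 0:
            return self._finalize(ids, ClusterAssignment.from_clusters([]))
        if (A < 0).any():
            raise ClusterkitError("MCL requires non-negative weights")
        A = A.copy()
        np.fill_diagonal(A, 0.0)
        if self.loop_policy == "max_incident":
            loops = A.max(axis=0)
            loops[loops == 0] = 1.0
        elif self.loop_policy == "unit":
            loops = np.ones(n)
        else:
            raise ClusterkitError(f"unknown loop_policy {self.loop_policy!r}")
        M = A + np.diag(loops)
        M = self._normalize(M)
        self.iterates_ = [M.copy()] if self.keep_iterates else None

        it, residual = -1, 0.0
        for it in range(int(self.max_iterations)):
            prev = M
            M = M @ M
            M = np.power(M, float(self.inflation))
            M = self._normalize(M)
            if self.pruning_threshold > 0:
                M[M < self.pruning_threshold] = 0.0
                M = self._normalize(M)
            if self.keep_iterates:
                self.iterates_.append(M.copy())
            residual = np.abs(M - prev).sum(axis=0).max()
            if residual <= self.max_residual:
                break
        self.n_iter_ = it + 1
        self.residual_ = float(residual)
        self.limit_matrix_ = M
        return self._finalize(ids, self._read_clusters(ids, M))

    @staticmethod
    def _normalize(M: np.ndarray) -> np.ndarray:
        sums = M.sum(axis=0)
        dead = sums == 0
        if dead.any():
            # a pruned-to-zero column becomes an absorbing self-state
            M = M.copy()
            for j in np.flatnonzero(dead):
                M[j, j] = 1.0
            sums = M.sum(axis=0)
        return M / sums

    def _read_clusters(self, ids: list[str], M: np.ndarray) -> ClusterAssignment:
        n = len(ids)
        eps = max(self.pruning_threshold, 1e-8)
        attractors = [i for i in range(n) if M[i, i] > eps]
        if not attractors:
            # cyclic limit behaviour: fall back to the strongest row per column
            attractors = sorted(set(int(np.argmax(M[:, j])) for j in range(n)))

        # union attractors whose supports overlap
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        attr_set = set(attractors)
        for j in range(n):
            present = [i for i in attractors if M[i, j] > eps]
            for a, b in zip(present, present[1:]):
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb

        clusters: dict[int, set] = {}
        for j in range(n):
            candidates = [i for i in attractors if M[i, j] > eps]
            if not candidates:
                if j in attr_set:
                    candidates = [j]
                else:
                    clusters.setdefault(-j - 1, set()).add(ids[j])  # singleton
                    continue
            best = max(candidates, key=lambda i: (M[i, j], ids[i]))
            # ties by lexicographically smallest attractor id
            top = [i for i in candidates if M[i, j] == M[best, j]]
            best = min(top, key=lambda i: ids[i])
            clusters.setdefault(find(best), set()).add(ids[j])
        return ClusterAssignment.from_clusters(clusters.values())


def mcl(
    network,
    inflation: float = 1.8,
    pruning_threshold: float = 0.0,
    max_residual: float = 1e-6,
    max_iterations: int = 16,
    loop_policy: str = "max_incident",
) -> ClusterAssignment:
    """Markov clustering of a network; see :class:`MarkovClustering`."""
    return MarkovClustering(
        inflation=inflation,
        pruning_threshold=pruning_threshold,
        max_residual=max_residual,
        max_iterations=max_iterations,
        loop_policy=loop_policy,
    ).fit(network).assignment_


# ---------------------------------------------------------------------------
# Affinity propagation
# ---------------------------------------------------------------------------


class AffinityPropagationClustering(_NetworkClusterer):
    """Exemplar-based clustering by message passing.

    Standard responsibility/availability updates with damping on a
    similarity matrix whose diagonal is overwritten by the ``preference``
    (``"median"`` = median off-diagonal similarity).  Iteration stops
    when the exemplar set is stable for ``convergence_window`` rounds.
    Every node joins the exemplar of maximal similarity; exemplars join
    themselves.
    """

    def __init__(
        self,
        preference="median",
        damping: float = 0.9,
        max_iterations: int = 500,
        convergence_window: int = 20,
    ):
        self.preference = preference
        self.damping = damping
        self.max_iterations = max_iterations
        self.convergence_window = convergence_window

    def fit(self, X, y=None):
        if not (0.5 <= self.damping < 1):
            raise ClusterkitError("damping must lie in [0.5, 1)")
        ids, S = _as_similarity(X)
        n = len(ids)
        if n == 0:
            return self._finalize(ids, ClusterAssignment.from_clusters([]))
        if n == 1:
            self.exemplars_ = [ids[0]]
            return self._finalize(ids, ClusterAssignment.from_clusters([{ids[0]}]))
        S = S.astype(float).copy()
        if self.preference == "median":
            off = S[~np.eye(n, dtype=bool)]
            pref = float(np.median(off))
        else:
            pref = float(self.preference)
        np.fill_diagonal(S, pref)

        # break exact symmetric ties (which make message passing oscillate)
        # with a deterministic, vanishingly small perturbation
        rng = np.random.default_rng(0)
        S = S + (np.finfo(float).eps * np.abs(S) + np.finfo(float).tiny * 100) * rng.standard_normal((n, n))

        R = np.zeros((n, n))
        A = np.zeros((n, n))
        lam = float(self.damping)
        stable = 0
        exemplars: tuple = ()
        for _ in range(int(self.max_iterations)):
            # responsibilities
            AS = A + S
            idx = np.argmax(AS, axis=1)
            first = AS[np.arange(n), idx]
            AS[np.arange(n), idx] = -np.inf
            second = AS.max(axis=1)
            Rnew = S - first[:, None]
            Rnew[np.arange(n), idx] = S[np.arange(n), idx] - second
            R = lam * R + (1 - lam) * Rnew
            # availabilities
            Rp = np.maximum(R, 0)
            np.fill_diagonal(Rp, R.diagonal())
            Anew = Rp.sum(axis=0)[None, :] - Rp
            dA = Anew.diagonal().copy()
            Anew = np.minimum(Anew, 0)
            np.fill_diagonal(Anew, dA)
            A = lam * A + (1 - lam) * Anew

            new_exemplars = tuple(np.flatnonzero(np.diagonal(A + R) > 0))
            if new_exemplars == exemplars and len(new_exemplars):
                stable += 1
                if stable >= self.convergence_window:
                    break
            else:
                stable = 0
            exemplars = new_exemplars

        if not exemplars:
            exemplars = (int(np.argmax(np.diagonal(A + R))),)
        ex = list(exemplars)
        assign = {}
        for i in range(n):
            if i in ex:
                assign[i] = i
            else:
                best = max(ex, key=lambda k: (S[i, k], -ex.index(k)))
                top = [k for k in ex if S[i, k] == S[i, best]]
                assign[i] = min(top, key=lambda k: ids[k])
        clusters: dict[int, set] = {}
        for i, e in assign.items():
            clusters.setdefault(e, set()).add(ids[i])
        self.exemplars_ = sorted(ids[e] for e in ex)
        return self._finalize(ids, ClusterAssignment.from_clusters(clusters.values()))


def affinity_propagation(
    similarity,
    preference="median",
    damping: float = 0.9,
    max_iterations: int = 500,
    convergence_window: int = 20,
):
    """Cluster a similarity matrix; returns (assignment, exemplar ids)."""
    est = AffinityPropagationClustering(
        preference=preference,
        damping=damping,
        max_iterations=max_iterations,
        convergence_window=convergence_window,
    ).fit(similarity)
    return est.assignment_, est.exemplars_


# ---------------------------------------------------------------------------
# MCODE
# ---------------------------------------------------------------------------


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def _vertex_weight(g: nx.Graph, v) -> float:
    """Core-clustering coefficient x highest core number of N[v]."""
    nbhd = g.subgraph(list(g.neighbors(v)) + [v])
    cores = nx.core_number(nbhd)
    k = max(cores.values())
    if k == 0:
        return 0.0
    kcore = nbhd.subgraph([u for u, c in cores.items() if c >= k])
    return _density(kcore) * k


class MCODE(_NetworkClusterer):
    """Molecular-complex detection by local density search.

    Stage 1 weights each vertex by the density of the highest k-core of
    its closed neighborhood times that core's k.  Stage 2 grows a complex
    from each highest-weight unseen vertex, breadth-first to
    ``max_depth``, admitting neighbors whose weight is at least
    ``(1 - vertex_weight_percentage)`` of the seed weight.  Stage 3
    optionally removes singly-connected vertices (``haircut``) and adds
    back dense neighbors (``fluff``, which may make complexes overlap);
    complexes whose densest core falls below ``k_core`` are dropped.
    Edge weights are ignored (logged).  Nodes in no complex are reported
    as unassigned.
    """

    def __init__(
        self,
        vertex_weight_percentage: float = 0.2,
        haircut: bool = True,
        fluff: bool = False,
        fluff_density_cutoff: float = 0.5,
        k_core: int = 2,
        max_depth: int = 100,
    ):
        self.vertex_weight_percentage = vertex_weight_percentage
        self.haircut = haircut
        self.fluff = fluff
        self.fluff_density_cutoff = fluff_density_cutoff
        self.k_core = k_core
        self.max_depth = max_depth

    def fit(self, X, y=None):
        if not (0 < self.vertex_weight_percentage <= 1):
            raise ClusterkitError("vertex_weight_percentage must lie in (0, 1]")
        if not (0 <= self.fluff_density_cutoff <= 1):
            raise ClusterkitError("fluff_density_cutoff must lie in [0, 1]")
        ids, A = _as_similarity(X)
        if isinstance(X, WeightedNetwork) and any(w != 1.0 for _, _, w in X.edges()):
            logger.info("MCODE ignores edge weights; treating the network as unweighted")
        g = nx.Graph()
        g.add_nodes_from(ids)
        n = len(ids)
        for i in range(n):
            for j in range(i + 1, n):
                if A[i, j] != 0:
                    g.add_edge(ids[i], ids[j])

        if g.number_of_nodes() == 0:
            return self._finalize(ids, ClusterAssignment.from_clusters([]))

        weight = {v: _vertex_weight(g, v) for v in g.nodes}
        self.vertex_weights_ = dict(weight)

        seen: set = set()
        complexes: list[set] = []
        for seed in sorted(g.nodes, key=lambda v: (-weight[v], v)):
            if seed in seen:
                continue
            threshold = (1 - self.vertex_weight_percentage) * weight[seed]
            complex_nodes = {seed}
            frontier = [seed]
            depth = 0
            while frontier and depth < self.max_depth:
                nxt = []
                for u in frontier:
                    for w in sorted(g.neighbors(u)):
                        if w in seen or w in complex_nodes:
                            continue
                        if weight[w] >= threshold:
                            complex_nodes.add(w)
                            nxt.append(w)
                frontier = nxt
                depth += 1
            seen |= complex_nodes
            complexes.append(complex_nodes)

        # stage 3 post-processing
        final: list[set] = []
        for comp in complexes:
            nodes = set(comp)
            if self.haircut:
                changed = True
                while changed and len(nodes) > 1:
                    sub = g.subgraph(nodes)
                    drop = {v for v in nodes if sub.degree(v) < 2}
                    changed = bool(drop)
                    nodes -= drop
            if self.fluff:
                extra = set()
                for v in set(nodes):
                    for u in g.neighbors(v):
                        if u in nodes or u in extra:
                            continue
                        nbhd = g.subgraph(list(g.neighbors(u)) + [u])
                        if _density(nbhd) > self.fluff_density_cutoff:
                            extra.add(u)
                nodes |= extra
            if not nodes:
                continue
            sub = g.subgraph(nodes)
            cores = nx.core_number(sub) if sub.number_of_nodes() else {}
            if not cores or max(cores.values()) < self.k_core:
                continue
            final.append(nodes)

        scored = sorted(
            final, key=lambda c: (-_density(g.subgraph(c)) * len(c), min(c))
        )
        self.scores_ = [
            _density(g.subgraph(c)) * len(c) for c in scored
        ]
        assigned = set().union(*scored) if scored else set()
        unassigned = set(ids) - assigned
        return self._finalize(
            ids, ClusterAssignment.from_clusters(scored, unassigned=unassigned)
        )


def mcode(network, **params) -> ClusterAssignment:
    """MCODE complex detection; see :class:`MCODE` for parameters."""
    return MCODE(**params).fit(network).assignment_


# ---------------------------------------------------------------------------
# Girvan-Newman
# ---------------------------------------------------------------------------


def modularity(g: nx.Graph, clusters) -> float:
    """Newman-Girvan modularity Q of a partition on an unweighted graph.

    Q = sum_c (e_c / m - (d_c / 2m)^2) with e_c the intra-community edge
    count, d_c the total degree of community c, m the edge count.  Q of
    an edgeless graph is defined as 0.
    """
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    q = 0.0
    for c in clusters:
        cset = set(c)
        e_c = g.subgraph(cset).number_of_edges()
        d_c = sum(g.degree(v) for v in cset)
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


class GirvanNewman(_NetworkClusterer):
    """Divisive community detection by edge-betweenness removal.

    Repeatedly removes the edge of highest betweenness (recomputed after
    each removal, ties to the lexicographically smallest edge), records
    the component partition at every distinct component count, and
    returns the recorded partition of maximal modularity Q measured on
    the original graph.
    """

    def fit(self, X, y=None):
        ids, A = _as_similarity(X)
        g0 = nx.Graph()
        g0.add_nodes_from(ids)
        n = len(ids)
        for i in range(n):
            for j in range(i + 1, n):
                if A[i, j] != 0:
                    g0.add_edge(ids[i], ids[j])
        if n == 0:
            return self._finalize(ids, ClusterAssignment.from_clusters([]))

        levels = []
        g = g0.copy()
        comps = [sorted(c) for c in nx.connected_components(g)]
        levels.append(comps)
        n_comp = len(comps)
        while g.number_of_edges() > 0:
            bet = nx.edge_betweenness_centrality(g)
            best_val = max(bet.values())
            candidates = [tuple(sorted(e)) for e, b in bet.items() if b >= best_val - 1e-12]
            u, v = min(candidates)
            g.remove_edge(u, v)
            comps = [sorted(c) for c in nx.connected_components(g)]
            if len(comps) != n_comp:
                levels.append(comps)
                n_comp = len(comps)

        qs = [modularity(g0, lvl) for lvl in levels]
        best_i = int(np.argmax(qs))
        self.modularity_ = float(qs[best_i])
        self.levels_ = levels
        self.level_modularities_ = [float(q) for q in qs]
        return self._finalize(
            ids, ClusterAssignment.from_clusters(levels[best_i])
        )


def girvan_newman(network) -> ClusterAssignment:
    """Girvan-Newman community detection; see :class:`GirvanNewman`."""
    return GirvanNewman().fit(network).assignment_


# ---------------------------------------------------------------------------
# connected components
# ---------------------------------------------------------------------------


class ConnectedComponentsClustering(_NetworkClusterer):
    """One cluster per connected component."""

    def fit(self, X, y=None):
        ids, A = _as_similarity(X)
        g = nx.Graph()
        g.add_nodes_from(ids)
        n = len(ids)
        for i in range(n):
            for j in range(i + 1, n):
                if A[i, j] != 0:
                    g.add_edge(ids[i], ids[j])
        comps = [set(c) for c in nx.connected_components(g)]
        return self._finalize(ids, ClusterAssignment.from_clusters(comps))


def connected_components(network) -> ClusterAssignment:
    return ConnectedComponentsClustering().fit(network).assignment_


# ---------------------------------------------------------------------------
# transitivity clustering (weighted cluster editing)
# ---------------------------------------------------------------------------


def cluster_editing_cost(S: np.ndarray, threshold: float, labels: np.ndarray) -> float:
    """Cost of a partition under the weighted cluster-editing objective.

    Every pair whose co-membership disagrees with the sign of
    ``s(i,j) - threshold`` pays ``|s(i,j) - threshold|``: similar pairs
    split apart and dissimilar pairs kept together are both edits.
    """
    n = S.shape[0]
    cost = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            margin = S[i, j] - threshold
            together = labels[i] == labels[j]
            if (margin > 0 and not together) or (margin < 0 and together):
                cost += abs(margin)
    return cost


def _exhaustive_partitions(n: int):
    """Yield all set partitions of range(n) as label arrays."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, n_used: int):
        if i == n:
            yield labels.copy()
            return
        for lab in range(n_used + 1):
            labels[i] = lab
            yield from rec(i + 1, max(n_used, lab + 1))

    yield from rec(0, 0)


class TransitivityClustering(_NetworkClusterer):
    """Weighted cluster editing against a similarity threshold.

    Pairs above ``threshold`` want to share a cluster, pairs below want
    separation; the optimal partition minimizes the total absolute margin
    of violated pairs.  Instances with at most ``exact_limit`` elements
    are solved exactly by set-partition enumeration; larger instances use
    a documented local-search heuristic: starting from each of two
    initializations (single-linkage components above the threshold, and
    all singletons), apply best-improvement moves -- relocating a single
    node to any cluster or a fresh singleton, or merging two clusters --
    until no move lowers the cost, and keep the cheaper of the two
    results.  All tie-breaking is deterministic (lexicographic node
    order, lowest cluster label).
    """

    def __init__(self, threshold: float = 0.0, exact_limit: int = 8):
        self.threshold = threshold
        self.exact_limit = exact_limit

    def fit(self, X, y=None):
        if self.exact_limit > 10:
            raise ClusterkitError("exact_limit must be <= 10")
        ids, S = _as_similarity(X)
        n = len(ids)
        if n == 0:
            return self._finalize(ids, ClusterAssignment.from_clusters([]))
        t = float(self.threshold)
        if n <= self.exact_limit:
            best_cost, best_labels = np.inf, None
            for labels in _exhaustive_partitions(n):
                c = cluster_editing_cost(S, t, labels)
                if c < best_cost - 1e-12:
                    best_cost, best_labels = c, labels
            labels = best_labels
            self.exact_ = True
        else:
            labels = self._greedy(S, t, ids)
            best_cost = cluster_editing_cost(S, t, labels)
            self.exact_ = False
        self.cost_ = float(best_cost)
        clusters: dict[int, set] = {}
        for i, lab in enumerate(labels):
            clusters.setdefault(int(lab), set()).add(ids[i])
        return self._finalize(ids, ClusterAssignment.from_clusters(clusters.values()))

    @staticmethod
    def _init_components(S: np.ndarray, t: float) -> np.ndarray:
        n = S.shape[0]
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i in range(n):
            for j in range(i + 1, n):
                if S[i, j] > t:
                    g.add_edge(i, j)
        labels = np.zeros(n, dtype=int)
        for lab, comp in enumerate(nx.connected_components(g)):
            for i in comp:
                labels[i] = lab
        return labels

    def _greedy(self, S: np.ndarray, t: float, ids: list[str]) -> np.ndarray:
        starts = [self._init_components(S, t), np.arange(S.shape[0])]
        results = [self._local_search(S, t, ids, init.copy()) for init in starts]
        costs = [cluster_editing_cost(S, t, lab) for lab in results]
        return results[int(np.argmin(costs))]

    @staticmethod
    def _local_search(S: np.ndarray, t: float, ids: list[str], labels: np.ndarray) -> np.ndarray:
        n = S.shape[0]
        margins = S - t
        np.fill_diagonal(margins, 0.0)
        order = sorted(range(n), key=lambda i: ids[i])
        while True:
            best_gain, best_move = 1e-12, None
            # single-node relocations (including to a fresh singleton);
            # f(C) = sum over j in C of (pen_together - pen_apart), so the
            # gain of moving i from its cluster to C is f(current) - f(C)
            present = sorted(set(labels))
            fresh = max(present) + 1
            for i in order:
                current = labels[i]
                # per pair, pen_together - pen_apart = -margin, so
                # f(C) = -sum of margins from i into C
                contrib = {
                    lab: -float(margins[i][labels == lab].sum()) for lab in present
                }
                remove_gain = contrib[current]  # i itself excluded via zero diagonal
                for lab in present + [fresh]:
                    if lab == current:
                        continue
                    add_cost = contrib.get(lab, 0.0)
                    gain = remove_gain - add_cost
                    if gain > best_gain + 1e-12:
                        best_gain, best_move = gain, ("move", i, lab)
            # cluster merges: gain = total margin between the two clusters
            for ai in range(len(present)):
                for bi in range(ai + 1, len(present)):
                    a, b = present[ai], present[bi]
                    gain = float(margins[np.ix_(labels == a, labels == b)].sum())
                    if gain > best_gain + 1e-12:
                        best_gain, best_move = gain, ("merge", a, b)
            if best_move is None:
                return labels
            kind, x, y = best_move
            if kind == "move":
                labels[x] = y
            else:
                labels[labels == y] = x


def transclust(similarity, threshold: float = 0.0, exact_limit: int = 8):
    """Transitivity clustering; returns (assignment, editing cost)."""
    est = TransitivityClustering(threshold=threshold, exact_limit=exact_limit).fit(similarity)
    return est.assignment_, est.cost_


# ---------------------------------------------------------------------------
# SCPS (spectral clustering of protein sequences)
# ---------------------------------------------------------------------------


class SCPS(_NetworkClusterer):
    """Spectral clustering of a non-negative similarity network.

    Forms the degree-normalized matrix ``D^{-1/2} S D^{-1/2}``, picks the
    cluster count at the largest gap of the sorted eigenvalue sequence
    (excluding the trivial leading eigenvalue) when ``n_clusters`` is
    ``"auto"``, embeds nodes in the top-k eigenvector space with row
    normalization, and partitions the embedding with k-means restarts.
    Zero-degree nodes become singletons before embedding.
    """

    def __init__(self, n_clusters="auto", kmeans_restarts: int = 10, random_state: int = 42):
        self.n_clusters = n_clusters
        self.kmeans_restarts = kmeans_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        ids, S = _as_similarity(X)
        n = len(ids)
        if n == 0:
            return self._finalize(ids, ClusterAssignment.from_clusters([]))
        if (S < 0).any():
            raise ClusterkitError("SCPS requires non-negative similarities")
        S = S.copy()
        np.fill_diagonal(S, 0.0)
        deg = S.sum(axis=1)
        isolated = np.flatnonzero(deg == 0)
        keep = np.flatnonzero(deg > 0)
        singletons = [{ids[i]} for i in isolated]
        if keep.size == 0:
            return self._finalize(ids, ClusterAssignment.from_clusters(singletons))
        Sk = S[np.ix_(keep, keep)]
        dk = Sk.sum(axis=1)
        Dk = 1.0 / np.sqrt(dk)
        L = Dk[:, None] * Sk * Dk[None, :]
        evals, evecs = np.linalg.eigh(L)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        m = keep.size

        if self.n_clusters == "auto":
            k = self._eigengap_k(evals)
        else:
            k = int(self.n_clusters)
            if k < 1:
                raise ClusterkitError("n_clusters must be >= 1")
        k = min(k, m)
        self.eigenvalues_ = evals
        self.k_ = k

        if k == 1 or m == 1:
            clusters = [set(ids[i] for i in keep)] + singletons
            return self._finalize(ids, ClusterAssignment.from_clusters(clusters))

        emb = evecs[:, :k]
        norms = np.linalg.norm(emb, axis=1)
        norms[norms == 0] = 1.0
        emb = emb / norms[:, None]

        from .attribute import KMeansClustering

        km = KMeansClustering(
            k=k,
            metric="euclidean",
            n_init=int(self.kmeans_restarts),
            random_state=int(self.random_state),
        ).fit(emb, ids=[ids[i] for i in keep])
        clusters = [set(c) for c in km.assignment_.clusters] + singletons
        return self._finalize(ids, ClusterAssignment.from_clusters(clusters))

    @staticmethod
    def _eigengap_k(evals: np.ndarray, tol: float = 1e-8) -> int:
        """k = 1 + position of the largest gap after the leading eigenvalue."""
        if evals.size < 3:
            return 1
        gaps = evals[1:-1] - evals[2:]  # gaps lambda_2-lambda_3, ...
        if gaps.size == 0 or gaps.max() <= tol:
            return 1
        return int(np.argmax(gaps)) + 2


def scps(similarity, n_clusters="auto", kmeans_restarts: int = 10, seed: int = 42) -> ClusterAssignment:
    """Spectral clustering; see :class:`SCPS`."""
    return SCPS(
        n_clusters=n_clusters, kmeans_restarts=kmeans_restarts, random_state=seed
    ).fit(similarity).assignment_
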