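"""Independent brute-force oracles used by the test suite.

Every function here recomputes a quantity from first principles (direct
definitions, exhaustive enumeration, fixed-point iteration) without
sharing code paths with the implementation under test.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np
from scipy import stats


# ---------------------------------------------------------------------------
# distance metrics (naive double-loop definitions)
# ---------------------------------------------------------------------------


def oracle_metric(x, y, metric: str) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    shared = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[shared], y[shared]
    if metric == "euclidean":
        return math.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)))
    if metric == "cityblock":
        return sum(abs(a - b) for a, b in zip(x, y))
    if metric in ("pearson", "pearson_abs"):
        mx, my = x.mean(), y.mean()
        num = sum((a - mx) * (b - my) for a, b in zip(x, y))
        den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
        r = 0.0 if den == 0 else num / den
    elif metric in ("uncentered", "uncentered_abs"):
        num = sum(a * b for a, b in zip(x, y))
        den = math.sqrt(sum(a * a for a in x) * sum(b * b for b in y))
        r = 0.0 if den == 0 else num / den
    elif metric == "spearman":
        r = stats.spearmanr(x, y).statistic
        r = 0.0 if np.isnan(r) else r
    elif metric == "kendall":
        r = stats.kendalltau(x, y).statistic
        r = 0.0 if np.isnan(r) else r
    else:
        raise ValueError(metric)
    return 1.0 - abs(r) if metric.endswith("_abs") else 1.0 - r


def oracle_distance_matrix(X, metric: str) -> np.ndarray:
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                D[i, j] = oracle_metric(X[i], X[j], metric)
    return D


# ---------------------------------------------------------------------------
# naive agglomeration: recompute every linkage from leaf pairs each step
# ---------------------------------------------------------------------------


def naive_hierarchical(X, ids, metric: str, linkage: str):
    """O(n^3)-per-step agglomeration recomputing linkage from scratch.

    Returns merges as a list of (left_members, right_members, height)
    frozenset pairs in merge order, applying the same deterministic
    tie-break (quantized distance, then lexicographic pair of smallest
    member ids) as the library contract states.
    """
    X = np.asarray(X, float)
    n = len(ids)
    leaf_D = oracle_distance_matrix(X, metric)
    clusters = [frozenset([i]) for i in range(n)]
    merges = []

    def linkage_distance(a: frozenset, b: frozenset) -> float:
        if linkage == "centroid":
            ca = np.nanmean(X[sorted(a)], axis=0)
            cb = np.nanmean(X[sorted(b)], axis=0)
            return oracle_metric(ca, cb, metric)
        pair_ds = [leaf_D[i, j] for i in a for j in b]
        if linkage == "single":
            return min(pair_ds)
        if linkage == "complete":
            return max(pair_ds)
        return sum(pair_ds) / len(pair_ds)  # average

    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            d = linkage_distance(a, b)
            pair = tuple(sorted((min(ids[i] for i in a), min(ids[i] for i in b))))
            key = (round(d, 12), pair)
            if best is None or key < best[0]:
                best = (key, a, b, d)
        _, a, b, d = best
        merges.append((frozenset(ids[i] for i in a), frozenset(ids[i] for i in b), d))
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(a | b)
    return merges


def dendrogram_as_member_merges(dendrogram):
    """Normalize a Dendrogram to (left_members, right_members, height)."""
    out = []
    for left, right, h in dendrogram.merges:
        lm = dendrogram.members(left) if not isinstance(left, str) else frozenset([left])
        rm = dendrogram.members(right) if not isinstance(right, str) else frozenset([right])
        out.append((lm, rm, h))
    return out


# ---------------------------------------------------------------------------
# set partitions / cluster editing / modularity
# ---------------------------------------------------------------------------


def set_partitions(items):
    """All set partitions of a sequence (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def oracle_editing_cost(S, threshold, partition) -> float:
    label = {}
    for ci, block in enumerate(partition):
        for i in block:
            label[i] = ci
    n = S.shape[0]
    cost = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            together = label[i] == label[j]
            if S[i, j] > threshold and not together:
                cost += S[i, j] - threshold
            if S[i, j] < threshold and together:
                cost += threshold - S[i, j]
    return cost


def exhaustive_transclust(S, threshold):
    best_cost, best_part = np.inf, None
    for part in set_partitions(range(S.shape[0])):
        c = oracle_editing_cost(S, threshold, part)
        if c < best_cost - 1e-12:
            best_cost, best_part = c, part
    return best_cost, best_part


def oracle_modularity(g: nx.Graph, partition) -> float:
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    label = {}
    for ci, block in enumerate(partition):
        for v in block:
            label[v] = ci
    e = {}
    d = {}
    for u, v in g.edges():
        if label[u] == label[v]:
            e[label[u]] = e.get(label[u], 0) + 1
    for v in g.nodes():
        d[label[v]] = d.get(label[v], 0) + g.degree(v)
    return sum(e.get(c, 0) / m - (d.get(c, 0) / (2 * m)) ** 2 for c in d)


# ---------------------------------------------------------------------------
# exhaustive exemplar search (affinity propagation ground truth)
# ---------------------------------------------------------------------------


def exhaustive_exemplars(S, preference):
    """Best exemplar subset by net similarity, brute force (small n)."""
    n = S.shape[0]
    S = S.copy().astype(float)
    if preference == "median":
        preference = float(np.median(S[~np.eye(n, dtype=bool)]))
    best_score, best_assign = -np.inf, None
    for r in range(1, n + 1):
        for ex in itertools.combinations(range(n), r):
            score = r * preference
            assign = {}
            for i in range(n):
                if i in ex:
                    assign[i] = i
                else:
                    k = max(ex, key=lambda k: S[i, k])
                    assign[i] = k
                    score += S[i, k]
            if score > best_score + 1e-12:
                best_score, best_assign = score, assign
    clusters = {}
    for i, k in best_assign.items():
        clusters.setdefault(k, set()).add(i)
    return best_score, sorted(frozenset(c) for c in clusters.values())


# ---------------------------------------------------------------------------
# dense fixed-point MCL
# ---------------------------------------------------------------------------


def mcl_fixed_point(A, inflation, loops=None, iterations=200):
    """Run dense MCL to (near) fixed point; clusters = components of the
    nonzero structure of the limit matrix."""
    A = np.asarray(A, float)
    n = A.shape[0]
    if loops is None:
        loops = np.maximum(A.max(axis=0), 1e-12)
        loops[loops <= 1e-12] = 1.0
    M = A + np.diag(loops)
    M = M / M.sum(axis=0)
    for _ in range(iterations):
        M = M @ M
        M = M ** inflation
        M = M / M.sum(axis=0)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(n):
            if M[i, j] > 1e-6:
                g.add_edge(i, j)
    return sorted((frozenset(c) for c in nx.connected_components(g)),
                  key=lambda c: (-len(c), min(c)))


# ---------------------------------------------------------------------------
# exhaustive k-partition search (kmeans/kmedoid ground truth)
# ---------------------------------------------------------------------------


def exhaustive_kpartition(X, k, center: str = "mean"):
    """Best k-cluster partition by total within-cluster distance (euclidean)."""
    X = np.asarray(X, float)
    n = X.shape[0]
    best_cost, best_part = np.inf, None
    for part in set_partitions(range(n)):
        if len(part) != k:
            continue
        cost = 0.0
        for block in part:
            pts = X[sorted(block)]
            if center == "mean":
                c = pts.mean(axis=0)
                cost += sum(np.linalg.norm(p - c) for p in pts)
            else:  # medoid
                cost += min(
                    sum(np.linalg.norm(p - q) for p in pts) for q in pts
                )
        if cost < best_cost - 1e-12:
            best_cost, best_part = cost, part
    return best_cost, sorted(frozenset(b) for b in best_part)
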