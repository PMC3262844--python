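"""Hierarchical, k-means and k-medoid clustering of attribute matrices,
plus silhouette-based selection of the number of clusters.

The agglomerative code follows the Cluster 3.0 / Eisen conventions named
throughout the field: four linkages (single, complete, average, pairwise
centroid with centroid recomputation), merge heights equal to the linkage
distance, and a deterministic left-to-right leaf ordering.  k-means keeps
arithmetic-mean centroids under every metric (Cluster 3.0 behaviour) and
handles missing values by per-column means over observed entries.

Estimators follow the scikit-learn protocol (``fit``, ``fit_predict``,
fitted attributes with a trailing underscore); the module-level functions
``hierarchical``, ``kmeans``, ``kmedoid``, ``cut_tree``, ``silhouette``
and ``select_k`` are thin wrappers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .model import AttributeMatrix, ClusterAssignment, ClusterkitError, Dendrogram
from .preprocess import (
    DistanceMatrix,
    compute_distance,
    max_distance,
    profile_distance,
)

logger = logging.getLogger("clusterkit")

__all__ = [
    "HierarchicalClustering",
    "KMeansClustering",
    "KMedoidClustering",
    "hierarchical",
    "cut_tree",
    "kmeans",
    "kmedoid",
    "silhouette",
    "select_k",
    "SelectKResult",
]

LINKAGES = ("single", "complete", "average", "centroid")


def _coerce_matrix(X, ids=None) -> AttributeMatrix:
    if isinstance(X, AttributeMatrix):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ClusterkitError("expected a 2-D matrix")
    row_ids = [str(i) for i in range(X.shape[0])] if ids is None else [str(i) for i in ids]
    return AttributeMatrix(row_ids=row_ids, col_ids=[f"c{j}" for j in range(X.shape[1])], values=X)


# ---------------------------------------------------------------------------
# hierarchical
# ---------------------------------------------------------------------------


def _pair_key(a_min: str, b_min: str) -> tuple[str, str]:
    return (a_min, b_min) if a_min <= b_min else (b_min, a_min)


def _agglomerate(
    D: np.ndarray,
    ids: list[str],
    linkage: str,
    X: np.ndarray | None = None,
    metric: str | None = None,
) -> Dendrogram:
    """Naive O(n^3) agglomeration with explicit deterministic tie-breaks.

    At each step the pair of current clusters at minimal linkage distance
    merges; ties go to the lexicographically smallest pair of smallest
    member ids.  Centroid linkage recomputes cluster centroids from the
    raw matrix ``X`` (missing entries ignored) and measures their distance
    in ``metric``; its heights may invert, which is logged and kept.
    """
    n = len(ids)
    if n < 2:
        raise ClusterkitError("hierarchical clustering needs at least 2 items")
    if linkage not in LINKAGES:
        raise ClusterkitError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    if linkage == "centroid":
        if X is None or metric is None:
            raise ClusterkitError("centroid linkage needs the raw matrix and metric")
        # per-cluster column sums and observed counts, so centroids stay
        # correct under missing data
        csum = {i: np.where(np.isnan(X[i]), 0.0, X[i]).astype(float) for i in range(n)}
        ccount = {i: (~np.isnan(X[i])).astype(float) for i in range(n)}

    D = D.astype(float).copy()
    active: dict[int, dict] = {
        i: {"ref": ids[i], "min": ids[i], "size": 1} for i in range(n)
    }
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(D[i, j])

    merges: list[tuple] = []
    next_idx = n
    last_height = 0.0
    inverted = False
    for step in range(n - 1):
        best = None
        for (i, j), d in dist.items():
            # distances quantized at 1e-12 for the comparison so that
            # tie-breaking is reproducible across algebraically equivalent
            # evaluation orders; the recorded height stays unrounded
            key = (round(d, 12), _pair_key(active[i]["min"], active[j]["min"]))
            if best is None or key < best[0]:
                best = (key, i, j)
        (_, _), bi, bj = best[0][1], best[1], best[2]
        d_merge = best[0][0]
        a, b = active[bi], active[bj]
        merges.append((a["ref"], b["ref"], max(d_merge, 0.0)))
        if d_merge < last_height - 1e-12:
            inverted = True
        last_height = d_merge

        new = {
            "ref": step,
            "min": min(a["min"], b["min"]),
            "size": a["size"] + b["size"],
        }
        # distances from the merged cluster to every other active cluster
        others = [k for k in active if k not in (bi, bj)]
        new_d: dict[int, float] = {}
        if linkage == "centroid":
            pass  # handled after bookkeeping below
        else:
            for k in others:
                dik = dist[(min(bi, k), max(bi, k))]
                djk = dist[(min(bj, k), max(bj, k))]
                if linkage == "single":
                    new_d[k] = min(dik, djk)
                elif linkage == "complete":
                    new_d[k] = max(dik, djk)
                else:  # average: size-weighted mean of leaf-pair distances
                    na, nb = a["size"], b["size"]
                    new_d[k] = (na * dik + nb * djk) / (na + nb)

        for k in (bi, bj):
            del active[k]
        dist = {
            (i, j): d
            for (i, j), d in dist.items()
            if bi not in (i, j) and bj not in (i, j)
        }
        active[next_idx] = new

        if linkage == "centroid":
            csum[next_idx] = csum[bi] + csum[bj]
            ccount[next_idx] = ccount[bi] + ccount[bj]
            with np.errstate(invalid="ignore"):
                merged_centroid = np.where(
                    ccount[next_idx] > 0,
                    csum[next_idx] / np.maximum(ccount[next_idx], 1),
                    np.nan,
                )
            for k in others:
                with np.errstate(invalid="ignore"):
                    other_centroid = np.where(
                        ccount[k] > 0, csum[k] / np.maximum(ccount[k], 1), np.nan
                    )
                d = profile_distance(merged_centroid, other_centroid, metric)
                if np.isnan(d):
                    d = max_distance(metric) or 0.0
                new_d[k] = d
            del csum[bi], csum[bj], ccount[bi], ccount[bj]

        for k, d in new_d.items():
            dist[(min(k, next_idx), max(k, next_idx))] = d
        next_idx += 1

    if inverted:
        logger.warning("centroid linkage produced height inversions; rendered as-is")
    return Dendrogram(leaf_ids=tuple(ids), merges=tuple(merges), metric=metric)


class HierarchicalClustering(BaseEstimator):
    """Agglomerative clustering with Eisen/Cluster 3.0 semantics.

    Parameters
    ----------
    linkage : {"single", "complete", "average", "centroid"}
    metric : distance metric name (see :data:`clusterkit.preprocess.METRICS`)
    axis : {"rows", "cols"} -- which axis of the matrix to cluster

    Attributes (after ``fit``)
    --------------------------
    dendrogram_ : :class:`~clusterkit.model.Dendrogram`
    leaf_order_ : list of ids in display order
    """

    def __init__(self, linkage: str = "average", metric: str = "uncentered", axis: str = "rows"):
        self.linkage = linkage
        self.metric = metric
        self.axis = axis

    def fit(self, X, y=None, ids=None):
        matrix = _coerce_matrix(X, ids)
        if self.axis == "cols":
            matrix = matrix.transpose()
        drop = set(matrix.all_missing_rows())
        if drop:
            keep = [i for i, r in enumerate(matrix.row_ids) if r not in drop]
            logger.warning("ignoring %d row(s) without data", len(drop))
            matrix = AttributeMatrix(
                row_ids=[matrix.row_ids[i] for i in keep],
                col_ids=list(matrix.col_ids),
                values=matrix.values[keep],
            )
        dm = compute_distance(matrix, metric=self.metric, axis="rows")
        self.dendrogram_ = _agglomerate(
            dm.d, dm.ids, self.linkage, X=matrix.values, metric=self.metric
        )
        self.leaf_order_ = self.dendrogram_.leaf_order
        return self

    def cut(self, height: float | None = None, n_groups: int | None = None) -> ClusterAssignment:
        return cut_tree(self.dendrogram_, height=height, n_groups=n_groups)


def hierarchical(distance: DistanceMatrix, linkage: str, matrix=None, metric: str | None = None) -> Dendrogram:
    """Build a dendrogram from a precomputed distance matrix.

    ``matrix`` (raw values, NaN for missing) is required for centroid
    linkage, which recomputes centroid-to-centroid distances in the
    distance matrix's metric.
    """
    metric = metric or distance.metric
    X = None
    if matrix is not None:
        X = matrix.values if isinstance(matrix, AttributeMatrix) else np.asarray(matrix, float)
    return _agglomerate(distance.d, list(distance.ids), linkage, X=X, metric=metric)


def cut_tree(
    dendrogram: Dendrogram,
    height: float | None = None,
    n_groups: int | None = None,
) -> ClusterAssignment:
    """Cut a dendrogram into groups.

    With ``height``, merges above the threshold are removed (a merge also
    dissolves if a child merge was removed, which matters when centroid
    linkage inverted heights).  With ``n_groups``, the last merges in
    merge order are undone until that many groups remain.
    """
    n = dendrogram.n_leaves
    if (height is None) == (n_groups is None):
        raise ClusterkitError("specify exactly one of height / n_groups")
    if n_groups is not None:
        if n_groups > n or n_groups < 1:
            raise ClusterkitError(f"n_groups must be in [1, {n}]")
        surviving = set(range(n - n_groups))
    else:
        surviving = set()
        for idx, (left, right, h) in enumerate(dendrogram.merges):
            ok = h <= height
            for child in (left, right):
                if isinstance(child, int) and child not in surviving:
                    ok = False
            if ok:
                surviving.add(idx)

    parent: dict = {}

    def find(x):
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    refs: dict = {}
    for idx in sorted(surviving):
        left, right, _ = dendrogram.merges[idx]
        lref = left if isinstance(left, str) else refs[left]
        rref = right if isinstance(right, str) else refs[right]
        union(lref, rref)
        refs[idx] = find(lref)

    groups: dict = {}
    for leaf in dendrogram.leaf_ids:
        groups.setdefault(find(leaf), set()).add(leaf)
    return ClusterAssignment.from_clusters(groups.values())


# ---------------------------------------------------------------------------
# k-means / k-medoid
# ---------------------------------------------------------------------------


def _row_center_distance(row: np.ndarray, center: np.ndarray, metric: str) -> float:
    d = profile_distance(row, center, metric)
    if np.isnan(d):
        cap = max_distance(metric)
        return cap if cap is not None else np.inf
    return d


class _KPartitionBase(BaseEstimator, ClusterMixin):
    """Shared Lloyd-style machinery for k-means and k-medoid."""

    def __init__(self, k=2, metric="euclidean", max_iterations=100, n_init=10, random_state=42):
        self.k = k
        self.metric = metric
        self.max_iterations = max_iterations
        self.n_init = n_init
        self.random_state = random_state

    # subclass hooks -------------------------------------------------------

    def _update_centers(self, V, labels, centers, medoid_rows):  # pragma: no cover
        raise NotImplementedError

    def fit(self, X, y=None, ids=None):
        matrix = _coerce_matrix(X, ids)
        drop = set(matrix.all_missing_rows())
        keep = [i for i, r in enumerate(matrix.row_ids) if r not in drop]
        if drop:
            logger.warning("ignoring %d row(s) without data", len(drop))
        V = matrix.values[keep]
        row_ids = [matrix.row_ids[i] for i in keep]
        n = len(row_ids)
        k = int(self.k)
        if k > n:
            raise ClusterkitError(f"k={k} exceeds the {n} clusterable rows")

        best = None
        for init in range(self.n_init):
            rng = np.random.default_rng([int(self.random_state), init])
            labels, centers, medoids, obj, path = self._lloyd(V, k, rng)
            if best is None or obj < best[3] - 1e-12:
                best = (labels, centers, medoids, obj, path)
        labels, centers, medoids, obj, path = best

        clusters: dict[int, set] = {c: set() for c in range(k)}
        for rid, lab in zip(row_ids, labels):
            clusters[lab].add(rid)
        assignment = ClusterAssignment.from_clusters(
            (c for c in clusters.values() if c), unassigned=drop
        )
        # relabel rows to the canonical cluster order
        canon = assignment.labels
        self.labels_ = np.array([canon[rid] for rid in row_ids])
        self.row_ids_ = row_ids
        self.assignment_ = assignment
        self.inertia_ = obj
        self.objective_path_ = path
        order = {}
        for lab, rid in zip(labels, row_ids):
            order.setdefault(canon[rid], lab)
        self.cluster_centers_ = np.array([centers[order[c]] for c in range(len(assignment.clusters))])
        if medoids is not None:
            self.medoid_ids_ = [row_ids[medoids[order[c]]] for c in range(len(assignment.clusters))]
        return self

    def fit_predict(self, X, y=None, ids=None):
        return self.fit(X, ids=ids).labels_

    # Lloyd ----------------------------------------------------------------

    def _assign(self, V, centers):
        n, k = V.shape[0], centers.shape[0]
        labels = np.zeros(n, dtype=int)
        total = 0.0
        dists = np.zeros(k)
        for i in range(n):
            for c in range(k):
                dists[c] = _row_center_distance(V[i], centers[c], self.metric)
            labels[i] = int(np.argmin(dists))  # argmin takes the lowest index on ties
            total += dists[labels[i]]
        return labels, total

    def _lloyd(self, V, k, rng):
        n = V.shape[0]
        idx = rng.choice(n, size=k, replace=False)
        medoid_rows = list(idx)
        centers = V[idx].copy()
        labels, obj = self._assign(V, centers)
        path = [obj]
        for _ in range(int(self.max_iterations)):
            centers, medoid_rows = self._update_centers(V, labels, centers, medoid_rows)
            new_labels, obj = self._assign(V, centers)
            # empty-cluster repair: reseed with the row farthest from its center
            for c in range(k):
                if not (new_labels == c).any():
                    far = -1.0
                    far_i = 0
                    for i in range(n):
                        d = _row_center_distance(V[i], centers[new_labels[i]], self.metric)
                        if d > far:
                            far, far_i = d, i
                    centers[c] = V[far_i]
                    if medoid_rows is not None:
                        medoid_rows[c] = far_i
                    new_labels, obj = self._assign(V, centers)
            path.append(obj)
            if (new_labels == labels).all():
                labels = new_labels
                break
            labels = new_labels
        return labels, centers, medoid_rows if medoid_rows is not None else None, obj, path


class KMeansClustering(_KPartitionBase):
    """Lloyd k-means with seeded restarts, missing-value aware.

    Initial centers are ``k`` distinct rows drawn by the seeded RNG; the
    update step is the per-column mean of cluster members over observed
    entries (arithmetic means even under correlation metrics, matching
    Cluster 3.0); the best of ``n_init`` restarts by total within-cluster
    distance wins.  Fitted attributes: ``labels_``, ``cluster_centers_``,
    ``assignment_``, ``inertia_``.
    """

    def _update_centers(self, V, labels, centers, medoid_rows):
        k = centers.shape[0]
        out = centers.copy()
        for c in range(k):
            members = V[labels == c]
            if len(members):
                with np.errstate(all="ignore"):
                    m = np.nanmean(members, axis=0)
                out[c] = m
        return out, None


class KMedoidClustering(_KPartitionBase):
    """k-medoid: centers restricted to actual rows.

    The update step picks the member minimizing the summed distance to
    its cluster (ties to the lowest row index).  Adds ``medoid_ids_``.
    """

    def _update_centers(self, V, labels, centers, medoid_rows):
        k = centers.shape[0]
        out = centers.copy()
        med = list(medoid_rows) if medoid_rows is not None else [0] * k
        for c in range(k):
            member_idx = np.flatnonzero(labels == c)
            if not len(member_idx):
                continue
            best_cost, best_i = None, None
            for i in member_idx:
                cost = sum(
                    _row_center_distance(V[j], V[i], self.metric) for j in member_idx
                )
                if best_cost is None or cost < best_cost - 1e-12:
                    best_cost, best_i = cost, i
            med[c] = int(best_i)
            out[c] = V[best_i]
        return out, med


def kmeans(matrix, k, metric="euclidean", max_iterations=100, n_init=10, seed=42):
    """Thin wrapper; returns the fitted :class:`KMeansClustering`."""
    return KMeansClustering(
        k=k, metric=metric, max_iterations=max_iterations, n_init=n_init, random_state=seed
    ).fit(matrix)


def kmedoid(matrix, k, metric="euclidean", max_iterations=100, n_init=10, seed=42):
    """Thin wrapper; returns the fitted :class:`KMedoidClustering`."""
    return KMedoidClustering(
        k=k, metric=metric, max_iterations=max_iterations, n_init=n_init, random_state=seed
    ).fit(matrix)


# ---------------------------------------------------------------------------
# silhouette and model selection
# ---------------------------------------------------------------------------


def silhouette(assignment: ClusterAssignment, distance: DistanceMatrix) -> tuple[dict, float]:
    """Per-node silhouette values s(i) = (b - a) / max(a, b) and their mean.

    a is the mean distance to the node's own cluster (excluding itself),
    b the smallest mean distance to any other cluster.  Nodes in singleton
    clusters score 0 by convention, as does the degenerate a == b == 0
    case.  Requires at least two clusters.
    """
    if assignment.n_clusters < 2:
        raise ClusterkitError("silhouette is undefined for a single-cluster partition")
    index = {nid: i for i, nid in enumerate(distance.ids)}
    D = distance.d
    values: dict[str, float] = {}
    member_idx = [np.array(sorted(index[n] for n in c)) for c in assignment.clusters]
    for ci, cluster in enumerate(assignment.clusters):
        for node in cluster:
            i = index[node]
            if len(cluster) == 1:
                values[node] = 0.0
                continue
            own = member_idx[ci]
            a = D[i, own[own != i]].mean()
            b = min(
                D[i, member_idx[cj]].mean()
                for cj in range(len(member_idx))
                if cj != ci
            )
            denom = max(a, b)
            values[node] = 0.0 if denom == 0 else (b - a) / denom
    mean = float(np.mean(list(values.values())))
    return values, mean


@dataclass
class SelectKResult:
    k: int
    silhouettes: dict  # k -> mean silhouette
    assignments: dict  # k -> ClusterAssignment


def select_k(
    matrix,
    algorithm: str = "kmeans",
    k_range: tuple[int, int] = (2, 5),
    metric: str = "euclidean",
    max_iterations: int = 100,
    n_init: int = 10,
    seed: int = 42,
) -> SelectKResult:
    """Choose k by maximizing the mean silhouette over ``k_range``.

    Runs the requested partitioner for each k in the inclusive range with
    the shared seed, scores each solution with the clustering metric's
    distance matrix, and returns the argmax (ties to the smaller k).
    """
    k_min, k_max = int(k_range[0]), int(k_range[1])
    matrix = _coerce_matrix(matrix)
    keep = [r for r in matrix.row_ids if r not in set(matrix.all_missing_rows())]
    n = len(keep)
    if not (2 <= k_min <= k_max <= max(n - 1, 2)):
        raise ClusterkitError(f"degenerate k range ({k_min}, {k_max}) for {n} rows")
    cls = {"kmeans": KMeansClustering, "kmedoid": KMedoidClustering}[algorithm]
    dm_full = compute_distance(matrix, metric=metric, axis="rows")
    keep_idx = [i for i, r in enumerate(matrix.row_ids) if r in set(keep)]
    dm = DistanceMatrix(
        ids=[matrix.row_ids[i] for i in keep_idx],
        d=dm_full.d[np.ix_(keep_idx, keep_idx)],
        metric=metric,
    )
    sils: dict[int, float] = {}
    assignments: dict[int, ClusterAssignment] = {}
    for k in range(k_min, k_max + 1):
        est = cls(
            k=k, metric=metric, max_iterations=max_iterations, n_init=n_init, random_state=seed
        ).fit(matrix)
        # silhouette over clustered rows only
        part = ClusterAssignment.from_clusters(est.assignment_.clusters)
        if part.n_clusters < 2:
            sils[k] = -1.0
        else:
            _, sils[k] = silhouette(part, dm)
        assignments[k] = est.assignment_
    best = max(sorted(sils), key=lambda k: sils[k])  # ties -> smaller k
    return SelectKResult(k=best, silhouettes=sils, assignments=assignments)
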