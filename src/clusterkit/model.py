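"""Core data containers shared by every clustering algorithm.

The toolkit operates on two kinds of primary input: a weighted, undirected
network (protein-protein interaction or sequence-similarity graphs) and a
numeric attribute matrix (gene expression profiles, genetic-interaction
scores) with explicit missing values.  Clustering results are represented
as a size-ordered partition (:class:`ClusterAssignment`), a full binary
merge tree (:class:`Dendrogram`), or a co-clustering frequency network
(:class:`CoClusterNetwork`).

Determinism conventions used throughout the package:

* node identifiers are opaque strings; every tie is broken by
  lexicographic id order;
* clusters are ordered by decreasing size, ties by the lexicographically
  smallest member id;
* networks are undirected, store at most one edge per unordered pair and
  never store self-loops at the user level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

logger = logging.getLogger("clusterkit")

__all__ = [
    "ClusterkitError",
    "ParseError",
    "WeightedNetwork",
    "AttributeMatrix",
    "ClusterAssignment",
    "Dendrogram",
    "CoClusterNetwork",
]


class ClusterkitError(Exception):
    """Base class for errors raised by clusterkit."""


class ParseError(ClusterkitError):
    """Malformed input file; the message names the file and offending line."""


# ---------------------------------------------------------------------------
# WeightedNetwork
# ---------------------------------------------------------------------------


class WeightedNetwork:
    """Undirected network with one numeric weight per edge.

    Invariants: no self-loops, at most one edge per unordered pair
    (duplicates collapsed keeping the maximum weight, logged), every edge
    endpoint is a node.  Node attributes are free-form per-node values.
    """

    def __init__(
        self,
        nodes: Iterable[str] = (),
        edges: Iterable[tuple] = (),
        node_attributes: Mapping[str, dict] | None = None,
    ) -> None:
        self._adj: dict[str, dict[str, float]] = {}
        self.node_attributes: dict[str, dict] = dict(node_attributes or {})
        for n in nodes:
            self.add_node(n)
        for e in edges:
            self.add_edge(*e)

    # -- construction ------------------------------------------------------

    def add_node(self, node: str) -> None:
        self._adj.setdefault(str(node), {})

    def add_edge(self, u: str, v: str, weight: float = 1.0, combine: str = "max") -> None:
        """Add an undirected edge, collapsing duplicates.

        ``combine`` decides what happens when the unordered pair already
        exists: ``"max"`` (default, logged) keeps the larger weight,
        ``"last"`` overwrites.  Self-loops are dropped with a debug log.
        """
        u, v = str(u), str(v)
        if u == v:
            logger.debug("dropping self-loop on node %r", u)
            self.add_node(u)
            return
        weight = float(weight)
        self.add_node(u)
        self.add_node(v)
        if v in self._adj[u]:
            old = self._adj[u][v]
            if combine == "max":
                if weight != old:
                    logger.warning(
                        "duplicate edge %s-%s: keeping max weight %g (had %g, saw %g)",
                        u, v, max(old, weight), old, weight,
                    )
                weight = max(old, weight)
        self._adj[u][v] = weight
        self._adj[v][u] = weight

    def remove_edge(self, u: str, v: str) -> None:
        del self._adj[u][v]
        del self._adj[v][u]

    # -- queries -----------------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        """Node ids in lexicographic order."""
        return sorted(self._adj)

    def __contains__(self, node: str) -> bool:
        return node in self._adj

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self._adj.values()) // 2

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Yield ``(u, v, weight)`` with ``u < v``, lexicographically sorted."""
        for u in sorted(self._adj):
            for v in sorted(self._adj[u]):
                if u < v:
                    yield u, v, self._adj[u][v]

    def has_edge(self, u: str, v: str) -> bool:
        return v in self._adj.get(u, ())

    def weight(self, u: str, v: str) -> float:
        return self._adj[u][v]

    def neighbors(self, u: str) -> dict[str, float]:
        return dict(self._adj[u])

    def degree(self, u: str) -> int:
        return len(self._adj[u])

    def copy(self) -> "WeightedNetwork":
        net = WeightedNetwork()
        net._adj = {u: dict(nbrs) for u, nbrs in self._adj.items()}
        net.node_attributes = {u: dict(a) for u, a in self.node_attributes.items()}
        return net

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedNetwork):
            return NotImplemented
        return self._adj == other._adj

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"WeightedNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"

    # -- conversions -------------------------------------------------------

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges())
        return g

    @classmethod
    def from_networkx(cls, g) -> "WeightedNetwork":
        net = cls(nodes=(str(n) for n in g.nodes))
        for u, v, data in g.edges(data=True):
            net.add_edge(str(u), str(v), float(data.get("weight", 1.0)))
        return net


# ---------------------------------------------------------------------------
# AttributeMatrix
# ---------------------------------------------------------------------------


@dataclass
class AttributeMatrix:
    """Rows (nodes/genes) x columns (arrays/attributes) with missing values.

    ``values`` is a float array with ``NaN`` marking missing entries; the
    boolean ``mask`` property mirrors it.  ``row_names`` carries the
    optional human-readable NAME column of the Cluster 3.0 dialect;
    ``gweights``/``eweights`` are parsed but only stored as metadata.
    """

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray
    row_names: list[str] | None = None
    gweights: np.ndarray | None = None
    eweights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ClusterkitError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.col_ids)} columns"
            )
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ClusterkitError("duplicate row ids")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise ClusterkitError("duplicate column ids")

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, ``True`` where the value is missing."""
        return np.isnan(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def all_missing_rows(self) -> list[str]:
        """Ids of rows with no observed value; downstream clustering skips them."""
        missing = np.all(np.isnan(self.values), axis=1)
        return [rid for rid, m in zip(self.row_ids, missing) if m]

    def transpose(self) -> "AttributeMatrix":
        return AttributeMatrix(
            row_ids=list(self.col_ids),
            col_ids=list(self.row_ids),
            values=self.values.T.copy(),
        )

    def copy(self) -> "AttributeMatrix":
        return AttributeMatrix(
            row_ids=list(self.row_ids),
            col_ids=list(self.col_ids),
            values=self.values.copy(),
            row_names=list(self.row_names) if self.row_names is not None else None,
            gweights=None if self.gweights is None else self.gweights.copy(),
            eweights=None if self.eweights is None else self.eweights.copy(),
        )


# ---------------------------------------------------------------------------
# ClusterAssignment
# ---------------------------------------------------------------------------


def _canonical_order(clusters: Iterable[frozenset]) -> tuple[frozenset, ...]:
    return tuple(sorted((frozenset(c) for c in clusters if c), key=lambda c: (-len(c), min(c))))


@dataclass(frozen=True)
class ClusterAssignment:
    """Partition (or partial, possibly overlapping cover) of nodes.

    Clusters are kept in canonical order: decreasing size, ties broken by
    the lexicographically smallest member.  ``unassigned`` is empty for
    partition-producing algorithms; module-density searches may leave
    nodes out or (with fluff) place one node in several clusters.
    """

    clusters: tuple[frozenset, ...]
    unassigned: frozenset = frozenset()

    @classmethod
    def from_clusters(
        cls, clusters: Iterable[Iterable[str]], unassigned: Iterable[str] = ()
    ) -> "ClusterAssignment":
        return cls(_canonical_order(frozenset(c) for c in clusters), frozenset(unassigned))

    @classmethod
    def from_labels(cls, labels: Mapping[str, int]) -> "ClusterAssignment":
        groups: dict[int, set] = {}
        for node, lab in labels.items():
            groups.setdefault(lab, set()).add(node)
        return cls.from_clusters(groups.values())

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def labels(self) -> dict[str, int]:
        """Node -> 0-based cluster index (first containing cluster if overlapping)."""
        out: dict[str, int] = {}
        for i, c in enumerate(self.clusters):
            for node in c:
                out.setdefault(node, i)
        return out

    @property
    def all_nodes(self) -> frozenset:
        nodes: set = set(self.unassigned)
        for c in self.clusters:
            nodes |= c
        return frozenset(nodes)

    @property
    def overlapping(self) -> bool:
        return sum(len(c) for c in self.clusters) > len(set().union(*self.clusters)) if self.clusters else False

    def is_partition_of(self, nodes: Iterable[str]) -> bool:
        nodes = set(nodes)
        seen: set = set()
        for c in self.clusters:
            if seen & c:
                return False
            seen |= c
        return seen == nodes and not self.unassigned

    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]


# ---------------------------------------------------------------------------
# Dendrogram
# ---------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """Full binary merge tree over ``leaf_ids`` with merge heights.

    ``merges`` holds ``n - 1`` triples ``(left, right, height)`` in merge
    order; a child is either a leaf id (str) or the integer index of an
    earlier merge.  ``leaf_order`` is the left-to-right traversal with the
    child containing the lexicographically smallest leaf placed left.
    ``metric`` records the distance metric the heights were measured in
    (used by the TreeView exporter to pick its score convention).
    """

    leaf_ids: tuple
    merges: tuple
    metric: str | None = None
    _members: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.leaf_ids = tuple(self.leaf_ids)
        self.merges = tuple((l, r, float(h)) for l, r, h in self.merges)
        n = len(self.leaf_ids)
        if n >= 1 and len(self.merges) != n - 1:
            raise ClusterkitError(
                f"dendrogram over {n} leaves needs {n - 1} merges, got {len(self.merges)}"
            )
        for left, right, h in self.merges:
            if h < 0:
                raise ClusterkitError("negative merge height")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def members(self, ref) -> frozenset:
        """Leaf set of a child reference (leaf id or merge index)."""
        if isinstance(ref, str):
            return frozenset((ref,))
        if ref not in self._members:
            left, right, _ = self.merges[ref]
            self._members[ref] = self.members(left) | self.members(right)
        return self._members[ref]

    @property
    def leaf_order(self) -> list[str]:
        def order(ref) -> list[str]:
            if isinstance(ref, str):
                return [ref]
            left, right, _ = self.merges[ref]
            lo, ro = order(left), order(right)
            if min(ro) < min(lo):
                lo, ro = ro, lo
            return lo + ro

        if not self.merges:
            return list(self.leaf_ids)
        return order(len(self.merges) - 1)

    def to_scipy(self) -> np.ndarray:
        """Linkage matrix in scipy convention (leaves 0..n-1 in leaf_ids order)."""
        index = {leaf: i for i, leaf in enumerate(self.leaf_ids)}
        n = self.n_leaves
        Z = np.zeros((len(self.merges), 4))
        for k, (left, right, h) in enumerate(self.merges):
            li = index[left] if isinstance(left, str) else n + left
            ri = index[right] if isinstance(right, str) else n + right
            Z[k] = [min(li, ri), max(li, ri), h, len(self.members(k))]
        return Z


# ---------------------------------------------------------------------------
# CoClusterNetwork
# ---------------------------------------------------------------------------


@dataclass
class CoClusterNetwork:
    """Node pairs weighted by co-clustering frequency across an ensemble.

    ``pairs`` maps ordered ``(u, v)`` with ``u < v`` to the fraction of the
    ``n_runs`` ensemble members in which the two nodes shared a cluster.
    ``consensus`` is the partition given by connected components of pairs
    with frequency above 0.5; ``cluster_colors`` exposes it as a discrete
    node -> label map for rendering.
    """

    pairs: dict
    n_runs: int
    consensus: ClusterAssignment

    def __post_init__(self) -> None:
        for (u, v), f in self.pairs.items():
            if not (0.0 <= f <= 1.0):
                raise ClusterkitError(f"co-cluster frequency {f} outside [0,1] for {u}-{v}")
            if not u < v:
                raise ClusterkitError(f"pair {(u, v)} not in canonical order")

    @property
    def cluster_colors(self) -> dict[str, int]:
        return self.consensus.labels

    def frequency(self, u: str, v: str) -> float:
        if u == v:
            return 1.0
        key = (u, v) if u < v else (v, u)
        return self.pairs.get(key, 0.0)
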