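"""Derived networks and visualization-ready exports.

Turns cluster assignments into: cluster-only networks (inter-cluster
edges dropped, optionally restored with labels), nested group trees
mirroring a dendrogram, ensemble co-clustering ("fuzzy") networks, Java
TreeView-compatible CDT/GTR/ATR file triplets, and ordered heat-map
tables with cluster separators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model import (
    AttributeMatrix,
    ClusterAssignment,
    ClusterkitError,
    CoClusterNetwork,
    Dendrogram,
    WeightedNetwork,
)
from .preprocess import CORRELATION_METRICS

logger = logging.getLogger("clusterkit")

__all__ = [
    "build_cluster_network",
    "write_cluster_network",
    "hierarchy_groups",
    "Group",
    "ensemble_cocluster",
    "write_cocluster_network",
    "write_treeview",
    "heatmap_table",
    "HeatmapTable",
]


# ---------------------------------------------------------------------------
# cluster networks
# ---------------------------------------------------------------------------


def build_cluster_network(
    network: WeightedNetwork,
    assignment: ClusterAssignment,
    restore_inter_cluster: bool = False,
) -> tuple[WeightedNetwork, dict]:
    """Network restricted to intra-cluster edges.

    Returns ``(network, edge_labels)`` where ``edge_labels`` maps each
    ``(u, v)`` pair (u < v) to ``"intra"`` or ``"inter"``.  With
    ``restore_inter_cluster`` false only intra-cluster edges survive;
    true adds the dropped edges back, labelled ``inter``.  Never invents
    edges: the output edge set is a subset of the input's.
    """
    missing = set(network.nodes) - set(assignment.all_nodes)
    if missing:
        raise ClusterkitError(
            "assignment does not cover nodes: " + ", ".join(sorted(missing)[:10])
        )
    membership: dict[str, set] = {}
    for i, cluster in enumerate(assignment.clusters):
        for node in cluster:
            membership.setdefault(node, set()).add(i)
    out = WeightedNetwork(nodes=network.nodes)
    labels: dict[tuple, str] = {}
    for u, v, w in network.edges():
        shared = membership.get(u, set()) & membership.get(v, set())
        if shared:
            out.add_edge(u, v, w)
            labels[(u, v)] = "intra"
        elif restore_inter_cluster:
            out.add_edge(u, v, w)
            labels[(u, v)] = "inter"
    return out, labels


def write_cluster_network(network: WeightedNetwork, edge_labels: dict, path) -> None:
    """Edge-list TSV with an ``edge_type`` column (intra/inter)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("source\ttarget\tweight\tedge_type\n")
        for u, v, w in network.edges():
            fh.write(f"{u}\t{v}\t{w!r}\t{edge_labels[(u, v)]}\n")


# ---------------------------------------------------------------------------
# hierarchical groups
# ---------------------------------------------------------------------------


@dataclass
class Group:
    """One node of the nested group tree mirroring a dendrogram merge.

    ``group_id`` is stable and derived from the members (smallest member
    id plus subtree size); ``children`` are two Groups or leaf id strings.
    """

    group_id: str
    members: frozenset
    children: tuple

    @property
    def depth_index(self) -> dict:
        """leaf id -> number of groups it appears in under this root."""
        out: dict[str, int] = {}

        def walk(g: "Group", depth: int):
            for child in g.children:
                if isinstance(child, Group):
                    walk(child, depth + 1)
                else:
                    out[child] = depth + 1

        walk(self, 0)
        return out


def hierarchy_groups(dendrogram: Dendrogram) -> Group:
    """Nested groups, one per internal merge of the dendrogram."""
    built: dict[int, Group] = {}
    for idx, (left, right, _h) in enumerate(dendrogram.merges):
        children = tuple(
            built[c] if isinstance(c, int) else c for c in (left, right)
        )
        members = dendrogram.members(idx)
        built[idx] = Group(
            group_id=f"group-{min(members)}-{len(members)}",
            members=members,
            children=children,
        )
    return built[len(dendrogram.merges) - 1]


# ---------------------------------------------------------------------------
# ensemble co-clustering (fuzzy networks)
# ---------------------------------------------------------------------------


def ensemble_cocluster(
    inputs,
    algorithm,
    n_runs: int,
    seed: int = 42,
    max_edges: int | None = None,
) -> CoClusterNetwork:
    """Fuzzy network from an ensemble of clustering runs.

    ``algorithm`` is any callable ``(inputs, seed) -> ClusterAssignment``;
    it is invoked with seeds ``seed .. seed + n_runs - 1``.  Pair
    frequency is the fraction of runs in which the two nodes shared a
    cluster; the consensus partition is the connected components of pairs
    with frequency above 0.5.  The pair list is truncated to the
    ``max_edges`` highest-frequency pairs (ties by lexicographic pair).
    A deterministic algorithm with ``n_runs > 1`` is allowed but logged.
    """
    if n_runs < 1:
        raise ClusterkitError("n_runs must be >= 1")
    counts: dict[tuple, int] = {}
    nodes: set = set()
    assignments = []
    for r in range(n_runs):
        assignment = algorithm(inputs, seed + r)
        assignments.append(assignment)
        nodes |= set(assignment.all_nodes)
        for cluster in assignment.clusters:
            members = sorted(cluster)
            for i, u in enumerate(members):
                for v in members[i + 1:]:
                    counts[(u, v)] = counts.get((u, v), 0) + 1
    if n_runs > 1 and len({tuple(tuple(sorted(c)) for c in a.clusters) for a in assignments}) == 1:
        logger.warning("ensemble of %d runs produced identical partitions (deterministic algorithm?)", n_runs)

    pairs = {p: c / n_runs for p, c in counts.items()}
    if max_edges is not None and len(pairs) > max_edges:
        kept = sorted(pairs.items(), key=lambda kv: (-kv[1], kv[0]))[:max_edges]
        pairs = dict(kept)

    # consensus from the untruncated frequencies
    parent: dict = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (u, v), c in counts.items():
        if c / n_runs > 0.5:
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[ru] = rv
    groups: dict = {}
    for node in nodes:
        groups.setdefault(find(node), set()).add(node)
    consensus = ClusterAssignment.from_clusters(groups.values())
    return CoClusterNetwork(pairs=pairs, n_runs=n_runs, consensus=consensus)


def write_cocluster_network(cocluster: CoClusterNetwork, path) -> None:
    """TSV: node, node, frequency, consensus_cluster (1-based, shared or empty)."""
    colors = cocluster.cluster_colors
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("source\ttarget\tfrequency\tconsensus_cluster\n")
        for (u, v), f in sorted(cocluster.pairs.items()):
            same = colors.get(u) == colors.get(v)
            cc = str(colors[u] + 1) if same else ""
            fh.write(f"{u}\t{v}\t{f!r}\t{cc}\n")


# ---------------------------------------------------------------------------
# TreeView export
# ---------------------------------------------------------------------------


def _tree_refs(dendrogram: Dendrogram, prefix: str) -> tuple[dict, list]:
    """Map leaves/merges to TreeView node ids and emit GTR/ATR rows."""
    index = {leaf: i for i, leaf in enumerate(dendrogram.leaf_ids)}

    def ref(child) -> str:
        if isinstance(child, str):
            return f"{prefix}{index[child]}X"
        return f"NODE{child + 1}X"

    rows = []
    correlationish = dendrogram.metric in CORRELATION_METRICS
    for idx, (left, right, h) in enumerate(dendrogram.merges):
        score = 1.0 - h if correlationish else -h
        rows.append((f"NODE{idx + 1}X", ref(left), ref(right), score))
    leaf_ref = {leaf: f"{prefix}{index[leaf]}X" for leaf in dendrogram.leaf_ids}
    return leaf_ref, rows


def write_treeview(
    matrix: AttributeMatrix,
    row_dendrogram: Dendrogram,
    col_dendrogram: Dendrogram | None = None,
    path_prefix: str = "clustered",
) -> list[str]:
    """Write a Java TreeView / Cluster 3.0 CDT (+ GTR, + ATR) triplet.

    The CDT holds the matrix permuted to the dendrogram leaf orders, with
    GID (and AID) columns referencing the GTR/ATR tree nodes.  Tree rows
    are ``(node, child, child, score)`` in merge order, where score is
    ``1 - height`` for correlation-family metrics and ``-height``
    otherwise (TreeView expects correlation-like scores; the convention
    in use is recorded in a leading comment for non-correlation trees).
    Values are written at full precision so reading the CDT back gives
    identical numbers.  Returns the list of files written.
    """
    if set(row_dendrogram.leaf_ids) != set(matrix.row_ids):
        raise ClusterkitError("row dendrogram leaves do not match matrix row ids")
    if col_dendrogram is not None and set(col_dendrogram.leaf_ids) != set(matrix.col_ids):
        raise ClusterkitError("column dendrogram leaves do not match matrix column ids")

    written = []
    gene_ref, gtr_rows = _tree_refs(row_dendrogram, "GENE")
    gtr_path = f"{path_prefix}.gtr"
    with open(gtr_path, "w", encoding="utf-8", newline="\n") as fh:
        if row_dendrogram.metric not in CORRELATION_METRICS:
            fh.write("# score = -merge_height (non-correlation metric)\n")
        for row in gtr_rows:
            fh.write("\t".join(str(x) if not isinstance(x, float) else repr(x) for x in row) + "\n")
    written.append(gtr_path)

    arry_ref = None
    if col_dendrogram is not None:
        arry_ref, atr_rows = _tree_refs(col_dendrogram, "ARRY")
        atr_path = f"{path_prefix}.atr"
        with open(atr_path, "w", encoding="utf-8", newline="\n") as fh:
            if col_dendrogram.metric not in CORRELATION_METRICS:
                fh.write("# score = -merge_height (non-correlation metric)\n")
            for row in atr_rows:
                fh.write("\t".join(str(x) if not isinstance(x, float) else repr(x) for x in row) + "\n")
        written.append(atr_path)

    row_order = row_dendrogram.leaf_order
    col_order = col_dendrogram.leaf_order if col_dendrogram is not None else list(matrix.col_ids)
    ridx = {r: i for i, r in enumerate(matrix.row_ids)}
    cidx = {c: i for i, c in enumerate(matrix.col_ids)}
    names = matrix.row_names or list(matrix.row_ids)

    cdt_path = f"{path_prefix}.cdt"
    with open(cdt_path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("GID\tGENE-ID\tNAME\tGWEIGHT\t" + "\t".join(col_order) + "\n")
        if arry_ref is not None:
            fh.write("AID\t\t\t\t" + "\t".join(arry_ref[c] for c in col_order) + "\n")
        fh.write("EWEIGHT\t\t\t\t" + "\t".join(["1.0"] * len(col_order)) + "\n")
        for rid in row_order:
            i = ridx[rid]
            cells = []
            for cid in col_order:
                v = matrix.values[i, cidx[cid]]
                cells.append("" if np.isnan(v) else repr(float(v)))
            fh.write(
                f"{gene_ref[rid]}\t{rid}\t{names[i]}\t1.0\t" + "\t".join(cells) + "\n"
            )
    written.append(cdt_path)
    return written


# ---------------------------------------------------------------------------
# heat-map tables
# ---------------------------------------------------------------------------

_COLOR_ANCHORS = {
    # (low, mid, high) RGB anchors; low maps to the most negative value
    "yellow_cyan": ((0, 255, 255), (0, 0, 0), (255, 255, 0)),
    "red_green": ((0, 255, 0), (0, 0, 0), (255, 0, 0)),
}


@dataclass
class HeatmapTable:
    """Row-ordered matrix view with cluster separators for rendering.

    ``row_ids`` groups matrix rows by cluster (clusters in size order,
    input row order preserved within each cluster); ``separators`` are
    the row indices after which a cluster boundary bar belongs.
    ``anchors`` are the (low, mid, high) RGB anchors of the scale.
    """

    row_ids: list
    separators: list
    values: np.ndarray
    anchors: tuple

    def colors(self) -> np.ndarray:
        """RGB (uint8) per cell on a symmetric scale: 0 maps to mid."""
        lo, mid, hi = (np.array(a, dtype=float) for a in self.anchors)
        vmax = np.nanmax(np.abs(self.values)) if np.isfinite(self.values).any() else 1.0
        if vmax == 0:
            vmax = 1.0
        t = np.clip(self.values / vmax, -1, 1)
        out = np.zeros(self.values.shape + (3,), dtype=float)
        pos = t >= 0
        for c in range(3):
            out[..., c] = np.where(
                pos,
                mid[c] + (hi[c] - mid[c]) * t,
                mid[c] + (lo[c] - mid[c]) * (-t),
            )
        out[np.isnan(self.values)] = (128, 128, 128)  # missing = grey
        return out.astype(np.uint8)


def heatmap_table(
    matrix: AttributeMatrix,
    assignment: ClusterAssignment,
    color_scale="yellow_cyan",
) -> HeatmapTable:
    """Order matrix rows by cluster and emit separator indices.

    ``color_scale`` is ``"yellow_cyan"``, ``"red_green"`` or a custom
    (low, mid, high) RGB anchor triple.
    """
    covered = assignment.all_nodes
    missing = [r for r in matrix.row_ids if r not in covered]
    if missing:
        raise ClusterkitError("assignment does not cover matrix rows: " + ", ".join(missing[:10]))
    anchors = (
        _COLOR_ANCHORS[color_scale] if isinstance(color_scale, str) else tuple(color_scale)
    )
    order: list[str] = []
    separators: list[int] = []
    pos = {r: i for i, r in enumerate(matrix.row_ids)}
    groups = list(assignment.clusters)
    if assignment.unassigned:
        groups.append(assignment.unassigned)
    for gi, cluster in enumerate(groups):
        members = sorted((r for r in cluster if r in pos), key=lambda r: pos[r])
        order.extend(members)
        if gi < len(groups) - 1 and members:
            separators.append(len(order))
    values = matrix.values[[pos[r] for r in order]]
    return HeatmapTable(row_ids=order, separators=separators, values=values, anchors=anchors)
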