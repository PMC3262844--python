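"""Readers and writers for the plain-text formats the toolkit touches.

Supported formats: weighted edge-list TSV, SIF, the Cluster 3.0 matrix
dialect (including CDT files with GID/AID bookkeeping columns), plain
one-id-column matrices, and a simple node -> cluster assignment TSV.
All writers emit UNIX newlines, UTF-8.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .model import (
    AttributeMatrix,
    ClusterAssignment,
    ParseError,
    WeightedNetwork,
)

logger = logging.getLogger("clusterkit")

__all__ = [
    "read_edge_list",
    "write_edge_list",
    "read_matrix",
    "write_matrix",
    "write_assignment",
    "read_assignment",
]

_MISSING_TOKENS = {"", "na", "nan", "null", "none"}

# Bookkeeping column/row labels of the Cluster 3.0 / CDT dialect.
_ID_HEADERS = {"GENE-ID", "UNIQID", "GENE", "YORF", "ID", "NAME"}
_META_ROWS = {"AID", "EWEIGHT"}


def _float(cell: str, path, lineno: int) -> float:
    try:
        return float(cell)
    except ValueError:
        raise ParseError(f"{path}: line {lineno}: non-numeric value {cell!r}") from None


# ---------------------------------------------------------------------------
# edge lists
# ---------------------------------------------------------------------------


def read_edge_list(
    path,
    weight_column: str | None = None,
    directed_policy: str = "symmetrize_max",
    node_path=None,
    fmt: str | None = None,
) -> WeightedNetwork:
    """Read a weighted network from an edge-list TSV or a SIF file.

    The TSV must have header columns ``source`` and ``target``;
    ``weight_column`` names the numeric column to use (default: a column
    called ``weight`` if present, else every edge gets weight 1.0).  SIF
    rows are ``node<TAB>interaction<TAB>node...`` with unit weights.
    Duplicate unordered pairs collapse to one edge keeping the maximum
    weight (logged); directed input is symmetrized the same way.  An
    optional ``node_path`` (one id per line) adds nodes that may have no
    edges.
    """
    path = Path(path)
    if fmt is None:
        fmt = "sif" if path.suffix.lower() == ".sif" else "tsv"
    net = WeightedNetwork()

    with open(path, encoding="utf-8") as fh:
        if fmt == "sif":
            for lineno, line in enumerate(fh, 1):
                parts = line.rstrip("\n").split("\t")
                if len(parts) == 1:
                    parts = line.split()
                if not parts or not parts[0]:
                    continue
                if len(parts) == 1:
                    net.add_node(parts[0])
                else:
                    for tgt in parts[2:]:
                        net.add_edge(parts[0], tgt, 1.0)
        else:
            header = fh.readline().rstrip("\n").split("\t")
            cols = {name.strip().lower(): i for i, name in enumerate(header)}
            if "source" not in cols or "target" not in cols:
                raise ParseError(f"{path}: expected header columns 'source' and 'target'")
            if weight_column is None and "weight" in cols:
                weight_column = header[cols["weight"]]
            wi = None
            if weight_column is not None:
                key = weight_column.strip().lower()
                if key not in cols:
                    raise ParseError(f"{path}: no column named {weight_column!r}")
                wi = cols[key]
            si, ti = cols["source"], cols["target"]
            for lineno, line in enumerate(fh, 2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                w = 1.0 if wi is None else _float(parts[wi], path, lineno)
                net.add_edge(parts[si], parts[ti], w)

    if node_path is not None:
        for line in Path(node_path).read_text(encoding="utf-8").splitlines():
            if line.strip():
                net.add_node(line.strip())
    return net


def write_edge_list(network: WeightedNetwork, path, node_path=None) -> None:
    """Write an edge-list TSV (``source  target  weight``).

    Weights round-trip at full precision via ``repr``.  Isolated nodes
    are only preserved if ``node_path`` is given a file to list them in.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("source\ttarget\tweight\n")
        for u, v, w in network.edges():
            fh.write(f"{u}\t{v}\t{w!r}\n")
    if node_path is not None:
        with open(node_path, "w", encoding="utf-8", newline="\n") as fh:
            for n in network.nodes:
                fh.write(n + "\n")


# ---------------------------------------------------------------------------
# matrices (Cluster 3.0 / CDT / plain)
# ---------------------------------------------------------------------------


def read_matrix(path, dialect: str = "auto") -> AttributeMatrix:
    """Read a tab-delimited matrix.

    ``dialect`` is one of ``auto``, ``plain`` (one id column, then value
    columns) or ``cluster3`` (Cluster 3.0 / CDT: optional GID column,
    NAME and GWEIGHT columns, AID and EWEIGHT rows; all parsed, the
    weights kept only as metadata).  Empty cells become missing values.
    """
    path = Path(path)
    rows = [line.rstrip("\n").split("\t") for line in open(path, encoding="utf-8")]
    rows = [r for r in rows if any(cell.strip() for cell in r)]
    if not rows:
        raise ParseError(f"{path}: empty file")
    header = rows[0]
    width = len(header)
    for lineno, r in enumerate(rows[1:], 2):
        if len(r) != width:
            raise ParseError(f"{path}: line {lineno}: expected {width} fields, got {len(r)}")

    if dialect == "auto":
        labels = {h.strip().upper() for h in header[:4]}
        dialect = "cluster3" if labels & ({"GID", "GWEIGHT"} | _ID_HEADERS) and (
            "NAME" in labels or "GID" in labels or "GWEIGHT" in labels
        ) else "plain"

    name_col = gweight_col = None
    if dialect == "cluster3":
        upper = [h.strip().upper() for h in header]
        lead = 1
        if upper[0] == "GID":
            id_col = 1
            lead = 2
        else:
            id_col = 0
        for i, h in enumerate(upper):
            if h == "NAME":
                name_col = i
                lead = max(lead, i + 1)
            elif h == "GWEIGHT":
                gweight_col = i
                lead = max(lead, i + 1)
        data_cols = list(range(lead, width))
    else:
        id_col = 0
        data_cols = list(range(1, width))

    col_ids = [header[i] for i in data_cols]
    row_ids: list[str] = []
    row_names: list[str] = []
    gweights: list[float] = []
    eweights = None
    values: list[list[float]] = []

    for lineno, r in enumerate(rows[1:], 2):
        tag = r[0].strip().upper()
        if dialect == "cluster3" and tag in _META_ROWS:
            if tag == "EWEIGHT":
                eweights = np.array(
                    [
                        np.nan if r[i].strip().lower() in _MISSING_TOKENS else _float(r[i], path, lineno)
                        for i in data_cols
                    ]
                )
            continue
        row_ids.append(r[id_col])
        if name_col is not None:
            row_names.append(r[name_col])
        if gweight_col is not None:
            cell = r[gweight_col].strip().lower()
            gweights.append(np.nan if cell in _MISSING_TOKENS else _float(r[gweight_col], path, lineno))
        vals = []
        for i in data_cols:
            cell = r[i].strip()
            if cell.lower() in _MISSING_TOKENS:
                vals.append(np.nan)
            else:
                vals.append(_float(cell, path, lineno))
        values.append(vals)

    dupes = sorted({rid for rid in row_ids if row_ids.count(rid) > 1})
    if dupes:
        raise ParseError(f"{path}: duplicate row ids: {', '.join(dupes)}")

    matrix = AttributeMatrix(
        row_ids=row_ids,
        col_ids=col_ids,
        values=np.array(values, dtype=float).reshape(len(row_ids), len(col_ids)),
        row_names=row_names or None,
        gweights=np.array(gweights) if gweights else None,
        eweights=eweights,
    )
    dropped = matrix.all_missing_rows()
    if dropped:
        logger.warning(
            "%s: %d row(s) with no observed data (kept, ignored by clustering): %s",
            path, len(dropped), ", ".join(dropped[:5]),
        )
    return matrix


def write_matrix(matrix: AttributeMatrix, path, dialect: str = "plain") -> None:
    """Write a matrix as plain TSV (id column + value columns)."""
    if dialect != "plain":
        raise ValueError("write_matrix only emits the plain dialect; use write_treeview for CDT")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("id\t" + "\t".join(matrix.col_ids) + "\n")
        for rid, row in zip(matrix.row_ids, matrix.values):
            cells = ["" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(rid + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# assignments
# ---------------------------------------------------------------------------


def write_assignment(assignment: ClusterAssignment, path) -> None:
    """Write ``node<TAB>cluster`` rows, clusters 1-based in size order.

    Unassigned nodes get an empty cluster field.  Overlapping covers list
    a node once per containing cluster.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("node\tcluster\n")
        for i, cluster in enumerate(assignment.clusters, 1):
            for node in sorted(cluster):
                fh.write(f"{node}\t{i}\n")
        for node in sorted(assignment.unassigned):
            fh.write(f"{node}\t\n")


def read_assignment(path) -> ClusterAssignment:
    """Read an assignment TSV written by :func:`write_assignment`."""
    clusters: dict[int, set] = {}
    unassigned: set = set()
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("node"):
            raise ParseError(f"{path}: expected 'node\\tcluster' header")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 fields")
            node, idx = parts
            if idx.strip() == "":
                unassigned.add(node)
            else:
                clusters.setdefault(int(idx), set()).add(node)
    return ClusterAssignment.from_clusters(clusters.values(), unassigned)
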