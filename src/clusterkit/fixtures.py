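"""Synthetic data generators.

Every clustering algorithm in the toolkit can be exercised without any
download: planted-partition graphs stand in for interaction networks,
block-structured expression matrices for microarray data, and jittered
block similarity matrices for BLAST-style all-versus-all scores.  All
generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

import numpy as np

from .model import AttributeMatrix, ClusterkitError, WeightedNetwork

__all__ = [
    "planted_partition",
    "synthetic_expression",
    "similarity_from_labels",
]


def _draw_weight(rng: np.random.Generator, dist) -> float:
    """Draw one edge weight.  ``dist`` is None (weight 1), a constant, a
    ("uniform", lo, hi) or ("normal", mu, sd) tuple, or a callable(rng)."""
    if dist is None:
        return 1.0
    if callable(dist):
        return float(dist(rng))
    if isinstance(dist, (int, float)):
        return float(dist)
    kind = dist[0]
    if kind == "uniform":
        return float(rng.uniform(dist[1], dist[2]))
    if kind == "normal":
        return float(rng.normal(dist[1], dist[2]))
    raise ClusterkitError(f"unknown weight distribution {dist!r}")


def planted_partition(
    block_sizes,
    p_in: float,
    p_out: float,
    weight_in_dist=None,
    weight_out_dist=None,
    seed: int = 42,
) -> tuple[WeightedNetwork, dict]:
    """Planted-partition (stochastic block model) network.

    Each intra-block pair gets an edge with probability ``p_in``,
    inter-block pairs with ``p_out``; weights are drawn from the given
    distributions (default 1.0).  Node ids are ``b<block>n<index>``,
    zero-padded so lexicographic order matches construction order.
    Returns ``(network, labels)`` with labels mapping node id -> block.
    """
    if not (0 <= p_in <= 1 and 0 <= p_out <= 1):
        raise ClusterkitError("probabilities must lie in [0, 1]")
    if any(s <= 0 for s in block_sizes):
        raise ClusterkitError("block sizes must be positive")
    rng = np.random.default_rng(seed)
    bw = len(str(len(block_sizes) - 1))
    nw = len(str(max(block_sizes) - 1))
    nodes: list[str] = []
    labels: dict[str, int] = {}
    for b, size in enumerate(block_sizes):
        for i in range(size):
            nid = f"b{str(b).zfill(bw)}n{str(i).zfill(nw)}"
            nodes.append(nid)
            labels[nid] = b
    net = WeightedNetwork(nodes=nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            same = labels[u] == labels[v]
            p = p_in if same else p_out
            if rng.random() < p:
                dist = weight_in_dist if same else weight_out_dist
                net.add_edge(u, v, _draw_weight(rng, dist))
    return net, labels


def synthetic_expression(
    n_genes: int,
    n_arrays: int,
    block_structure: int | list = 4,
    effect_size: float = 3.0,
    noise_sd: float = 1.0,
    missing_rate: float = 0.0,
    seed: int = 42,
) -> tuple[AttributeMatrix, dict]:
    """Block-structured expression matrix on a log-like scale.

    ``block_structure`` is a block count (genes split as evenly as
    possible) or an explicit list of block sizes.  Each block draws a
    random +/- ``effect_size`` pattern over arrays (patterns guaranteed
    distinct across blocks); gene values are the block pattern plus
    Gaussian noise, masked missing at ``missing_rate``, and finally
    median-centered per gene so the output resembles preprocessed
    (log-scaled, centered) microarray data.  Returns
    ``(matrix, labels)`` with labels mapping gene id -> block.
    """
    if not (0 <= missing_rate <= 1):
        raise ClusterkitError("missing_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if isinstance(block_structure, int):
        base = n_genes // block_structure
        sizes = [base + (1 if b < n_genes % block_structure else 0) for b in range(block_structure)]
    else:
        sizes = list(block_structure)
        if sum(sizes) != n_genes:
            raise ClusterkitError("block sizes must sum to n_genes")
    n_blocks = len(sizes)

    patterns = np.zeros((n_blocks, n_arrays))
    seen: set = set()
    for b in range(n_blocks):
        for _ in range(1000):
            pat = rng.choice([-1.0, 1.0], size=n_arrays)
            key = tuple(pat)
            if key not in seen:
                seen.add(key)
                break
        patterns[b] = pat * effect_size

    gene_ids: list[str] = []
    labels: dict[str, int] = {}
    rows = []
    gw = len(str(n_genes - 1))
    g = 0
    for b, size in enumerate(sizes):
        for _ in range(size):
            gid = f"gene{str(g).zfill(gw)}"
            gene_ids.append(gid)
            labels[gid] = b
            rows.append(patterns[b] + rng.normal(0.0, noise_sd, size=n_arrays) if noise_sd > 0 else patterns[b].copy())
            g += 1
    V = np.array(rows, dtype=float)
    if missing_rate > 0:
        mask = rng.random(V.shape) < missing_rate
        V[mask] = np.nan
    med = np.nanmedian(V, axis=1, keepdims=True)
    V = V - np.where(np.isnan(med), 0.0, med)
    matrix = AttributeMatrix(
        row_ids=gene_ids,
        col_ids=[f"array{str(j).zfill(len(str(n_arrays - 1)))}" for j in range(n_arrays)],
        values=V,
    )
    return matrix, labels


def similarity_from_labels(
    labels: dict,
    s_in: float = 10.0,
    s_out: float = 0.0,
    jitter_sd: float = 0.0,
    seed: int = 42,
) -> tuple[list, np.ndarray]:
    """Toy BLAST-like block similarity matrix from a label map.

    Within-group pairs get ``s_in``, between-group pairs ``s_out``, plus
    symmetric Gaussian jitter.  The diagonal is ``s_in``.  Returns
    ``(ids, matrix)`` with ids in lexicographic order.
    """
    if not s_in > s_out:
        raise ClusterkitError("s_in must exceed s_out")
    rng = np.random.default_rng(seed)
    ids = sorted(labels)
    n = len(ids)
    S = np.full((n, n), float(s_out))
    for i in range(n):
        for j in range(n):
            if labels[ids[i]] == labels[ids[j]]:
                S[i, j] = s_in
    if jitter_sd > 0:
        J = rng.normal(0.0, jitter_sd, size=(n, n))
        J = (J + J.T) / 2.0
        S = S + J
        np.fill_diagonal(S, s_in)
    return ids, S
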