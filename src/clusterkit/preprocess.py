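"""Edge-weight conversion, cutoffs, adjacency construction, normalization
and distance metrics feeding every clustering algorithm.

Edge weights on similarity networks often arrive on awkward scales
(BLAST e-values, confidence scores); :func:`convert_weights` maps them to
additive similarities (e.g. ``-log10`` for e-values).  A weight histogram
plus the pluggable cutoff heuristic then separates signal from background
before clustering.  For attribute matrices, :func:`normalize_matrix`
applies the usual expression preprocessing (log2, median centering,
sum-of-squares scaling) and :func:`compute_distance` builds pairwise
distance matrices with Cluster 3.0 pairwise-complete missing-value
semantics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import AttributeMatrix, ClusterkitError, WeightedNetwork

logger = logging.getLogger("clusterkit")

__all__ = [
    "WeightHistogram",
    "DistanceMatrix",
    "convert_weights",
    "edge_weight_histogram",
    "heuristic_cutoff",
    "register_cutoff_heuristic",
    "apply_cutoff",
    "adjacency_from_edge_attribute",
    "normalize_matrix",
    "compute_distance",
    "profile_distance",
    "CORRELATION_METRICS",
    "METRICS",
]

#: metrics whose distances are 1 - correlation (range [0, 2], abs variants [0, 1])
CORRELATION_METRICS = frozenset(
    {"pearson", "pearson_abs", "uncentered", "uncentered_abs", "spearman", "kendall"}
)
METRICS = ("euclidean", "cityblock", "pearson", "pearson_abs", "uncentered",
           "uncentered_abs", "spearman", "kendall")

_CONVERSIONS = ("none", "neg_log10", "reciprocal", "log10")


# ---------------------------------------------------------------------------
# weight conversion / histogram / cutoff
# ---------------------------------------------------------------------------


@dataclass
class WeightHistogram:
    """Equal-width histogram of edge weights.

    ``len(counts) == len(bin_edges) - 1``; counts sum to the number of
    edges histogrammed.  ``conversion`` records which weight transform
    produced the underlying values.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    conversion: str = "none"

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ClusterkitError("histogram counts/edges length mismatch")
        if (self.counts < 0).any():
            raise ClusterkitError("negative histogram count")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def to_tsv(self, path) -> None:
        """Two-column TSV (bin_left, count) for external plotting."""
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("bin_left\tcount\n")
            for left, c in zip(self.bin_edges[:-1], self.counts):
                fh.write(f"{left!r}\t{c}\n")


def convert_weights(network: WeightedNetwork, mode: str, clamp: bool = True) -> WeightedNetwork:
    """Apply a per-edge weight transform; the node set is unchanged.

    Modes: ``none``, ``neg_log10`` (e-value to similarity), ``reciprocal``,
    ``log10``.  Under the log modes non-positive weights are clamped to
    the smallest positive float (logged) unless ``clamp`` is false, in
    which case they raise an error naming the edge.
    """
    if mode not in _CONVERSIONS:
        raise ClusterkitError(f"unknown conversion {mode!r}; choose from {_CONVERSIONS}")
    out = network.copy()
    if mode == "none":
        return out
    tiny = np.finfo(float).tiny
    for u, v, w in network.edges():
        if mode == "reciprocal":
            if w == 0:
                raise ClusterkitError(f"reciprocal of zero weight on edge {u}-{v}")
            nw = 1.0 / w
        else:
            if w <= 0:
                if not clamp:
                    raise ClusterkitError(f"non-positive weight {w} on edge {u}-{v} under {mode}")
                logger.warning("clamping non-positive weight %g on edge %s-%s to %g", w, u, v, tiny)
                w = tiny
            nw = math.log10(w) if mode == "log10" else -math.log10(w)
        out._adj[u][v] = nw
        out._adj[v][u] = nw
    return out


def edge_weight_histogram(network: WeightedNetwork, n_bins: int = 100) -> WeightHistogram:
    """Equal-width histogram over [min, max] weight; right-most bin closed.

    A degenerate range (all weights equal) is widened by +/-0.5 so the
    single occupied bin has nonzero width.
    """
    if n_bins < 2:
        raise ClusterkitError("n_bins must be >= 2")
    weights = np.array([w for _, _, w in network.edges()])
    if weights.size == 0:
        raise ClusterkitError("cannot histogram an empty edge set")
    lo, hi = weights.min(), weights.max()
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, n_bins + 1)
    # bins are right-inclusive ((left, right]); the first bin also
    # includes its left edge, so every weight lands in exactly one bin
    idx = np.clip(np.searchsorted(edges, weights, side="left") - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return WeightHistogram(bin_edges=edges, counts=counts)


_CUTOFF_HEURISTICS: dict = {}


def register_cutoff_heuristic(name: str):
    """Decorator registering an alternative cutoff heuristic by name."""

    def deco(fn):
        _CUTOFF_HEURISTICS[name] = fn
        return fn

    return deco


@register_cutoff_heuristic("smoothed_valley")
def _smoothed_valley(hist: WeightHistogram) -> float:
    counts = hist.counts.astype(float)
    n = len(counts)
    # centered moving average, window 3, truncated at the boundaries
    smooth = np.array(
        [counts[max(0, i - 1): i + 2].mean() for i in range(n)]
    )
    peak = int(np.argmax(smooth))
    for i in range(peak + 1, n - 1):
        if smooth[i] < smooth[i - 1] and smooth[i] <= smooth[i + 1]:
            return float(hist.bin_edges[i])
    # fallback: weight at which the cumulative count reaches 90%
    cum = np.cumsum(counts)
    target = 0.9 * cum[-1]
    idx = int(np.searchsorted(cum, target))
    return float(hist.bin_edges[idx + 1])


def heuristic_cutoff(histogram: WeightHistogram, heuristic: str = "smoothed_valley") -> float:
    """Pick an edge-weight cutoff from the histogram shape.

    The default rule smooths counts with a centered moving average of
    window 3 and returns the left edge of the first local-minimum bin
    after the global maximum; if no interior valley exists it falls back
    to the weight at which the cumulative count reaches 90%.
    """
    if histogram.n_bins < 5:
        raise ClusterkitError("heuristic cutoff needs >= 5 bins; re-bin the histogram")
    return _CUTOFF_HEURISTICS[heuristic](histogram)


def apply_cutoff(network: WeightedNetwork, cutoff: float) -> WeightedNetwork:
    """Drop edges with weight < cutoff; nodes remain (possibly isolated)."""
    out = network.copy()
    for u, v, w in list(out.edges()):
        if w < cutoff:
            out.remove_edge(u, v)
    return out


def adjacency_from_edge_attribute(
    network: WeightedNetwork,
    missing_value: float = 0.0,
    diagonal: float = 0.0,
) -> tuple[list[str], np.ndarray]:
    """Symmetric adjacency matrix keyed by sorted node ids.

    Missing edges take ``missing_value`` (default 0), the diagonal the
    ``diagonal`` policy value.  This is the bridge by which attribute
    clustering algorithms consume a single numeric edge attribute.
    """
    ids = network.nodes
    index = {n: i for i, n in enumerate(ids)}
    A = np.full((len(ids), len(ids)), float(missing_value))
    np.fill_diagonal(A, float(diagonal))
    for u, v, w in network.edges():
        A[index[u], index[v]] = w
        A[index[v], index[u]] = w
    return ids, A


# ---------------------------------------------------------------------------
# matrix normalization
# ---------------------------------------------------------------------------

_NORM_STEPS = ("log2", "median_center_rows", "median_center_cols", "ss1_rows", "ss1_cols")


def normalize_matrix(matrix: AttributeMatrix, steps) -> AttributeMatrix:
    """Apply normalization steps in order, ignoring missing values.

    Steps: ``log2``, ``median_center_rows``/``_cols`` (subtract the
    row/column median), ``ss1_rows``/``_cols`` (scale so the sum of
    squares is 1).  All-missing rows/columns pass through untouched.
    """
    out = matrix.copy()
    V = out.values
    for step in steps:
        if step not in _NORM_STEPS:
            raise ClusterkitError(f"unknown normalization step {step!r}")
        if step == "log2":
            bad = np.argwhere(~np.isnan(V) & (V <= 0))
            if bad.size:
                i, j = bad[0]
                raise ClusterkitError(
                    f"log2 of non-positive value {V[i, j]} at row {out.row_ids[i]!r}, "
                    f"column {out.col_ids[j]!r}"
                )
            V = np.log2(V)
        elif step in ("median_center_rows", "median_center_cols"):
            axis = 1 if step.endswith("rows") else 0
            with np.errstate(all="ignore"):
                med = np.nanmedian(V, axis=axis, keepdims=True)
            V = V - np.where(np.isnan(med), 0.0, med)
        else:  # ss1
            axis = 1 if step.endswith("rows") else 0
            ss = np.nansum(V**2, axis=axis, keepdims=True)
            scale = np.where(ss > 0, np.sqrt(ss), 1.0)
            V = V / scale
    out.values = V
    return out


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with a zero diagonal."""

    ids: list[str]
    d: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ClusterkitError("distance matrix shape mismatch")

    @property
    def n(self) -> int:
        return len(self.ids)


def _corr_distance(x: np.ndarray, y: np.ndarray, metric: str) -> float:
    """1 - r (or 1 - |r|) on already-aligned complete observations."""
    if metric in ("pearson", "pearson_abs"):
        xc, yc = x - x.mean(), y - y.mean()
        denom = math.sqrt((xc**2).sum() * (yc**2).sum())
        if denom == 0:
            logger.warning("zero-variance profile under pearson; correlation taken as 0")
            r = 0.0
        else:
            r = float((xc * yc).sum() / denom)
    elif metric in ("uncentered", "uncentered_abs"):
        denom = math.sqrt((x**2).sum() * (y**2).sum())
        r = 0.0 if denom == 0 else float((x * y).sum() / denom)
    elif metric == "spearman":
        r = stats.spearmanr(x, y).statistic
        r = 0.0 if np.isnan(r) else float(r)
    elif metric == "kendall":
        r = stats.kendalltau(x, y).statistic
        r = 0.0 if np.isnan(r) else float(r)
    else:  # pragma: no cover
        raise ClusterkitError(f"not a correlation metric: {metric}")
    if metric.endswith("_abs"):
        return 1.0 - abs(r)
    return 1.0 - r


def profile_distance(x: np.ndarray, y: np.ndarray, metric: str) -> float:
    """Distance between two profiles using only mutually observed entries.

    Returns ``nan`` when fewer than the minimum shared observations exist
    (2 for correlation metrics, 1 for euclidean/cityblock); callers decide
    the fallback.
    """
    if metric not in METRICS:
        raise ClusterkitError(f"unknown metric {metric!r}; choose from {METRICS}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    shared = ~np.isnan(x) & ~np.isnan(y)
    xs, ys = x[shared], y[shared]
    if metric == "euclidean":
        if xs.size < 1:
            return np.nan
        return float(np.sqrt(((xs - ys) ** 2).sum()))
    if metric == "cityblock":
        if xs.size < 1:
            return np.nan
        return float(np.abs(xs - ys).sum())
    if xs.size < 2:
        return np.nan
    return _corr_distance(xs, ys, metric)


def max_distance(metric: str) -> float | None:
    """Largest possible distance for bounded (correlation) metrics."""
    if metric in CORRELATION_METRICS:
        return 1.0 if metric.endswith("_abs") else 2.0
    return None


def compute_distance(matrix, metric: str = "euclidean", axis: str = "rows") -> DistanceMatrix:
    """Pairwise distances between rows (or columns) of a matrix.

    ``matrix`` is an :class:`AttributeMatrix` or a plain ndarray with NaN
    for missing values.  Each pair is computed over the columns observed
    in both profiles; pairs with too few shared observations get the
    metric's maximal distance (2 for correlation metrics, the largest
    finite distance in the matrix otherwise) with a logged warning.
    """
    if axis not in ("rows", "cols"):
        raise ClusterkitError("axis must be 'rows' or 'cols'")
    if isinstance(matrix, AttributeMatrix):
        V = matrix.values
        ids = list(matrix.row_ids) if axis == "rows" else list(matrix.col_ids)
    else:
        V = np.asarray(matrix, dtype=float)
        ids = [str(i) for i in range(V.shape[0] if axis == "rows" else V.shape[1])]
    if axis == "cols":
        V = V.T
    n = V.shape[0]
    D = np.zeros((n, n))
    short: list[tuple[int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            d = profile_distance(V[i], V[j], metric)
            if np.isnan(d):
                short.append((i, j))
            D[i, j] = D[j, i] = d
    if short:
        cap = max_distance(metric)
        if cap is None:
            finite = D[np.isfinite(D)]
            cap = float(finite.max()) if finite.size else 0.0
        for i, j in short:
            D[i, j] = D[j, i] = cap
        logger.warning(
            "%d pair(s) with too few shared observations set to maximal distance %g",
            len(short), cap,
        )
    return DistanceMatrix(ids=ids, d=D, metric=metric)
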