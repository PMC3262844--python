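# Methods

This note documents the models implemented in `clusterkit`, the
parameters that matter, the synthetic data the test-suite runs on, and
the numerical and design choices made where the design was genuinely
open.

## Data model and determinism

Networks are undirected, with at most one edge per unordered node pair
and no user-level self-loops. On ingest, duplicate pairs collapse to the
**maximum** weight and directed input is symmetrized the same way (both
logged); for similarity semantics the stronger observation is the
conservative one to keep. Node ids are opaque strings and every tie in
the package — merge order, cluster ordering, seed selection, attractor
assignment — is broken lexicographically on ids (for plain array inputs,
ids are zero-padded row indices, so ties follow input order). Cluster
assignments are canonically ordered by decreasing size, then smallest
member id. Missing values in attribute matrices are explicit (`NaN`);
rows with no observed value are excluded from clustering and reported in
the assignment's unassigned set rather than dropped silently.

## Preprocessing

* **Weight conversions** `none`, `neg_log10`, `log10`, `reciprocal`.
  `neg_log10` is base 10, the convention that maps a BLAST e-value of
  1e-6 to an additive similarity of 6. Non-positive inputs under the
  log modes are clamped to the smallest positive float and logged
  (opt-out raises instead).
* **Weight histogram**: equal-width bins over [min, max]; bins are
  right-inclusive so every weight lands in exactly one bin; a degenerate
  range (all weights equal) is widened by ±0.5.
* **Cutoff heuristic** (pluggable registry, default `smoothed_valley`):
  smooth the counts with a centered moving average of window 3
  (truncated at the boundaries), take the global maximum bin, and
  return the left edge of the first interior local minimum after it;
  with no interior valley (monotone histograms) fall back to the right
  edge of the bin where the cumulative count reaches 90%. At least 5
  bins are required. Edge cutoffs keep edges with weight ≥ cutoff.
* **Normalization** steps applied in caller order: `log2`,
  `median_center_rows/cols`, `ss1_rows/cols` (sum of squares scaled to
  1); medians and sums of squares ignore missing entries.
* **Distances** (rows or columns): euclidean, cityblock, and the
  correlation family pearson, pearson_abs, uncentered, uncentered_abs,
  spearman, kendall, each as 1 − r (or 1 − |r|). Pairs are computed over
  mutually observed columns only (Cluster 3.0 pairwise-complete
  semantics). Pairs with fewer than 2 shared observations get the
  metric's maximal distance — 2 (or 1 for the |r| variants) in the
  correlation family; for the unbounded metrics, the largest finite
  distance observed in the same matrix — with a logged warning. A
  zero-variance profile under pearson has r defined as 0 (distance 1).

## Network clustering

**MCL.** Column-stochastic matrix from adjacency plus self-loops;
default `loop_policy="max_incident"` gives each node a self-loop equal
to its largest incident weight (1 for isolated nodes), which damps
oscillation on bipartite-ish structure; `unit` loops are available. One
round = expansion (matrix squaring) then inflation (entrywise power
`inflation`, column renormalization), zeroing entries below
`pruning_threshold` (default 0) and renormalizing. Iteration stops when
the residual — the maximum over columns of the L1 change per round —
falls to `max_residual` (default 1e-6) or after `max_iterations`
(default 16) rounds. Clusters are read from attractors (positive
diagonal in the limit matrix, threshold `max(pruning_threshold, 1e-8)`);
attractor rows whose supports overlap merge, and each column joins the
attractor of largest limit value, ties to the smallest id, so the
output is always a partition even where vanilla MCL would emit overlaps.
A column left with no attractor support becomes a singleton. Defaults
`inflation=1.8` follow the protocol commonly used on purification-score
PPI networks. Inflation is a genuine granularity dial: on sparse
planted blocks (15 nodes, within-density 0.3) inflation 2.0
systematically fragments blocks that 1.8 recovers — verified against an
independent dense fixed-point implementation, so this is MCL behaviour,
not an implementation artifact.

**Affinity propagation.** Standard responsibility/availability message
passing with damping λ ∈ [0.5, 1) (default 0.9), diagonal preference
(default: median off-diagonal similarity), stopping when the exemplar
set is stable for `convergence_window` (20) rounds or after
`max_iterations` (500). Exactly symmetric inputs make the messages
oscillate, so a deterministic, vanishingly small perturbation
(ε·|S| scaled noise from a fixed-seed generator) is added; results are
therefore reproducible run to run. Non-exemplars join the exemplar of
maximal similarity, ties to the smallest id.

**MCODE.** Stage 1 weights each vertex by the density of the highest
k-core of its closed neighborhood times that core's k. Stage 2 grows a
complex from each highest-weight unseen vertex breadth-first (depth ≤
`max_depth`, default 100), admitting unseen neighbors with weight ≥
(1 − `vertex_weight_percentage`) × seed weight (default vwp 0.2).
Stage 3: `haircut` (default on) iteratively removes vertices with
complex-degree < 2; `fluff` (default off) adds neighbors whose closed
neighborhood density exceeds `fluff_density_cutoff` and may make
complexes overlap; complexes whose densest core is below `k_core`
(default 2) are dropped. Complexes are scored by density × size.
Weights are ignored (logged); nodes in no complex are unassigned.
Note: when all vertices share one core weight (e.g. two K4s joined by a
bridge), expansion legitimately crosses the bridge — the stages are
executed exactly as stated.

**Girvan–Newman.** Unweighted edge betweenness recomputed after every
removal (ties at the maximum, compared with a 1e-12 tolerance, go to the
lexicographically smallest edge); the component partition is recorded at
every distinct component count, and the recorded level maximizing
modularity Q on the original graph is returned. An edgeless graph is
all singletons with Q = 0.

**Transitivity clustering** (weighted cluster editing). Cost =
Σ |s(i,j) − t| over pairs whose co-membership disagrees with
sign(s(i,j) − t). Instances with n ≤ `exact_limit` (default 8, capped
at 10) are solved exactly by set-partition enumeration. Larger
instances use a deterministic local search: from each of two
initializations — single-linkage components above the threshold, and
all singletons — apply best-improvement moves (single-node relocation
including to a fresh singleton, or a two-cluster merge) until no move
lowers the cost, and keep the cheaper result. The merge move is
essential: from a giant connected component, single-node moves alone
cannot split balanced dense clusters, and from singletons they cannot
assemble them efficiently. The heuristic's cost is never below the
exact optimum (tested on random n ≤ 8 instances).

For recovering planted blocks from a 0/1 adjacency, the threshold is not
arbitrary: cluster editing with edge cost log(p_in/p_out) and non-edge
cost log((1−p_out)/(1−p_in)) is the profile-likelihood objective of the
stochastic block model, which on the 0/1 weight scale corresponds to
t* = ℓ₀/(ℓ₁+ℓ₀) with ℓ₁ = log(p_in/p_out), ℓ₀ = log((1−p_out)/(1−p_in)).
The benchmark runs use that value (≈ 0.0925 for p_in 0.3, p_out 0.01).
At larger, unprincipled thresholds (e.g. the midpoint of the two rates)
the editing optimum provably differs from the planted partition, so
failure to recover it there is a property of the objective, not of the
search.

**SCPS (spectral).** Degree-normalized similarity D^{−1/2} S D^{−1/2};
zero-degree nodes are split off as singletons first. With
`n_clusters="auto"`, k = 1 + the position of the largest gap in the
eigenvalue sequence after the trivial leading eigenvalue (all-equal
spectra, gap ≤ 1e-8, give k = 1). Nodes are embedded in the top-k
eigenvector space, row-normalized to unit length, and partitioned by
the package's own k-means with `kmeans_restarts` (10) seeded restarts.

## Attribute clustering

**Hierarchical.** Four linkages with Eisen/Cluster 3.0 conventions:
single/complete/average via Lance–Williams updates, pairwise centroid by
recomputing the centroid (per-column mean over members, missing
ignored) and measuring centroid-to-centroid distance in the chosen
metric — not the Lance–Williams median. Merge height = linkage
distance; the minimal pair wins, ties by the lexicographic pair of
smallest member ids. For reproducible tie-breaking across algebraically
equivalent evaluation orders, pair comparisons quantize distances at
1e-12 (recorded heights stay unrounded). Centroid linkage may invert
heights; inversions are logged and rendered as-is. The leaf order puts
the child containing the lexicographically smallest leaf on the left.
Tree cuts: by height (a merge above the cut, or resting on a removed
merge, dissolves) or by group count (undo the last merges in merge
order).

**k-means / k-medoid.** `n_init` (10) seeded restarts, each choosing k
distinct rows as initial centers from `default_rng([seed, restart])`;
Lloyd iterations (≤ `max_iterations`, 100) assign rows to the nearest
center under the chosen metric (ties to the lowest cluster index) and
update centers as per-column means over observed entries — arithmetic
means even under correlation metrics, matching Cluster 3.0. An empty
cluster is repaired by reseeding with the row farthest from its center.
The best restart by total within-cluster distance wins. k-medoid
restricts centers to actual rows, choosing the member minimizing the
summed within-cluster distance. The within-run objective is
non-increasing (tested).

**Silhouette and select_k.** s(i) = (b − a)/max(a, b); singleton
clusters and the degenerate a = b = 0 case score 0. `select_k` runs the
partitioner for each k in the inclusive range with the shared seed,
scores with the clustering metric's distance matrix (not a fixed
euclidean), and returns the argmax, ties to the smaller k.

## Result export

* Cluster networks keep exactly the intra-cluster edges; restoring
  inter-cluster edges labels them `inter`. The output edge set is
  always a subset of the input's.
* The nested group tree has one group per merge; group ids are
  `group-<smallest member>-<size>`, which is unique within a tree.
* Ensemble co-clustering runs any `(inputs, seed) -> assignment`
  callable with seeds `seed..seed+n_runs−1`; pair frequency = fraction
  of runs co-clustered; the consensus partition is the connected
  components of pairs with frequency > 0.5 (the natural majority rule;
  the display list may additionally be truncated to the `max_edges`
  highest-frequency pairs, ties lexicographic, without affecting the
  consensus).
* TreeView export writes CDT/GTR/ATR with `GENE<i>X`/`ARRY<j>X` leaf
  ids (indices in original matrix order) and `NODE<k>X` internal nodes
  in merge order. The score column is 1 − height for correlation-family
  metrics (TreeView expects correlation-like scores) and −height
  otherwise, flagged by a leading comment. Values are written with
  shortest round-trip `repr`, so reading the CDT back reproduces the
  matrix bit-exactly.
* Heat-map tables group rows by cluster (size order; input order within
  a cluster), emit separator indices, and map values to RGB on a
  symmetric scale where 0 is the mid color (yellow/cyan and red/green
  presets, custom anchor triples accepted; missing values render grey).

## Synthetic data

`planted_partition(block_sizes, p_in, p_out, ...)` draws each
intra-block pair with probability p_in and inter-block pair with p_out,
weights from optional distributions (default 1.0). It emulates the
modular structure of interaction networks but none of their degree
heterogeneity — real PPI networks are heavy-tailed, so recovery rates
here bound what block-structured data allows, not field performance.
`synthetic_expression` gives each block a random ±effect_size pattern
over arrays (patterns distinct across blocks), adds Gaussian noise,
masks entries at `missing_rate`, and median-centers rows, emulating
log-scale, centered microarray data; because patterns are drawn
randomly, two blocks can differ in as little as one array, so block
separability varies across seeds. `similarity_from_labels` produces a
symmetric block matrix with optional symmetric jitter as a stand-in for
all-versus-all sequence similarities. All generators are pure functions
of their arguments including the seed.

## Problem sizes and benchmarks

The test-suite and `scripts/acceptance.py` run at desk scale, chosen so
every quantity has an independent oracle: hierarchical clustering is
checked against a from-scratch O(n³) agglomeration on 50 random 8×3
matrices across all 4 linkages × 8 metrics; cluster editing against
exhaustive set-partition enumeration at n ≤ 8; modularity against the
direct formula over all recorded levels; exemplar selection against
brute-force subset search at n = 6; recovery benchmarks use 4 blocks of
15 nodes (p_in 0.3, p_out 0.01) and 60–80 gene expression matrices.
These sizes are the package's own benchmark design: small enough to
enumerate, large enough for the planted structure to dominate noise.

## Known limitations

* MCL granularity is data-dependent; there is no auto-selection of the
  inflation parameter.
* The transitivity-clustering local search is a heuristic above
  `exact_limit`; no optimality guarantee.
* The affinity-propagation preference is a scalar (no per-point
  preferences).
* SCPS's automatic k uses the largest eigengap; ratio-based criteria
  are not implemented.
* TreeView export targets the Cluster 3.0 dialect only; CDT reading of
  files from other producers is best-effort within that dialect.
* The CLI's network clusterers read edge lists only; matrix-shaped
  similarity input is a library-level feature.
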