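# Methods

## Problem

Two undirected networks with nonnegative edge weights are given: an
original network `X = (N_X, E_X)` and an augmented network `Y = (N_Y, E_Y)`
with `N_X ⊂ N_Y`. Edges among original nodes may appear or disappear
between `X` and `Y` (`E_X ⊆ E_Y` is *not* assumed). For every unordered
pair `(i, j)` of original nodes two quantities are compared:

- `d_X(i, j)` — the ordinary shortest-path length in `X` (∞ if
  disconnected), and
- the **constrained distance** — the minimum length of a *simple* path
  from `i` to `j` in `Y` that visits at least one added node
  `k ∈ N_Y \ N_X` (∞ if no such path exists).

The pair is labeled Breakthrough, Roadblock, Impasse, Detour, Equal or
Shortcut according to the status table in the README. Finding a shortest
simple path through a prescribed set of must-include nodes is NP-hard, and
even counting simple paths is #P-hard, so the per-pair constrained
distance is estimated heuristically; two exact engines serve as ground
truth.

## Heuristic strategies

All four strategies share Step 1–2 machinery: Dijkstra from each relevant
source over `Y`, retaining *all* tight predecessors (every neighbor `u` of
`v` with `d(u) + w(u,v) = d(v)`), which spans the DAG of all equal-length
shortest paths. Up to `MaxPathNumber` of these are enumerated
deterministically (depth-first, predecessors in sorted node-id order).
For each pair a candidate list `L_ij` of added nodes `k` is built: `k` must
be reachable from both endpoints with `d(i,k) ≤ MaxDistance` and
`d(j,k) ≤ MaxDistance`; candidates are sorted by
`min max(d(i,k), d(j,k))` (ordering strategy 1, the default) or
`min (d(i,k) + d(j,k))` (strategy 2), ties broken by the other strategy's
key and then by node id, and truncated to `MaxNode` entries.

**brides** (original). Step 3: if one of the enumerated shortest `i–j`
paths in `Y` contains an added node, classify from `(d_X, d_Y)` directly —
this catches Breakthroughs, Shortcuts, and Equal/Detour cases whose
witness is an unconstrained shortest path. Step 4: otherwise walk `L_ij`
in order; for each `k` try every pair of stored shortest `i→k` and `j→k`
paths and accept the first concatenation that is simple (length
`d(i,k) + d(j,k)`). If all stored pairs collide, delete all nodes of one
stored path except `k` from `Y`, recompute the opposite leg by Dijkstra in
the reduced network, and take the shorter of the two directions (the
rerouted leg cannot intersect the fixed leg, so the concatenation is
simple by construction). A direction is skipped when the reroute source
itself lies on the fixed path — deleting the source would make the
computation ill-posed. The first witness found classifies the pair;
exhausting `L_ij` without a witness yields Roadblock (`d_X` finite) or
Impasse (`d_X` infinite). Pairs disconnected in `Y` short-circuit to that
final rule, since no candidate could be reachable.

**brides_y**. Enumerate the `MaxPathNumber` shortest loopless `i–j` paths
with Yen's algorithm and classify from the first path containing an added
node. Because Yen enumerates in nondecreasing length order, that first
qualifying path *is* the exact constrained shortest path whenever it ranks
within the cap; the strategy errs only when more than `MaxPathNumber`
strictly shorter or equal-length paths avoid all added nodes — exactly the
regime of few, distant added nodes.

**brides_yc**. As `brides`, but Step 4 concatenates Yen-enumerated `i→k`
and `j→k` path lists (up to `MaxPathNumber` each), trying pairs in
nondecreasing combined length with ties by list rank, and performs no
rerouting. Unlike `brides_y`, every witness is guaranteed to contain the
added junction `k`, which restores accuracy when added nodes are rare.

**brides_ec**. As `brides`, but every candidate `k` is examined and the
minimum-length witness is kept before classifying. Witness lengths are
therefore never longer than those of `brides`; the label can differ when
the first-found witness and the shortest witness straddle `d_X`.

Heuristic witness lengths are upper bounds on the exact constrained
distance: a reported Detour length can exceed the best possible Detour.
The method estimates the *distribution of path types*, not exact lengths.

## Exact oracles

**DFS engine.** Branch-and-bound search over all simple paths. A partial
path at node `v` with accumulated length `ℓ` is pruned when
`ℓ + bound(v) ≥ incumbent`, where `bound` is the plain Dijkstra distance
`d_Y(v, j)` once an added node has been collected, and
`min_k (d(v,k) + d(k,j))` over added `k` otherwise — both admissible.
Exponential in the worst case; an instance-size guard (default 25 nodes)
prevents accidental use at scale.

**Flow engine.** Exact and polynomial. Any simple `i..k..j` path through a
fixed added node `k` decomposes at `k` into two internally vertex-disjoint
paths `k→i` and `k→j`, and conversely any such disjoint pair concatenates
into a simple path through `k`. The per-`k` optimum is therefore a
minimum-cost two-unit flow from `k` to a super-sink fed by `i` and `j` in
the node-split digraph (each node an `in→out` arc of capacity 1; `k` has
no `in` copy, so paths cannot revisit it; `i` and `j` feed the sink
directly, so neither can be an interior node). Minimizing over all added
`k` gives the exact constrained distance. Candidates are scanned in
increasing lower bound `d(i,k) + d(j,k)`: the scan stops once the bound
cannot beat the incumbent, and when the plain shortest `i→k` and `j→k`
paths are already internally disjoint the per-`k` optimum equals the bound
and no flow is run. The flow itself uses two successive-shortest-path
augmentations with SPFA (label-correcting Bellman–Ford), which tolerates
the negative residual costs that arise with real-valued weights; a
min-cost-flow routine requiring integral costs would not. The test suite
asserts exact agreement of the two engines on 200 seeded random instances.

## Numerical choices

- Path lengths are sums of `float` edge weights; unweighted input uses
  weight 1.0, so all arithmetic on hop counts is exact.
- Length equality (the Equal label, tight-predecessor membership in
  networkx, oracle cross-checks) uses a relative-and-absolute tolerance of
  1e-9 (`AlgoParams.length_tolerance`).
- All orderings that the underlying mathematics leaves free are fixed for
  reproducibility: predecessor traversal and candidate tie-breaks use
  string order of node ids; Yen concatenation pairs are tried in
  nondecreasing combined length with ties by list rank.
- Degenerate inputs: an empty added set classifies every pair Roadblock or
  Impasse (with a warning at validation); pairs disconnected in `Y` skip
  candidate search entirely.

## Synthetic benchmark

`brides.simulate` reproduces the validation protocol: random original
networks of 100 nodes, augmented with 5, 25, 50 or 100 added nodes, 100
sampled original pairs per network, heuristic labels scored against the
flow oracle. Because no generative recipe for *augmenting* a random graph
is canonical — growing a Watts–Strogatz ring node-by-node is ill-defined —
the generator builds the augmented network `Y` at full size, designates
added nodes uniformly at random, and takes `X` as the induced subgraph on
the rest. This guarantees `N_X ⊂ N_Y` and `E_X ⊆ E_Y`, matching how
similarity networks are rebuilt on enlarged datasets, and is identical
across models. Model parameters default to a mean degree of about 4:
Erdős–Rényi `p = 4/(n−1)`, Barabási–Albert `m = 2`, Watts–Strogatz `k = 4`
with rewiring probability 0.05. These densities are this package's own
choice; absolute accuracy values at few added nodes depend on them, so the
package asserts only the density-robust claims — exactness of `brides` and
`brides_ec`, 100% `brides_y` accuracy at 100 added nodes, accuracy
nondecreasing in the number of added nodes, and `brides_yc` at least as
accurate as `brides_y` when added nodes are few. Randomness flows from one
root seed through `numpy.random.SeedSequence` keyed by
(seed, replicate, purpose), so any replicate is reproducible alone.

Problem sizes used by the shipped runs: the acceptance script averages 50
replicates per model at 100 + 100 nodes; the test grid uses 8 replicates
per cell for the monotonicity check and 200 instances of at most 15 + 6
nodes for oracle equivalence. These sizes give sub-percent Monte-Carlo
error on the quantities asserted while keeping a full run in minutes.

What the synthetic generator does *not* emulate: weighted similarity
scores (all benchmark edges have weight 1), degree heterogeneity beyond
the three models, and the community structure of real genome networks.
Passing benchmarks demonstrate correctness of the path logic, not that any
particular biological dataset will show a particular BRIDES profile.

## Known limitations

- Undirected networks with nonnegative weights only; directed graphs and
  negative weights (which would require Bellman–Ford in place of Dijkstra)
  are out of scope.
- The DFS oracle is exponential and guarded; use the flow engine beyond
  ~25 nodes.
- `brides_y` is both the slowest and least accurate strategy when added
  nodes are few and far from the queried pair — its Yen scan can exhaust
  `MaxPathNumber` paths without meeting one.
- Witness lengths are upper bounds; do not interpret Detour magnitudes as
  exact detour costs.
- No parallel execution; the per-pair computations are independent and
  could be distributed by a caller if needed.
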