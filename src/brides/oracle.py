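"""Exact reference classifiers for the constrained-path problem.

The quantity the heuristics estimate is the *constrained distance*: the
minimum length of a simple path in the augmented network Y between two
original nodes that traverses at least one added node (inf when no such
path exists).  Two independent exact engines compute it:

``dfs``
    Brute-force branch-and-bound depth-first search over simple paths.
    Exponential; guarded by a node-count limit.  Serves as the ground-truth
    engine at desk scale.

``flow``
    Polynomial engine.  A simple i..k..j path through a fixed added node k
    splits into two internally vertex-disjoint paths k->i and k->j, so the
    per-k optimum is the minimum-cost two-unit flow from k to {i, j} in the
    node-split digraph (each node capacity 1).  Minimizing over added k
    gives the exact constrained distance: while the shortest simple path
    through an ordered *set* of must-include nodes is NP-hard, a single
    must-include node reduces to the vertex-disjoint path pair.

Both engines agree exactly on every input; the test suite asserts this on
seeded random instances.
"""

from __future__ import annotations

import math
from collections import deque
from heapq import heappop, heappush

import networkx as nx

from .netio import AugmentedPair
from .classify import BridesResult, PairRecord, classify_statuses
from .paths import INF

__all__ = [
    "dfs_constrained_distance",
    "flow_constrained_distance",
    "oracle_classify",
]


def dfs_constrained_distance(
    Y: nx.Graph, i, j, added, node_limit: int = 25
) -> float:
    """Exact constrained distance by exhaustive simple-path search.

    Branch-and-bound: a partial path at node v is pruned when its length
    plus an admissible lower bound on the remaining distance (the plain
    shortest v->j distance once an added node has been collected, else the
    best v->k->j detour over all added k) cannot beat the incumbent.

    ``node_limit`` guards against accidentally running the exponential
    search on large instances.
    """
    n = Y.number_of_nodes()
    if n > node_limit:
        raise ValueError(
            f"instance has {n} nodes, above the DFS guard of {node_limit}; "
            "use flow_constrained_distance for larger networks"
        )
    added = set(added)
    if i not in Y or j not in Y:
        raise nx.NodeNotFound(f"{i!r} or {j!r} not in network")
    if not added:
        return INF
    dist_j = nx.single_source_dijkstra_path_length(Y, j, weight="weight")
    # admissible bound when no added node collected yet: min_k d(v,k)+d(k,j)
    via_added: dict = {}
    for k in added:
        dk = nx.single_source_dijkstra_path_length(Y, k, weight="weight")
        dkj = dk.get(j, INF)
        if math.isinf(dkj):
            continue
        for v, d in dk.items():
            cand = d + dkj
            if cand < via_added.get(v, INF):
                via_added[v] = cand
    if not via_added:
        return INF

    nbrs = {
        v: sorted(
            ((u, d.get("weight", 1.0)) for u, d in Y[v].items()),
            key=lambda t: dist_j.get(t[0], INF),
        )
        for v in Y
    }
    best = INF
    visited = {i}

    def rec(v, length: float, has_added: bool):
        nonlocal best
        if v == j:
            if has_added and length < best:
                best = length
            return
        for u, w in nbrs[v]:
            if u in visited:
                continue
            nl = length + w
            ha = has_added or u in added
            bound = nl + (dist_j.get(u, INF) if ha else via_added.get(u, INF))
            if bound >= best or math.isinf(bound):
                continue
            visited.add(u)
            rec(u, nl, ha)
            visited.discard(u)

    rec(i, 0.0, i in added)
    return best


def _min_two_disjoint(Y: nx.Graph, k, i, j) -> float:
    """Minimum total length of internally vertex-disjoint paths k->i and k->j.

    Min-cost two-unit flow on the node-split digraph: every node except i, j
    and k becomes an in->out arc of capacity 1; i and j feed a common sink;
    k is the source (with no in-copy, so paths cannot revisit it).
    Successive shortest paths with SPFA handle the negative residual costs
    that arise with real-valued weights.
    """
    idx: dict = {}
    adj: list[list[int]] = []
    arcs: list[list] = []  # [head, residual capacity, cost]

    def nid(x) -> int:
        if x not in idx:
            idx[x] = len(adj)
            adj.append([])
        return idx[x]

    def add(u: int, v: int, cap: int, cost: float) -> None:
        adj[u].append(len(arcs))
        arcs.append([v, cap, cost])
        adj[v].append(len(arcs))
        arcs.append([u, 0, -cost])

    T = nid("sink")
    for v in Y.nodes:
        if v in (i, j, k):
            continue
        add(nid(("in", v)), nid(("out", v)), 1, 0.0)
    add(nid(("in", i)), T, 1, 0.0)
    add(nid(("in", j)), T, 1, 0.0)
    S = nid(("out", k))
    for u, v, data in Y.edges(data=True):
        w = data.get("weight", 1.0)
        for a, b in ((u, v), (v, u)):
            if a in (i, j) or b == k:
                continue
            add(nid(("out", a)), nid(("in", b)), 1, w)

    n = len(adj)
    total = 0.0
    for _ in range(2):
        dist = [INF] * n
        prev_arc = [-1] * n
        dist[S] = 0.0
        queue = deque([S])
        in_queue = [False] * n
        in_queue[S] = True
        while queue:
            u = queue.popleft()
            in_queue[u] = False
            for ai in adj[u]:
                head, cap, cost = arcs[ai]
                if cap <= 0:
                    continue
                nd = dist[u] + cost
                if nd < dist[head] - 1e-12:
                    dist[head] = nd
                    prev_arc[head] = ai
                    if not in_queue[head]:
                        queue.append(head)
                        in_queue[head] = True
        if math.isinf(dist[T]):
            return INF
        v = T
        while v != S:
            ai = prev_arc[v]
            arcs[ai][1] -= 1
            arcs[ai ^ 1][1] += 1
            total += arcs[ai][2]
            v = arcs[ai ^ 1][0]
    return total


def flow_constrained_distance(
    Y: nx.Graph,
    i,
    j,
    added,
    dist_i: dict | None = None,
    dist_j: dict | None = None,
) -> float:
    """Exact constrained distance in polynomial time.

    Candidates k are visited in increasing lower bound d(i,k) + d(j,k); the
    scan stops as soon as the bound cannot beat the incumbent.  When the
    plain shortest i->k and j->k paths are already internally disjoint the
    per-k optimum equals the bound and no flow is run.

    Precomputed Dijkstra maps from i and j may be supplied for reuse.
    """
    if i not in Y or j not in Y:
        raise nx.NodeNotFound(f"{i!r} or {j!r} not in network")
    added = set(added) - {i, j}
    if not added:
        return INF
    if dist_i is None:
        dist_i = nx.single_source_dijkstra_path_length(Y, i, weight="weight")
    if dist_j is None:
        dist_j = nx.single_source_dijkstra_path_length(Y, j, weight="weight")
    heap = []
    for k in added:
        dik = dist_i.get(k, INF)
        djk = dist_j.get(k, INF)
        if math.isinf(dik) or math.isinf(djk):
            continue
        heappush(heap, (dik + djk, str(k), k))
    best = INF
    while heap:
        lb, _, k = heappop(heap)
        if lb >= best:
            break
        p = nx.dijkstra_path(Y, i, k, weight="weight")
        q = nx.dijkstra_path(Y, j, k, weight="weight")
        if set(p) & set(q) == {k}:
            best = lb  # disjoint shortest pair attains the lower bound
            continue
        cost = _min_two_disjoint(Y, k, i, j)
        if cost < best:
            best = cost
    return best


def oracle_classify(
    ap: AugmentedPair,
    engine: str = "flow",
    pairs=None,
    tol: float = 1e-9,
    node_limit: int = 25,
) -> BridesResult:
    """Exact six-way classification of original pairs.

    ``engine`` selects the exact constrained-distance computation: ``"dfs"``
    (brute force, small instances only) or ``"flow"`` (polynomial).
    """
    if engine not in ("dfs", "flow"):
        raise ValueError(f"unknown oracle engine {engine!r}")
    X, Y, added = ap.original, ap.augmented, ap.added
    if pairs is None:
        pairs = list(ap.original_pairs())
    dx_cache: dict = {}
    dy_cache: dict = {}

    def dx(s):
        if s not in dx_cache:
            dx_cache[s] = nx.single_source_dijkstra_path_length(X, s, weight="weight")
        return dx_cache[s]

    def dy(s):
        if s not in dy_cache:
            dy_cache[s] = nx.single_source_dijkstra_path_length(Y, s, weight="weight")
        return dy_cache[s]

    records = []
    for i, j in pairs:
        d_x = dx(i).get(j, INF)
        if engine == "dfs":
            d_c = dfs_constrained_distance(Y, i, j, added, node_limit=node_limit)
        else:
            d_c = flow_constrained_distance(Y, i, j, added, dy(i), dy(j))
        records.append(
            PairRecord((i, j), d_x, d_c, classify_statuses(d_x, d_c, tol))
        )
    return BridesResult.from_records(records)
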