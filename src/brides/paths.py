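"""Shortest-path primitives.

Everything the classification heuristics need: single-source Dijkstra with
the full tight-predecessor structure, deterministic enumeration of the
equal-length shortest simple paths, Yen's k-shortest loopless paths, path
concatenation at a junction node, and "delete-and-reroute" recomputation.

Path lengths are sums of edge weights (hop counts when every weight is 1).
All operations return only simple (loopless) paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import islice

import networkx as nx

from .netio import node_key

__all__ = [
    "Path",
    "PathSet",
    "dijkstra_sssp",
    "enumerate_shortest_paths",
    "yen_k_shortest",
    "concatenate",
    "remove_and_reroute",
    "path_length",
]

INF = math.inf


@dataclass(frozen=True)
class Path:
    """An ordered node sequence with its total weighted length."""

    nodes: tuple
    length: float

    @property
    def source(self):
        return self.nodes[0]

    @property
    def target(self):
        return self.nodes[-1]

    def is_simple(self) -> bool:
        return len(set(self.nodes)) == len(self.nodes)

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class PathSet:
    """Paths sharing both endpoints; ``truncated`` marks a hit enumeration cap."""

    source: object
    target: object
    paths: list[Path] = field(default_factory=list)
    truncated: bool = False

    def __iter__(self):
        return iter(self.paths)

    def __len__(self) -> int:
        return len(self.paths)

    def __bool__(self) -> bool:
        return bool(self.paths)


def path_length(net: nx.Graph, nodes) -> float:
    """Sum of edge weights along a node sequence of ``net``."""
    return sum(net[u][v].get("weight", 1.0) for u, v in zip(nodes, nodes[1:]))


def dijkstra_sssp(net: nx.Graph, source) -> tuple[dict, dict]:
    """Shortest-path distances and ALL tight predecessors from ``source``.

    Returns ``(dist, preds)`` where ``preds[v]`` lists every neighbor u with
    d(u) + w(u,v) = d(v) (the shortest-path DAG needed to enumerate all
    equal-length shortest paths).  Unreachable nodes are absent from both
    maps.  Nonnegative weights are assumed.
    """
    if source not in net:
        raise nx.NodeNotFound(f"source {source!r} not in network")
    preds, dist = nx.dijkstra_predecessor_and_distance(net, source, weight="weight")
    return dist, preds


def _paths_from_preds(preds: dict, source, target, cap: int) -> tuple[list[tuple], bool]:
    """Depth-first walk of the tight-predecessor DAG, predecessors in sorted
    node-id order; stops after finding cap+1 paths (to set the truncated flag)."""
    out: list[tuple] = []
    stack: list[object] = [target]

    def rec(v):
        if len(out) > cap:
            return
        if v == source:
            out.append(tuple(reversed(stack)))
            return
        for u in sorted(preds.get(v, ()), key=node_key):
            stack.append(u)
            rec(u)
            stack.pop()
            if len(out) > cap:
                return

    rec(target)
    truncated = len(out) > cap
    return out[:cap], truncated


def enumerate_shortest_paths(net: nx.Graph, i, j, cap: int = 100) -> PathSet:
    """Up to ``cap`` distinct simple shortest paths from i to j.

    All returned paths have exactly minimal length; the enumeration order is
    deterministic (depth-first over the tight-predecessor DAG, predecessors
    visited in sorted node-id order).  Empty set when i and j are
    disconnected.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    for v in (i, j):
        if v not in net:
            raise nx.NodeNotFound(f"node {v!r} not in network")
    dist, preds = dijkstra_sssp(net, i)
    if j not in dist:
        return PathSet(i, j)
    d = dist[j]
    seqs, truncated = _paths_from_preds(preds, i, j, cap)
    return PathSet(i, j, [Path(s, d) for s in seqs], truncated)


def yen_k_shortest(net: nx.Graph, i, j, K: int = 100) -> PathSet:
    """The K shortest loopless paths from i to j (Yen's algorithm).

    Paths come in nondecreasing length order; the first one is a shortest
    path.  Fewer than K are returned when fewer loopless paths exist.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    for v in (i, j):
        if v not in net:
            raise nx.NodeNotFound(f"node {v!r} not in network")
    try:
        gen = nx.shortest_simple_paths(net, i, j, weight="weight")
        seqs = list(islice(gen, K + 1))
    except nx.NetworkXNoPath:
        return PathSet(i, j)
    truncated = len(seqs) > K
    seqs = seqs[:K]
    return PathSet(
        i, j, [Path(tuple(s), path_length(net, s)) for s in seqs], truncated
    )


def concatenate(p_ik: Path, p_jk: Path) -> Path | None:
    """Join i->..->k and j->..->k into the simple path i->..->k->..->j.

    Both inputs must terminate at the same junction node k.  Returns None
    when the paths share any node besides k (the concatenation would not be
    simple); the length of a successful join is the sum of the two lengths.
    """
    k = p_ik.target
    if p_jk.target != k:
        raise ValueError(
            f"junction mismatch: paths end at {p_ik.target!r} and {p_jk.target!r}"
        )
    if set(p_ik.nodes) & set(p_jk.nodes) != {k}:
        return None
    nodes = p_ik.nodes + tuple(reversed(p_jk.nodes[:-1]))
    return Path(nodes, p_ik.length + p_jk.length)


def remove_and_reroute(net: nx.Graph, fixed: Path, j, k) -> Path | None:
    """Shortest j->k path in ``net`` with every node of ``fixed`` except k removed.

    ``fixed`` must terminate at k and must not contain j.  Any returned path
    is therefore internally disjoint from ``fixed``, so concatenating the two
    at k always yields a simple path.  Returns None when the reduced network
    disconnects j from k.
    """
    if fixed.target != k:
        raise ValueError("fixed path must terminate at the junction node k")
    if j in fixed.nodes:
        raise ValueError(f"reroute source {j!r} lies on the fixed path")
    banned = set(fixed.nodes) - {k}
    view = nx.restricted_view(net, banned, [])
    try:
        length, nodes = nx.single_source_dijkstra(view, j, target=k, weight="weight")
    except nx.NetworkXNoPath:
        return None
    return Path(tuple(nodes), length)
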