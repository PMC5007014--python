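"""Reading, writing and validation of networks and original/augmented pairs.

Networks are undirected graphs with nonnegative edge weights, held in
:class:`networkx.Graph` objects whose edges always carry a ``weight``
attribute (1.0 for unweighted input).  Node identifiers are arbitrary
non-whitespace strings when read from disk; in-memory graphs may use any
hashable identifiers.

The on-disk dialect is a tab/whitespace-separated edge list::

    # comment
    u	v        -> edge (u, v) of weight 1
    u	v	w    -> edge of weight w (only when weighted=True)
    u            -> declares the isolated node u

Isolated nodes must be representable because they generate Impasses in the
path classification.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path as FilePath
from typing import IO, Iterable, Iterator

import networkx as nx

__all__ = [
    "EdgeListError",
    "ValidationError",
    "AugmentationWarning",
    "AugmentedPair",
    "NetworkStats",
    "read_edge_list",
    "write_edge_list",
    "validate_augmentation",
    "network_stats",
    "node_key",
]


class EdgeListError(ValueError):
    """Malformed edge-list input (carries a line number in the message)."""


class ValidationError(ValueError):
    """Structurally invalid network or network pair."""


class AugmentationWarning(UserWarning):
    """Suspicious but legal original/augmented pair (empty added set, lost edges)."""


def node_key(v) -> str:
    """Canonical sort key for node identifiers (string order, type-agnostic)."""
    return str(v)


@dataclass(frozen=True)
class AugmentedPair:
    """A validated (X, Y) bundle: original network, augmented network, added nodes.

    ``added`` is exactly ``set(Y) - set(X)``.  Edges of X need not persist in
    Y: similarity networks rebuilt on a larger dataset can lose edges among
    the original nodes.
    """

    original: nx.Graph
    augmented: nx.Graph
    added: frozenset = field(default_factory=frozenset)

    def original_pairs(self) -> Iterator[tuple]:
        """All unordered pairs of original nodes, in deterministic order."""
        return combinations(sorted(self.original.nodes, key=node_key), 2)

    @property
    def n_pairs(self) -> int:
        n = self.original.number_of_nodes()
        return n * (n - 1) // 2


@dataclass(frozen=True)
class NetworkStats:
    n_nodes: int
    n_edges: int
    average_degree: float
    average_path_length: float
    clustering_coefficient: float


def _open_maybe(source) -> tuple[IO[str], bool]:
    if isinstance(source, (str, FilePath)):
        return open(source, "r", encoding="utf-8"), True
    return source, False


def read_edge_list(source, weighted: bool = False) -> nx.Graph:
    """Parse an edge list into an undirected weighted graph.

    Parameters
    ----------
    source
        File path or open text stream.
    weighted
        When true, a third column holds the nonnegative edge weight;
        otherwise every edge has weight 1 and a third column is an error.

    Raises
    ------
    EdgeListError
        Malformed line (wrong column count, self-loop syntax aside).
    ValidationError
        Negative/non-numeric weight, self-loop, or duplicate edge lines
        with conflicting weights.
    """
    fh, close = _open_maybe(source)
    net = nx.Graph()
    try:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) == 1:
                net.add_node(fields[0])
                continue
            if len(fields) == 2:
                u, v = fields
                w = 1.0
            elif len(fields) == 3 and weighted:
                u, v, ws = fields
                try:
                    w = float(ws)
                except ValueError:
                    raise ValidationError(
                        f"line {lineno}: non-numeric weight {ws!r}"
                    ) from None
                if math.isnan(w):
                    raise ValidationError(f"line {lineno}: NaN weight")
            else:
                raise EdgeListError(
                    f"line {lineno}: expected 1-{3 if weighted else 2} fields, "
                    f"got {len(fields)}: {line!r}"
                )
            if w < 0:
                raise ValidationError(f"line {lineno}: negative weight {w}")
            if u == v:
                raise ValidationError(f"line {lineno}: self-loop on node {u!r}")
            if net.has_edge(u, v):
                old = net[u][v]["weight"]
                if old != w:
                    raise ValidationError(
                        f"line {lineno}: duplicate edge {u!r}-{v!r} with "
                        f"conflicting weights {old} and {w}"
                    )
                continue
            net.add_edge(u, v, weight=w)
    finally:
        if close:
            fh.close()
    return net


def write_edge_list(net: nx.Graph, target, weighted: bool | None = None) -> None:
    """Write a graph in the dialect of :func:`read_edge_list`.

    ``weighted=None`` auto-detects: weights are emitted iff any differs from 1.
    """
    if weighted is None:
        weighted = any(d.get("weight", 1.0) != 1.0 for _, _, d in net.edges(data=True))
    fh, close = (open(target, "w", encoding="utf-8"), True) if isinstance(
        target, (str, FilePath)
    ) else (target, False)
    try:
        covered = set()
        for u, v in sorted(
            (tuple(sorted(e, key=node_key)) for e in net.edges), key=lambda e: (node_key(e[0]), node_key(e[1]))
        ):
            covered.update((u, v))
            w = net[u][v].get("weight", 1.0)
            if weighted:
                fh.write(f"{u}\t{v}\t{w:g}\n")
            else:
                fh.write(f"{u}\t{v}\n")
        for v in sorted(set(net.nodes) - covered, key=node_key):
            fh.write(f"{v}\n")
    finally:
        if close:
            fh.close()


def validate_augmentation(X: nx.Graph, Y: nx.Graph) -> AugmentedPair:
    """Check that Y augments X (every node of X present in Y) and bundle them.

    Emits :class:`AugmentationWarning` when the added set is empty or when X
    has edges absent from Y (legal: edge sets need not be nested).

    Raises
    ------
    ValidationError
        Some node of X is missing from Y.
    """
    missing = sorted(set(X.nodes) - set(Y.nodes), key=node_key)
    if missing:
        raise ValidationError(
            "original-network nodes absent from augmented network: "
            + ", ".join(map(str, missing))
        )
    added = frozenset(set(Y.nodes) - set(X.nodes))
    if not added:
        warnings.warn("augmented network adds no nodes", AugmentationWarning, stacklevel=2)
    lost = [e for e in X.edges if not Y.has_edge(*e)]
    if lost:
        warnings.warn(
            f"{len(lost)} edge(s) of the original network are absent from the "
            "augmented network",
            AugmentationWarning,
            stacklevel=2,
        )
    return AugmentedPair(original=X, augmented=Y, added=added)


def _is_unweighted(net: nx.Graph) -> bool:
    return all(d.get("weight", 1.0) == 1.0 for _, _, d in net.edges(data=True))


def network_stats(net: nx.Graph) -> NetworkStats:
    """Summary statistics: size, average degree, path length, clustering.

    Average path length is the mean shortest-path length over *connected*
    pairs only (hop count for unweighted input, weighted distance otherwise),
    which stays finite on disconnected similarity networks.  Clustering is
    the mean local clustering coefficient with degree<2 nodes contributing 0.
    """
    n = net.number_of_nodes()
    m = net.number_of_edges()
    avg_degree = 2.0 * m / n if n else 0.0
    total = 0.0
    npairs = 0
    if n:
        if _is_unweighted(net):
            sp_iter: Iterable = nx.all_pairs_shortest_path_length(net)
        else:
            sp_iter = nx.all_pairs_dijkstra_path_length(net, weight="weight")
        for src, dists in sp_iter:
            for dst, d in dists.items():
                if dst != src:
                    total += d
                    npairs += 1
    apl = total / npairs if npairs else 0.0  # each connected pair counted twice; ratio unchanged
    clustering = nx.average_clustering(net) if n else 0.0
    return NetworkStats(
        n_nodes=n,
        n_edges=m,
        average_degree=avg_degree,
        average_path_length=apl,
        clustering_coefficient=clustering,
    )
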