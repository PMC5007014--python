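"""Six-way classification of original-node pairs in an evolving network.

Given an original network X and an augmented network Y (all nodes of X plus
a set of *added* nodes), every unordered pair (i, j) of original nodes is
labeled by comparing the shortest-path status in X with the status of the
shortest simple path in Y that is forced to traverse at least one added
node:

==============  =============================  ============================
label           simple path i..j in X          constrained simple path in Y
==============  =============================  ============================
Breakthrough    impossible                     possible
Roadblock       possible                       impossible
Impasse         impossible                     impossible
Detour          shorter                        longer
Equal           equal length                   equal length
Shortcut        longer                         shorter
==============  =============================  ============================

Finding the exact constrained distance is hard in general (the must-include
shortest simple path problem is NP-hard for node *sets*), so four heuristic
strategies estimate it:

``brides``
    The original strategy.  If one of the enumerated shortest i-j paths in Y
    already contains an added node, classify directly.  Otherwise walk a
    candidate list of added nodes k ordered by closeness to the pair and try
    to stitch a simple i->k->j path out of stored shortest i->k and j->k
    paths, rerouting around overlaps through a node-deleted copy of Y when
    the stored paths collide.  The first witness found wins.
``brides_y``
    Scan Yen's k-shortest loopless i-j paths in order and use the first one
    containing an added node (exact whenever that path ranks within
    ``max_path_number``).
``brides_yc``
    Like ``brides`` but concatenates Yen-enumerated i->k and j->k path lists
    (pairs tried in nondecreasing combined length) and never reroutes.
``brides_ec``
    Exhaustive concatenation: like ``brides`` but examines every candidate k
    and keeps the shortest witness.

Heuristic witness lengths are upper bounds on the exact constrained
distance; see :mod:`brides.oracle` for exact references.
"""

from __future__ import annotations

import enum
import heapq
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import networkx as nx

from .netio import AugmentedPair, node_key
from .paths import INF, Path, path_length, remove_and_reroute

__all__ = [
    "PathClass",
    "AlgoParams",
    "CandidateList",
    "PairRecord",
    "BridesResult",
    "classify_statuses",
    "build_candidate_list",
    "brides",
    "brides_y",
    "brides_yc",
    "brides_ec",
    "STRATEGIES",
]


class PathClass(enum.Enum):
    """The six path types, with their canonical single-letter codes."""

    BREAKTHROUGH = "B"
    ROADBLOCK = "R"
    IMPASSE = "I"
    DETOUR = "D"
    EQUAL = "E"
    SHORTCUT = "S"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name.capitalize()


#: canonical output order
CLASS_ORDER = (
    PathClass.BREAKTHROUGH,
    PathClass.ROADBLOCK,
    PathClass.IMPASSE,
    PathClass.DETOUR,
    PathClass.EQUAL,
    PathClass.SHORTCUT,
)


@dataclass(frozen=True)
class AlgoParams:
    """Tunable algorithm parameters.

    The defaults (100/100/100) are the program defaults for MaxPathNumber,
    MaxDistance and MaxNode.  In unweighted networks ``max_distance`` bounds
    the number of edges between an original and an added node; for weighted
    networks it is on the scale of the edge weights and should be set by the
    user.  ``ordering_strategy`` 1 sorts candidate added nodes k by
    min Max(d(i,k), d(j,k)); strategy 2 by min (d(i,k) + d(j,k)).
    """

    max_path_number: int = 100
    max_distance: float = 100.0
    max_node: int = 100
    ordering_strategy: int = 1
    length_tolerance: float = 1e-9

    def __post_init__(self):
        if self.max_path_number < 1 or self.max_node < 1:
            raise ValueError("max_path_number and max_node must be >= 1")
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")
        if self.ordering_strategy not in (1, 2):
            raise ValueError("ordering_strategy must be 1 or 2")
        if self.length_tolerance < 0:
            raise ValueError("length_tolerance must be nonnegative")


@dataclass(frozen=True)
class CandidateList:
    """Ordered candidate added nodes k for one pair: (k, d(i,k), d(j,k))."""

    pair: tuple
    candidates: tuple = ()

    def __iter__(self):
        return iter(self.candidates)

    def __len__(self) -> int:
        return len(self.candidates)


@dataclass(frozen=True)
class PairRecord:
    """Outcome for one original pair.

    ``d_y_constrained`` is the length of the witnessing constrained path in
    Y found by the heuristic (an upper bound on the exact constrained
    distance), or inf when no witness was found.
    """

    pair: tuple
    d_x: float
    d_y_constrained: float
    label: PathClass
    witness: Path | None = None


@dataclass
class BridesResult:
    """Per-pair records plus the aggregate six-way counts."""

    records: list[PairRecord] = field(default_factory=list)
    counts: Counter = field(default_factory=Counter)

    @classmethod
    def from_records(cls, records: list[PairRecord]) -> "BridesResult":
        return cls(records, Counter(r.label for r in records))

    def summary(self) -> str:
        """Counts in canonical order, e.g. ``B=1 R=1 I=20 D=4 E=1 S=1``."""
        return " ".join(f"{c.value}={self.counts.get(c, 0)}" for c in CLASS_ORDER)

    def counts_row(self) -> tuple[int, ...]:
        return tuple(self.counts.get(c, 0) for c in CLASS_ORDER)

    def to_tsv(self) -> str:
        """Per-pair table: i, j, d_x, d_y_constrained, label, witness."""
        def fmt(d: float) -> str:
            return "inf" if math.isinf(d) else f"{d:g}"

        lines = ["i\tj\td_x\td_y_constrained\tlabel\twitness"]
        for r in self.records:
            wit = "-".join(map(str, r.witness.nodes)) if r.witness else ""
            lines.append(
                f"{r.pair[0]}\t{r.pair[1]}\t{fmt(r.d_x)}\t"
                f"{fmt(r.d_y_constrained)}\t{r.label.name}\t{wit}"
            )
        return "\n".join(lines) + "\n"


def classify_statuses(d_x: float, d_y: float, tol: float = 1e-9) -> PathClass:
    """Map the (X, constrained-Y) distance statuses to one of the six labels.

    ``inf`` encodes "no such simple path".  Finite lengths equal within the
    relative tolerance ``tol`` are classified Equal.
    """
    ix, iy = math.isinf(d_x), math.isinf(d_y)
    if ix and iy:
        return PathClass.IMPASSE
    if ix:
        return PathClass.BREAKTHROUGH
    if iy:
        return PathClass.ROADBLOCK
    if math.isclose(d_x, d_y, rel_tol=tol, abs_tol=tol):
        return PathClass.EQUAL
    return PathClass.DETOUR if d_x < d_y else PathClass.SHORTCUT


def build_candidate_list(
    pair: tuple,
    ap: AugmentedPair,
    dist_i: dict,
    dist_j: dict,
    params: AlgoParams,
) -> CandidateList:
    """Filter and order the added nodes k usable as junctions for one pair.

    Keeps k reachable from both endpoints with d(i,k) and d(j,k) at most
    ``max_distance``, sorts by the active strategy key (ties broken by the
    other strategy's key, then node id), and truncates to ``max_node``.
    """
    entries = []
    for k in ap.added:
        dik = dist_i.get(k, INF)
        djk = dist_j.get(k, INF)
        if math.isinf(dik) or math.isinf(djk):
            continue
        if dik > params.max_distance or djk > params.max_distance:
            continue
        entries.append((k, dik, djk))
    if params.ordering_strategy == 1:
        key = lambda e: (max(e[1], e[2]), e[1] + e[2], node_key(e[0]))
    else:
        key = lambda e: (e[1] + e[2], max(e[1], e[2]), node_key(e[0]))
    entries.sort(key=key)
    return CandidateList(pair, tuple(entries[: params.max_node]))


class _Runner:
    """Shared per-run state: distance/predecessor caches over X and Y."""

    def __init__(self, ap: AugmentedPair, params: AlgoParams):
        self.ap = ap
        self.params = params
        self.X = ap.original
        self.Y = ap.augmented
        self.added = ap.added
        self._dx: dict = {}
        self._dy: dict = {}

    def dist_x(self, source) -> dict:
        if source not in self._dx:
            self._dx[source] = nx.single_source_dijkstra_path_length(
                self.X, source, weight="weight"
            )
        return self._dx[source]

    def dijkstra_y(self, source) -> tuple[dict, dict]:
        if source not in self._dy:
            preds, dist = nx.dijkstra_predecessor_and_distance(
                self.Y, source, weight="weight"
            )
            self._dy[source] = (dist, preds)
        return self._dy[source]

    def shortest_path_sets(self, source, target, cap: int) -> list[Path]:
        """Up to cap equal-length shortest simple paths, deterministic order."""
        dist, preds = self.dijkstra_y(source)
        if target not in dist:
            return []
        from .paths import _paths_from_preds

        seqs, _ = _paths_from_preds(preds, source, target, cap)
        return [Path(s, dist[target]) for s in seqs]

    def contains_added(self, nodes: Iterable) -> bool:
        return any(v in self.added for v in nodes)


def _iter_pairs(ap: AugmentedPair, pairs) -> Sequence[tuple]:
    if pairs is None:
        return list(ap.original_pairs())
    return [tuple(p) for p in pairs]


def _run(ap, params, pairs, pair_fn: Callable) -> BridesResult:
    params = params or AlgoParams()
    runner = _Runner(ap, params)
    records = []
    for i, j in _iter_pairs(ap, pairs):
        d_x = runner.dist_x(i).get(j, INF)
        records.append(pair_fn(runner, i, j, d_x))
    return BridesResult.from_records(records)


def _record(i, j, d_x, d_y, tol, witness=None) -> PairRecord:
    return PairRecord((i, j), d_x, d_y, classify_statuses(d_x, d_y, tol), witness)


def _step3_witness(runner: _Runner, i, j) -> tuple[Path | None, float]:
    """Scan the enumerated shortest i-j paths in Y for one with an added node.

    Returns (witness or None, d_Y unconstrained).  d_Y is inf when i and j
    are disconnected in Y.
    """
    dist_i, _ = runner.dijkstra_y(i)
    d_y = dist_i.get(j, INF)
    if math.isinf(d_y):
        return None, INF
    for p in runner.shortest_path_sets(i, j, runner.params.max_path_number):
        if runner.contains_added(p.nodes):
            return p, d_y
    return None, d_y


def _witness_via_k(runner: _Runner, i, j, k, reroute: bool) -> Path | None:
    """Step 4 for one candidate k: simple concatenation, else delete-and-reroute."""
    cap = runner.params.max_path_number
    p_ik = runner.shortest_path_sets(i, k, cap)
    p_jk = runner.shortest_path_sets(j, k, cap)
    if not p_ik or not p_jk:
        return None
    from .paths import concatenate

    for p in p_ik:
        for q in p_jk:
            c = concatenate(p, q)
            if c is not None:
                return c
    if not reroute:
        return None
    # Step 4.2: delete the nodes of one stored path (except k) and reroute the
    # opposite endpoint; try both directions, keep the shortest concatenation.
    best: Path | None = None
    for fixed, other in ((p_ik[0], j), (p_jk[0], i)):
        if other in fixed.nodes:
            continue  # deleting the reroute source would be ill-posed
        r = remove_and_reroute(runner.Y, fixed, other, k)
        if r is None:
            continue
        c = concatenate(fixed, r) if other == j else concatenate(r, fixed)
        if c is not None and (best is None or c.length < best.length):
            best = c
    return best


def _pair_brides(runner: _Runner, i, j, d_x, exhaustive: bool = False) -> PairRecord:
    tol = runner.params.length_tolerance
    witness, d_y = _step3_witness(runner, i, j)
    if witness is not None:
        return _record(i, j, d_x, witness.length, tol, witness)
    if math.isinf(d_y):  # disconnected in Y: no constrained path can exist
        return _record(i, j, d_x, INF, tol)
    dist_i, _ = runner.dijkstra_y(i)
    dist_j, _ = runner.dijkstra_y(j)
    cands = build_candidate_list((i, j), runner.ap, dist_i, dist_j, runner.params)
    best: Path | None = None
    for k, _dik, _djk in cands:
        w = _witness_via_k(runner, i, j, k, reroute=True)
        if w is None:
            continue
        if not exhaustive:
            best = w
            break
        if best is None or w.length < best.length:
            best = w
    if best is not None:
        return _record(i, j, d_x, best.length, tol, best)
    return _record(i, j, d_x, INF, tol)  # Step 5


def brides(ap: AugmentedPair, params: AlgoParams | None = None, pairs=None) -> BridesResult:
    """The original strategy: shortest-path screen, then ordered candidate
    concatenation with delete-and-reroute repair; first witness wins."""
    return _run(ap, params, pairs, _pair_brides)


def brides_ec(ap: AugmentedPair, params: AlgoParams | None = None, pairs=None) -> BridesResult:
    """Exhaustive concatenation: examine every candidate k, keep the
    shortest witness found before classifying."""
    return _run(
        ap, params, pairs, lambda r, i, j, d_x: _pair_brides(r, i, j, d_x, exhaustive=True)
    )


def _pair_brides_y(runner: _Runner, i, j, d_x) -> PairRecord:
    tol = runner.params.length_tolerance
    Y = runner.Y
    try:
        gen = nx.shortest_simple_paths(Y, i, j, weight="weight")
        count = 0
        for seq in gen:
            count += 1
            if runner.contains_added(seq):
                length = path_length(Y, seq)
                return _record(i, j, d_x, length, tol, Path(tuple(seq), length))
            if count >= runner.params.max_path_number:
                break
    except nx.NetworkXNoPath:
        pass
    return _record(i, j, d_x, INF, tol)  # Step 5


def brides_y(ap: AugmentedPair, params: AlgoParams | None = None, pairs=None) -> BridesResult:
    """Yen-based strategy: classify from the first of the k-shortest loopless
    i-j paths that contains an added node."""
    return _run(ap, params, pairs, _pair_brides_y)


def _yen_paths(runner: _Runner, source, target, cap: int) -> list[Path]:
    Y = runner.Y
    try:
        paths = []
        for seq in nx.shortest_simple_paths(Y, source, target, weight="weight"):
            paths.append(Path(tuple(seq), path_length(Y, seq)))
            if len(paths) >= cap:
                break
        return paths
    except nx.NetworkXNoPath:
        return []


def _pair_brides_yc(runner: _Runner, i, j, d_x) -> PairRecord:
    tol = runner.params.length_tolerance
    witness, d_y = _step3_witness(runner, i, j)
    if witness is not None:
        return _record(i, j, d_x, witness.length, tol, witness)
    if math.isinf(d_y):
        return _record(i, j, d_x, INF, tol)
    dist_i, _ = runner.dijkstra_y(i)
    dist_j, _ = runner.dijkstra_y(j)
    cands = build_candidate_list((i, j), runner.ap, dist_i, dist_j, runner.params)
    cap = runner.params.max_path_number
    from .paths import concatenate

    for k, _dik, _djk in cands:
        p_ik = _yen_paths(runner, i, k, cap)
        p_jk = _yen_paths(runner, j, k, cap)
        if not p_ik or not p_jk:
            continue
        # pairs of stored paths in nondecreasing combined length, ties by rank
        heap = [(p_ik[0].length + p_jk[0].length, 0, 0)]
        seen = {(0, 0)}
        while heap:
            _, a, b = heapq.heappop(heap)
            c = concatenate(p_ik[a], p_jk[b])
            if c is not None:
                return _record(i, j, d_x, c.length, tol, c)
            for na, nb in ((a + 1, b), (a, b + 1)):
                if na < len(p_ik) and nb < len(p_jk) and (na, nb) not in seen:
                    seen.add((na, nb))
                    heapq.heappush(
                        heap, (p_ik[na].length + p_jk[nb].length, na, nb)
                    )
    return _record(i, j, d_x, INF, tol)  # Step 5


def brides_yc(ap: AugmentedPair, params: AlgoParams | None = None, pairs=None) -> BridesResult:
    """Yen + concatenation strategy: stitch Yen-enumerated i->k and j->k path
    lists; no rerouting."""
    return _run(ap, params, pairs, _pair_brides_yc)


#: name -> strategy function, in the order the study compares them
STRATEGIES: dict[str, Callable] = {
    "brides": brides,
    "brides_y": brides_y,
    "brides_yc": brides_yc,
    "brides_ec": brides_ec,
}
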