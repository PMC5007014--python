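"""Random-graph accuracy benchmark for the four classification strategies.

The protocol mirrors the method's validation study: generate random
original networks, augment them with added nodes, sample original-node
pairs, and score each heuristic's label against the exact
constrained-distance oracle.

Augmentation works by generating the *augmented* network Y at full size
under the chosen random-graph model, picking the added nodes uniformly at
random, and taking the original network X as the induced subgraph on the
remaining nodes.  This is model-agnostic (growing a Watts-Strogatz ring
node-by-node is ill-defined) and guarantees N_X subset N_Y and
E_X subset E_Y, matching how similarity networks are rebuilt on enlarged
datasets.

Default model parameters (mean degree about 4 in each model):

* ER (Erdos-Renyi G(n, p)): p = 4/(n-1)
* BA (Barabasi-Albert): m = 2 edges per new node
* WS (Watts-Strogatz): ring degree k = 4, rewiring probability 0.05

All randomness flows from one root seed through ``numpy.random.SeedSequence``
keyed by (seed, replicate, purpose), so any single replicate is
reproducible in isolation.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .classify import STRATEGIES, AlgoParams
from .netio import AugmentedPair, node_key
from .oracle import dfs_constrained_distance, flow_constrained_distance, oracle_classify

__all__ = [
    "MODELS",
    "SimConfig",
    "AccuracyRow",
    "default_model_params",
    "generate_pair",
    "score_strategies",
    "run_experiment",
    "rows_to_tsv",
]

MODELS = ("ER", "BA", "WS")


def default_model_params(model: str, n_total: int) -> dict:
    """Model parameters giving mean degree about 4 at size ``n_total``."""
    if model == "ER":
        return {"p": 4.0 / max(n_total - 1, 1)}
    if model == "BA":
        return {"m": 2}
    if model == "WS":
        return {"k": 4, "p": 0.05}
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


@dataclass(frozen=True)
class SimConfig:
    """One cell of the benchmark grid."""

    model: str
    n_original: int = 100
    n_added: int = 25
    replicates: int = 1000
    pairs_sampled: int = 100
    model_params: dict | None = None
    seed: int = 0

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        for name in ("n_original", "n_added", "replicates", "pairs_sampled"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class AccuracyRow:
    model: str
    n_added: int
    strategy: str
    accuracy: float  # percent of sampled pairs labeled like the oracle
    mean_runtime_s: float  # informational only; never asserted
    replicates: int
    seed: int


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def generate_pair(cfg: SimConfig, replicate: int) -> AugmentedPair:
    """Deterministically generate one augmented instance.

    The augmented network Y has ``n_original + n_added`` nodes under the
    configured model; ``n_added`` nodes are designated added uniformly at
    random and X is the induced subgraph on the rest.
    """
    n_total = cfg.n_original + cfg.n_added
    mp = cfg.model_params or default_model_params(cfg.model, n_total)
    root = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(replicate,))
    ss_graph, ss_pick = root.spawn(2)
    gseed = _seed_int(ss_graph)
    if cfg.model == "ER":
        Y = nx.gnp_random_graph(n_total, mp["p"], seed=gseed)
    elif cfg.model == "BA":
        Y = nx.barabasi_albert_graph(n_total, mp["m"], seed=gseed)
    else:
        Y = nx.watts_strogatz_graph(n_total, mp["k"], mp["p"], seed=gseed)
    nx.set_edge_attributes(Y, 1.0, "weight")
    rng = np.random.default_rng(ss_pick)
    added = frozenset(
        int(v) for v in rng.choice(n_total, size=cfg.n_added, replace=False)
    )
    X = Y.subgraph(set(Y.nodes) - added).copy()
    return AugmentedPair(original=X, augmented=Y, added=added)


def sample_pairs(
    ap: AugmentedPair, pairs_sampled: int, rng: np.random.Generator
) -> list[tuple]:
    """Sample original pairs without replacement (all pairs when fewer exist)."""
    all_pairs = list(ap.original_pairs())
    if pairs_sampled >= len(all_pairs):
        return all_pairs
    idx = rng.choice(len(all_pairs), size=pairs_sampled, replace=False)
    return [all_pairs[t] for t in sorted(idx)]


def score_strategies(
    ap: AugmentedPair,
    params: AlgoParams | None = None,
    pairs_sampled: int = 100,
    rng: np.random.Generator | None = None,
    strategies: Sequence[str] = tuple(STRATEGIES),
    dfs_check_fraction: float = 0.0,
    dfs_node_limit: int = 25,
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Score heuristic labels against the exact oracle on sampled pairs.

    Returns ``(matches, runtimes)``: per strategy a boolean array (True where
    the heuristic label equals the oracle label on that pair) and the wall
    time of the strategy run.  The oracle is the polynomial flow engine;
    when ``dfs_check_fraction`` > 0 and the instance is within the DFS node
    guard, that fraction of pairs is re-checked with the brute-force engine
    (an AssertionError on disagreement would indicate an oracle defect).
    """
    params = params or AlgoParams()
    rng = rng or np.random.default_rng()
    pairs = sample_pairs(ap, pairs_sampled, rng)
    ref = oracle_classify(ap, engine="flow", pairs=pairs, tol=params.length_tolerance)
    if dfs_check_fraction > 0 and ap.augmented.number_of_nodes() <= dfs_node_limit:
        for rec in ref.records:
            if rng.random() < dfs_check_fraction:
                d = dfs_constrained_distance(
                    ap.augmented, *rec.pair, ap.added, node_limit=dfs_node_limit
                )
                assert (math.isinf(d) and math.isinf(rec.d_y_constrained)) or math.isclose(
                    d, rec.d_y_constrained, rel_tol=1e-9, abs_tol=1e-9
                ), f"flow/DFS oracle disagreement on pair {rec.pair}"
    ref_labels = [r.label for r in ref.records]
    matches: dict[str, np.ndarray] = {}
    runtimes: dict[str, float] = {}
    for name in strategies:
        fn = STRATEGIES[name]
        t0 = time.perf_counter()
        res = fn(ap, params, pairs=pairs)
        runtimes[name] = time.perf_counter() - t0
        matches[name] = np.array(
            [r.label == ref for r, ref in zip(res.records, ref_labels)], dtype=bool
        )
    return matches, runtimes


def run_experiment(
    configs: Iterable[SimConfig],
    params: AlgoParams | None = None,
    strategies: Sequence[str] = tuple(STRATEGIES),
    dfs_check_fraction: float = 0.0,
    progress: bool = False,
) -> list[AccuracyRow]:
    """Average per-replicate accuracy over each configuration cell.

    Accuracy for one replicate is the percent of its sampled pairs labeled
    like the oracle; the row value is the mean over replicates.  Runtime is
    recorded for information only.
    """
    params = params or AlgoParams()
    rows: list[AccuracyRow] = []
    for cfg in configs:
        acc: dict[str, list[float]] = {s: [] for s in strategies}
        rts: dict[str, list[float]] = {s: [] for s in strategies}
        for rep in range(cfg.replicates):
            ap = generate_pair(cfg, rep)
            ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(rep, 1))
            rng = np.random.default_rng(ss)
            matches, runtimes = score_strategies(
                ap,
                params,
                cfg.pairs_sampled,
                rng,
                strategies=strategies,
                dfs_check_fraction=dfs_check_fraction,
            )
            for s in strategies:
                acc[s].append(100.0 * float(np.mean(matches[s])))
                rts[s].append(runtimes[s])
            if progress:  # pragma: no cover - console feedback only
                print(
                    f"{cfg.model} n_added={cfg.n_added} rep {rep + 1}/{cfg.replicates}",
                    flush=True,
                )
        for s in strategies:
            rows.append(
                AccuracyRow(
                    model=cfg.model,
                    n_added=cfg.n_added,
                    strategy=s,
                    accuracy=float(np.mean(acc[s])),
                    mean_runtime_s=float(np.mean(rts[s])),
                    replicates=cfg.replicates,
                    seed=cfg.seed,
                )
            )
    return rows


def rows_to_tsv(rows: Sequence[AccuracyRow]) -> str:
    lines = ["model\tn_added\tstrategy\taccuracy\tmean_runtime_s\treplicates\tseed"]
    for r in rows:
        lines.append(
            f"{r.model}\t{r.n_added}\t{r.strategy}\t{r.accuracy:.4f}\t"
            f"{r.mean_runtime_s:.6f}\t{r.replicates}\t{r.seed}"
        )
    return "\n".join(lines) + "\n"
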