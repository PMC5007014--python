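from pathlib import Path

import networkx as nx
import numpy as np
import pytest

from brides import AugmentedPair, read_edge_list, validate_augmentation
from brides.simulate import MODELS, SimConfig, generate_pair

DATA = Path(__file__).parent / "data"

#: ground-truth six-way counts for the shipped 11-node fixture
#: (B, R, I, D, E, S) over the 28 original pairs, established by exhaustive
#: enumeration of all simple paths
F1_COUNTS = (1, 1, 20, 4, 1, 1)

F1_LABELS = {
    ("1", "4"): "SHORTCUT",
    ("1", "3"): "EQUAL",
    ("1", "2"): "DETOUR",
    ("2", "3"): "DETOUR",
    ("2", "4"): "DETOUR",
    ("3", "4"): "DETOUR",
    ("7", "8"): "BREAKTHROUGH",
    ("5", "6"): "ROADBLOCK",
}


@pytest.fixture(scope="session")
def f1_x_file() -> Path:
    return DATA / "f1_x.tsv"


@pytest.fixture(scope="session")
def f1_y_file() -> Path:
    return DATA / "f1_y.tsv"


@pytest.fixture(scope="session")
def f1_pair(f1_x_file, f1_y_file) -> AugmentedPair:
    X = read_edge_list(f1_x_file)
    Y = read_edge_list(f1_y_file)
    return validate_augmentation(X, Y)


def small_random_instance(seed: int) -> AugmentedPair:
    """Seeded random augmented pair small enough for the DFS oracle."""
    rng = np.random.default_rng(seed)
    model = MODELS[seed % 3]
    n_orig = int(rng.integers(5, 16))
    n_add = int(rng.integers(1, 7))
    cfg = SimConfig(
        model=model, n_original=n_orig, n_added=n_add,
        replicates=1, pairs_sampled=1, seed=seed,
    )
    return generate_pair(cfg, 0)


def graph_from_edges(edges, nodes=(), weight: float = 1.0) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for e in edges:
        if len(e) == 3:
            g.add_edge(e[0], e[1], weight=float(e[2]))
        else:
            g.add_edge(e[0], e[1], weight=weight)
    return g
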