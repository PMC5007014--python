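# brides

Characterize how a similarity network changed when new nodes appeared.

Genome and gene similarity networks — graphs whose nodes are genomes (or
gene families) and whose edges record shared homologous content — are
routinely rebuilt as datasets grow or as stringency thresholds move. Given
an *original* network `X = (N_X, E_X)` and an *augmented* network
`Y = (N_Y, E_Y)` with `N_X ⊂ N_Y` (edges among original nodes may differ),
`brides` classifies every unordered pair `(i, j)` of original nodes by
comparing the shortest simple (loopless) path between them in `X` against
the shortest simple path in `Y` that is **forced to traverse at least one
added node** `k ∈ N_Y \ N_X`:

| in X            | constrained in Y | label        |
|-----------------|------------------|--------------|
| impossible      | possible         | Breakthrough |
| possible        | impossible       | Roadblock    |
| impossible      | impossible       | Impasse      |
| shorter         | longer           | Detour       |
| equal length    | equal length     | Equal        |
| longer          | shorter          | Shortcut     |

The distribution of these six counts (the "BRIDES statistics") separates
evolutionary scenarios that ordinary network summaries (degree, path
length, clustering) cannot: added plasmids tend to create Shortcuts between
prokaryotic genomes, added viruses create Roadblocks, photosynthetic
eukaryotes create Detours and Equals that nonphotosynthetic eukaryotes do
not.

Because the shortest simple path through a prescribed node set is NP-hard
in general, the package provides four heuristic strategies plus two exact
reference oracles:

- **`brides`** — the original strategy: screen the enumerated shortest
  `i–j` paths in `Y` for an added node; otherwise walk a candidate list of
  added nodes `k` ordered by closeness (`min max(d(i,k), d(j,k))`,
  strategy 1, or `min d(i,k)+d(j,k)`, strategy 2) and stitch a simple
  `i→k→j` path from stored shortest paths, repairing collisions by deleting
  the blocking path's nodes and rerouting.
- **`brides_y`** — scan Yen's k-shortest loopless `i–j` paths and classify
  from the first one containing an added node.
- **`brides_yc`** — concatenate Yen-enumerated `i→k` and `j→k` path lists.
- **`brides_ec`** — exhaustive concatenation over all candidates, keeping
  the shortest witness.
- **oracles** — a brute-force DFS over simple paths (small instances) and a
  polynomial exact engine reducing the single-must-include-node problem to
  a minimum-cost pair of internally vertex-disjoint paths.

Tunable parameters `MaxPathNumber`, `MaxDistance` and `MaxNode` all default
to 100.

## Worked example

`tests/data/` ships an 11-node fixture: `X` has nodes 1–8 with edges
1–2, 2–3, 3–4 and 5–6 (7 and 8 isolated); `Y` adds nodes 9, 10, 11 and
edges 1–9, 9–4, 7–10, 10–8, 1–11, 11–3.

```
$ brides run tests/data/f1_x.tsv tests/data/f1_y.tsv
B=1 R=1 I=20 D=4 E=1 S=1
```

Of the 28 original pairs: (7,8) is a Breakthrough (connected only via added
node 10), (5,6) a Roadblock (its component contains no added node), (1,4) a
Shortcut (1–9–4 of length 2 beats the original 1–2–3–4 of length 3), (1,3)
an Equal (1–11–3 ties 1–2–3), four pairs are Detours and the remaining 20
pairs, disconnected in both networks, are Impasses. The same counts are
returned by all four strategies and by both oracles
(`brides oracle … --engine dfs|flow`).

The same library calls are:

```python
from brides import read_edge_list, validate_augmentation, brides

X = read_edge_list("tests/data/f1_x.tsv")
Y = read_edge_list("tests/data/f1_y.tsv")
result = brides(validate_augmentation(X, Y))
print(result.summary())   # B=1 R=1 I=20 D=4 E=1 S=1
```

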