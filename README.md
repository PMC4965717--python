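# glyconet

Rule-based construction of N-glycosylation reaction networks.

Given one or more starting glycans and a database of enzyme reaction rules,
`glyconet` applies the rules breadth-first — every rule to every glycan found
so far, at every matching site — and records each product as a node and each
enzymatic step as a directed edge. Glycans are immutable trees with a
canonical [LinearCode](https://doi.org/10.1021/bk-2012-1102.ch003)-style
serialisation, so structures discovered along different routes deduplicate
exactly and repeated runs are byte-identical.

The bundled database contains 27 rules for 22 glycosidases and
glycosyltransferases of the mammalian Golgi: ER/Golgi mannosidases I and II,
the branching GlcNAc-transferases MGAT1–5, core fucosylation (FUT8),
galactosylation (type-1 and type-2 chains), poly-LacNAc extension,
sialylation, and Lewis/blood-group decoration. Each rule carries a substrate
pattern, a product pattern, an optional constraint expression, and eight
fine-grained specificity fields (minimal/maximal substrate structure,
excluded branches/structures/residues, target-branch conditions). The full
dialect is documented in [docs/methods.md](docs/methods.md).

## Worked example

Grow the network from Man9GlcNAc2 (`M9`) for seven rounds using only the
core-processing rules 1–13 (mannosidases, MGAT1–5, FUT8, galactosylation,
α2-3 sialylation, poly-LacNAc initiation):

```console
$ glyconet infer --rules 1-13
 round  new_structures  cum_structures  cum_reactions  cum_reactions_known  MGAT1  ManI  ManII
     0               1               1              0                    0      0     0      0
     1               2               3              2                    2      0     2      0
     2               2               5              5                    5      0     5      0
     3               3               8              9                    9      1     8      0
     4               3              11             15                   15      3    12      0
     5               1              12             18                   18      4    14      0
     6               1              13             19                   19      4    14      1
     7               1              14             20                   20      4    14      2
cumulative: 14 structures, 20 reactions
```

Round 0 is the starting structure. Within seven rounds this subset produces
the 14 structures of the classical trimming pathway: ManI removes the three
accessible α1-2 mannoses, MGAT1 opens the hybrid pathway, and ManII finishes
the trimming on MGAT1 products. The complex-type enzymes (MGAT2–5, FUT8,
b4GalT, a3SiaT) need the biantennary core, which lies beyond seven rounds,
so they contribute no reactions yet — the per-enzyme columns list only the
enzymes that fired.

With all 27 rules, the hybrid antennae additionally acquire type-1 chains
(b3GalT1) and their fucosylated/sialylated decorations:

```console
$ glyconet infer
...
cumulative: 31 structures, 54 reactions
```

Export any network for Cytoscape, Gephi or Graphviz:

```console
$ glyconet infer --out network.graphml                  # also: --format sif|dot|csv-edges
$ glyconet infer --root Man5 --rules MGAT1 --rounds 2   # custom root and rule selection
$ glyconet rules                                        # list the rule database
$ glyconet validate-rules                               # 27 rules, 22 enzymes: ...
```

Roots may be fixture names (`M9`, `M8`, `Man5`) or any LinearCode string,
and `--rules-csv` points the engine at your own rule database.

## Python API

```python
from glyconet import forward_network_inference, load_fixture, load_rule_db, select_rules

rules = select_rules(load_rule_db(), "1-13")
net = forward_network_inference([load_fixture("M9")], rules, max_rounds=7)
print(net.n_structures, net.n_reactions)   # 14 20
```

## Tests

```console
python -m pytest -q tests/
```

The suite covers the tree/canonicalisation core, the LinearCode parser and
pattern dialect, every rule against a minimal golden substrate, the
specificity predicates, network inference (including an independent
exhaustive-search oracle), exporters, the CLI, and hypothesis-based property
tests. Two acceptance tests asserting external reference reaction tallies
(64 and 26) fail by design; `docs/methods.md` explains the counting
discrepancy.
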