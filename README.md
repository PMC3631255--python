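# motifmatch

Exact enumeration of small typed subgraph motifs ("composite motifs") in
large networks whose edges carry types — directed or undirected — such as
integrated biological interaction networks with physical, genetic and
signaling layers.

The package provides:

* **`typed_graph`** — an edge-typed multigraph with two incrementally
  maintained indexes (start nodes per type key, typed neighbors per node)
  so the search engines never scan edge lists.
* **`motif_spec`** — the linear motif specification language (upper case =
  forward typed link, lower case = reverse of a directed type, `0` = no
  link, pairs ordered `(1,2),(1,3),(2,3),(1,4),…`), plus symmetry
  analysis: the motif automorphism group, reflection classes, rotation
  cycles, and a plain-changes (Steinhaus–Johnson–Trotter) permutation
  generator.
* **`matcher`** — three enumeration engines sharing one contract:
  * `find_motifs_rsma` — naive recursive baseline, fixed investigation
    order, first level over all network nodes;
  * `find_motifs_isma_recursive` — dynamic investigation order, always
    extending the motif node with the smallest candidate upper bound;
  * `find_motifs_isma` — iterative engine built on a checklist,
    per-motif-node candidate iterators, a priority-queue map, and symmetry
    sets that prune reflection- and rotation-equivalent branches before
    they are explored; residual symmetric duplicates are eliminated by
    canonical forms under the full automorphism group.

  All engines report search statistics (`tree_nodes` counts every mapping
  of a network node onto a motif node — the cost metric; STRF = RSMA tree
  size / ISMA tree size).
* **`fixtures_oracle`** — a brute-force enumeration oracle (ground truth on
  small inputs), a seeded random typed-graph generator, and the bundled
  6-node worked-example network.
* **`io_cli`** — per-type edge-list input, the `Motif [SPEC]: [n1, n2, …]`
  output format, and the command line interface.

## Command line

One input file per link type, one link per line as `start<TAB>end`:

```sh
motifmatch -folder input/ \
    -linkfiles "A d linksAtype.txt B d linksBtype.txt C u linksCtype.txt" \
    -motif "ABC" \
    -output output/results.txt
```

Each `-linkfiles` triple is `<type> <d|u> <filename>` (directed or
undirected). Optional flags:

| flag | effect |
| --- | --- |
| `--algorithm {isma,isma-recursive,rsma,oracle,compare}` | engine choice (`compare` runs RSMA and ISMA, checks agreement, reports STRF) |
| `--induced` | require `0` motif pairs to be edge-free in matches |
| `--no-symmetry` | disable symmetry-set pruning (duplicates still eliminated) |
| `--stats` | print instance/tree-size statistics |

The output file has one line per unique instance (counted up to motif
automorphism), nodes in motif order, sorted:

```
Motif [ABC]: [1, 5, 4]
Motif [ABC]: [5, 6, 3]
```

## Library example

```python
from motifmatch import LinkTypeRegistry, TypedGraph, parse_motif, find_motifs_isma

reg = LinkTypeRegistry([("A", True), ("C", False)])
g = TypedGraph(reg)
g.add_link("x", "y", "A")
g.add_link("y", "z", "C")
motif = parse_motif("A0C", reg)   # x->y (A), y-z (C)
instances, stats = find_motifs_isma(motif, g)
```

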