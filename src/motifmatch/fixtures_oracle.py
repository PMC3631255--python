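"""Deterministic test assets: the 6-node worked example, a random typed
graph generator, and a brute-force enumeration oracle.

The oracle tests every injective k-tuple of network nodes against every
pair code and is deliberately independent of the search engines: it defines
ground truth on small inputs.  Its automorphism group is likewise computed
by direct permutation enumeration rather than through the plain-changes
generator used elsewhere.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from itertools import combinations, permutations
from pathlib import Path

from .motif_spec import MotifSpec, parse_motif
from .typed_graph import LinkTypeRegistry, TypedGraph, sorted_nodes

ORACLE_MAX_NODES = 40
ORACLE_MAX_MOTIF = 5


@dataclass
class FixtureBundle:
    graph: TypedGraph
    motif: MotifSpec
    expected_instances: list[tuple[str, ...]]
    expected_tree_sizes: tuple[int, int]  # (rsma, isma)


# Six-node network with three link layers.  The edge lists are a
# constraint-based reconstruction: they simultaneously satisfy the five
# per-type start-node sets of the initialization table and the six narrated
# typed neighbor sets (a(5)={1,2}, C(5)={4}, b(4)={1}, a(6)={5},
# C(6)={2,3}, B(5)={3}).  One A-edge is under-determined by those
# constraints: 2->1 (canonical) and 5->1 (alternative) both fit, and both
# yield the same instances and tree sizes -- the test suite checks the two
# reconstructions side by side.
_A_EDGES = [("1", "5"), ("2", "5"), ("5", "6"), ("2", "1")]
_A_EDGES_ALT = [("1", "5"), ("2", "5"), ("5", "6"), ("5", "1")]
_B_EDGES = [("1", "4"), ("2", "3"), ("4", "2"), ("5", "3")]
_C_EDGES = [("4", "5"), ("2", "6"), ("3", "6")]


def worked_example_registry() -> LinkTypeRegistry:
    return LinkTypeRegistry([("A", True), ("B", True), ("C", False)])


def build_worked_example(alternative: bool = False) -> FixtureBundle:
    """The example network and its "ABC" motif, with known ground truth:
    exactly the instances (1,5,4) and (5,6,3), an RSMA tree of 12 mapping
    events and an ISMA tree of 6."""
    registry = worked_example_registry()
    g = TypedGraph(registry)
    for u, v in (_A_EDGES_ALT if alternative else _A_EDGES):
        g.add_link(u, v, "A")
    for u, v in _B_EDGES:
        g.add_link(u, v, "B")
    for u, v in _C_EDGES:
        g.add_link(u, v, "C")
    motif = parse_motif("ABC", registry)
    return FixtureBundle(
        graph=g,
        motif=motif,
        expected_instances=[("1", "5", "4"), ("5", "6", "3")],
        expected_tree_sizes=(12, 6),
    )


def random_typed_graph(
    n: int,
    registry: LinkTypeRegistry,
    p: float,
    seed: int,
) -> TypedGraph:
    """Erdos-Renyi graph per registered type: directed types sample ordered
    node pairs, undirected types unordered pairs; reproducible per seed."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"edge probability must be in [0, 1], got {p}")
    rng = random.Random(seed)
    g = TypedGraph(registry)
    nodes = [str(i) for i in range(n)]
    for nd in nodes:
        g.add_node(nd)
    for t, directed in registry:
        if directed:
            for u in nodes:
                for v in nodes:
                    if u != v and rng.random() < p:
                        g.add_link(u, v, t)
        else:
            for i, u in enumerate(nodes):
                for v in nodes[i + 1:]:
                    if rng.random() < p:
                        g.add_link(u, v, t)
    return g


def _brute_force_automorphisms(m: MotifSpec) -> list[tuple[int, ...]]:
    auts = []
    for p in permutations(range(1, m.k + 1)):
        if all(
            m.code_between(p[i - 1], p[j - 1]) == m.code_between(i, j)
            for i, j in combinations(range(1, m.k + 1), 2)
        ):
            auts.append(p)
    return auts


def oracle_enumerate(
    m: MotifSpec,
    g: TypedGraph,
    mode: str = "non-induced",
) -> tuple[list[tuple[str, ...]], list[tuple[str, ...]]]:
    """Exhaustively enumerate (ordered embeddings, unique instances).

    Every injective k-tuple is checked pair by pair: non-'0' codes must be
    realized by an edge of exactly that oriented type; in induced mode '0'
    pairs must additionally be edge-free across all types.  Unique instances
    are the ordered embeddings collapsed by the automorphism group
    (canonical representative kept).  Guarded to small inputs.
    """
    if mode not in ("non-induced", "induced"):
        raise ValueError(f"unknown mode {mode!r}")
    n = len(g.nodes)
    if n > ORACLE_MAX_NODES or m.k > ORACLE_MAX_MOTIF:
        raise ValueError(
            f"oracle guard exceeded (n={n} > {ORACLE_MAX_NODES} or "
            f"k={m.k} > {ORACLE_MAX_MOTIF}); use the search engines instead"
        )
    induced = mode == "induced"
    pairs = [
        (i, j, m.code_between(i, j))
        for i, j in combinations(range(1, m.k + 1), 2)
    ]
    ordered: list[tuple[str, ...]] = []
    for tup in permutations(sorted_nodes(g.nodes), m.k):
        ok = True
        for i, j, code in pairs:
            u, v = tup[i - 1], tup[j - 1]
            if code == "0":
                if induced and g.has_any_edge(u, v):
                    ok = False
                    break
            elif v not in g.neighbors_of_type(u, code):
                ok = False
                break
        if ok:
            ordered.append(tup)
    auts = _brute_force_automorphisms(m)
    unique: list[tuple[str, ...]] = []
    seen: set[tuple[str, ...]] = set()
    for tup in ordered:
        best = min(
            (tuple(_apply(p, tup)) for p in auts),
            key=lambda t: tuple(map(_node_sort, t)),
        )
        if best not in seen:
            seen.add(best)
            unique.append(best)
    return ordered, unique


def _apply(p: tuple[int, ...], tup: tuple[str, ...]) -> list[str]:
    img = [""] * len(tup)
    for i, nn in enumerate(tup):
        img[p[i] - 1] = nn
    return img


def _node_sort(name: str):
    from .typed_graph import node_key

    return node_key(name)


def export_link_files(g: TypedGraph, folder: str | Path) -> list[tuple[str, str, str]]:
    """Write one per-type edge-list file into ``folder``; return the
    (type name, d/u flag, filename) triples for a CLI invocation."""
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    triples = []
    for t, directed in g.registry:
        fname = f"links{t}type.txt"
        lines = sorted(
            f"{u}\t{v}" for (u, v, tt) in g.edges if tt == t
        )
        (folder / fname).write_text("\n".join(lines) + ("\n" if lines else ""))
        triples.append((t, "d" if directed else "u", fname))
    return triples
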