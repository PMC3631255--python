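"""Exact motif enumeration engines.

Three engines share one contract -- return the unique instances (tuples of
network nodes in motif-node order 1..k) plus search statistics:

* :func:`find_motifs_rsma` -- naive depth-first baseline, fixed
  investigation order 1..k, first level iterating over all network nodes;
* :func:`find_motifs_isma_recursive` -- dynamic investigation order, always
  extending the motif node with the smallest candidate upper bound;
* :func:`find_motifs_isma` -- the iterative engine built on a checklist,
  per-motif-node candidate iterators, a priority-queue map, and optional
  symmetry sets that prune reflection- and rotation-equivalent branches.

'0' pairs impose no constraint during search (non-induced matching); the
optional induced mode post-filters complete instances whose '0' pairs are
joined by an edge of any type.  All engines apply canonical-form duplicate
elimination under the full automorphism group, so their instance sets are
identical and free of symmetric duplicates.

The search-tree size (``SearchStats.tree_nodes``) counts every mapping of a
network node onto a motif node; it is the cost metric used to compare the
engines (STRF = RSMA tree size / ISMA tree size).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .motif_spec import (
    MotifSpec,
    SymmetryInfo,
    automorphisms,
    canonical_instance,
    classify_symmetries,
)
from .typed_graph import TypedGraph, node_key, sorted_nodes

Instance = tuple[str, ...]
TraceEvent = tuple  # ("check", mn, candidates) | ("map", mn, nn) | ("export", tup)


class MatcherError(ValueError):
    """Invalid matching request."""


class DisconnectedMotifError(MatcherError):
    """The motif is not connected through non-'0' pairs."""


@dataclass
class SearchStats:
    tree_nodes: int = 0
    instances_found: int = 0
    duplicates_discarded: int = 0


# ---------------------------------------------------------------------------
# shared primitives
# ---------------------------------------------------------------------------

def determine_set(
    inst: dict[int, str],
    mn: int,
    g: TypedGraph,
    m: MotifSpec,
    sym_sets: dict[int, set[str]] | None = None,
    sym: SymmetryInfo | None = None,
    checked: tuple[int, ...] = (),
) -> list[str]:
    """Candidate network nodes for motif node ``mn`` given a partial instance.

    Empty instance: intersection of the start-node sets of every non-'0'
    code departing ``mn``.  Otherwise: intersection, over mapped nodes with a
    non-'0' code toward ``mn``, of their typed neighbor sets; when symmetry
    sets are supplied, the sets of already-checked nodes whose symmetry
    covers ``mn`` join the intersection.  Already-mapped nodes are excluded
    (injectivity).  The result is sorted for deterministic iteration.
    """
    sets: list = []
    if not inst:
        for code in m.departing_codes(mn):
            sets.append(g.start_nodes_of_type(code))
        if not sets:
            raise MatcherError(f"motif node {mn} has no links")
    else:
        for mi, nn in inst.items():
            code = m.code_between(mi, mn)
            if code != "0":
                sets.append(g.neighbors_of_type(nn, code))
        if not sets:
            raise DisconnectedMotifError(
                f"disconnected motif ordering: node {mn} has no link to any mapped node"
            )
        if sym_sets is not None and sym is not None:
            for mc in checked:
                if mn in sym.consulted_by.get(mc, ()) and mc in sym_sets:
                    sets.append(sym_sets[mc])
    inter = set(sets[0])
    for s in sets[1:]:
        inter &= s
    inter.difference_update(inst.values())
    return sorted(inter, key=node_key)


def select_first_motif_node(g: TypedGraph, m: MotifSpec) -> tuple[int, list[str]]:
    """Pick the motif node to investigate first and its candidate set.

    The number of start nodes is counted for every oriented code occurring
    in the motif (reverse codes included).  A unique minimum selects the
    motif node from which that code departs; any tie falls back to the
    intersection value (IV) -- the candidate-set cardinality -- evaluated
    for all motif nodes, smallest set winning, residual ties broken by the
    smallest motif index.
    """
    codes = m.all_codes()
    if not codes:
        raise MatcherError("motif has no links (all pair codes are '0')")
    counts = {c: len(g.start_nodes_of_type(c)) for c in codes}
    minv = min(counts.values())
    min_codes = sorted(c for c, v in counts.items() if v == minv)
    if len(min_codes) == 1:
        holders = [
            i for i in range(1, m.k + 1) if min_codes[0] in m.departing_codes(i)
        ]
        if len(holders) == 1:
            mn = holders[0]
            return mn, determine_set({}, mn, g, m)
    best_mn, best_set = None, None
    for i in range(1, m.k + 1):
        s = determine_set({}, i, g, m)
        if best_set is None or len(s) < len(best_set):
            best_mn, best_set = i, s
    assert best_mn is not None and best_set is not None
    return best_mn, best_set


# priority objects are (nbs_count, motif_start, network_node) tuples stored
# per motif end node; queues are tiny (at most k*k entries) so plain lists
# with linear scans beat heap bookkeeping here.
PQM = dict[int, list[tuple[int, int, str]]]


def poll_next(pqm: PQM, rest: set[int]) -> int:
    """Motif end node of the globally minimal priority object among the
    queues of uninvestigated motif nodes; ties go to the smallest motif
    index.

    The winning object is left in its queue: objects are removed only when
    the network node that contributed them is unmapped.  Destructive polling
    would leave a re-checked motif node with an empty queue whenever its
    only object came from a node mapped before a '0'-linked stretch of the
    search.
    """
    best_key = None
    best_mn = None
    for mn in sorted(rest):
        for po in pqm.get(mn, ()):
            key = (po[0], mn, node_key(po[2]), po[1])
            if best_key is None or key < best_key:
                best_key, best_mn = key, mn
    if best_mn is None:
        raise MatcherError("all priority queues of uninvestigated motif nodes are empty")
    return best_mn


def _purge(pqm: PQM, motif_start: int) -> None:
    # drop every priority object contributed by the node mapped on motif_start
    for mn, queue in pqm.items():
        if queue:
            pqm[mn] = [po for po in queue if po[1] != motif_start]


def residual_deduplicate(
    tup: Instance, auts, seen: set[Instance]
) -> bool:
    """Keep/discard decision for a freshly completed instance.

    The canonical form is the lexicographically smallest image of the tuple
    under the full automorphism group; the instance is kept iff that form is
    unseen.  Sound regardless of how many duplicates the symmetry-set
    pruning already removed.
    """
    canon = canonical_instance(tup, auts)
    if canon in seen:
        return False
    seen.add(canon)
    return True


def _induced_ok(tup: Instance, m: MotifSpec, g: TypedGraph) -> bool:
    for i in range(1, m.k + 1):
        for j in range(i + 1, m.k + 1):
            if m.code_between(i, j) == "0" and g.has_any_edge(tup[i - 1], tup[j - 1]):
                return False
    return True


def _make_exporter(
    m: MotifSpec,
    g: TypedGraph,
    auts,
    induced: bool,
    out: list[Instance],
    stats: SearchStats,
    seen: set[Instance],
    trace: list[TraceEvent] | None,
):
    def export(inst: dict[int, str]) -> None:
        tup = tuple(inst[i] for i in range(1, m.k + 1))
        if induced and not _induced_ok(tup, m, g):
            return
        if residual_deduplicate(tup, auts, seen):
            out.append(tup)
            stats.instances_found += 1
            if trace is not None:
                trace.append(("export", tup))
        else:
            stats.duplicates_discarded += 1

    return export


# ---------------------------------------------------------------------------
# RSMA: naive recursive baseline
# ---------------------------------------------------------------------------

def find_motifs_rsma(
    m: MotifSpec,
    g: TypedGraph,
    induced: bool = False,
    trace: list[TraceEvent] | None = None,
) -> tuple[list[Instance], SearchStats]:
    """Depth-first enumeration in fixed motif-node order 1..k.

    The first level iterates over all network nodes.  A deeper motif node
    with no non-'0' code toward any mapped node (possible for motifs whose
    connecting links appear later in the order) falls back to all unmapped
    nodes, keeping the baseline correct for every motif.
    """
    auts = automorphisms(m)
    stats = SearchStats()
    seen: set[Instance] = set()
    out: list[Instance] = []
    export = _make_exporter(m, g, auts, induced, out, stats, seen, trace)
    all_nodes = sorted_nodes(g.nodes)
    inst: dict[int, str] = {}

    def rec(mn: int) -> None:
        if mn > m.k:
            export(inst)
            return
        if mn == 1:
            candidates = all_nodes
        else:
            sets = []
            for mi, nn in inst.items():
                code = m.code_between(mi, mn)
                if code != "0":
                    sets.append(g.neighbors_of_type(nn, code))
            if sets:
                inter = set(sets[0])
                for s in sets[1:]:
                    inter &= s
                inter.difference_update(inst.values())
                candidates = sorted(inter, key=node_key)
            else:
                candidates = [n for n in all_nodes if n not in inst.values()]
        for nn in candidates:
            inst[mn] = nn
            stats.tree_nodes += 1
            rec(mn + 1)
            del inst[mn]

    rec(1)
    return out, stats


# ---------------------------------------------------------------------------
# recursive engine with dynamic ordering
# ---------------------------------------------------------------------------

def _next_dynamic(inst: dict[int, str], m: MotifSpec, g: TypedGraph) -> int:
    """Unmapped motif node whose cheapest incident neighbor set is globally
    smallest (the candidate-set upper bound); ties to the smallest index."""
    best = None
    best_mn = None
    for mn in range(1, m.k + 1):
        if mn in inst:
            continue
        for mi, nn in inst.items():
            code = m.code_between(mi, mn)
            if code == "0":
                continue
            nbs = len(g.neighbors_of_type(nn, code))
            if best is None or (nbs, mn) < best:
                best = (nbs, mn)
                best_mn = mn
    if best_mn is None:
        raise DisconnectedMotifError(
            "no unmapped motif node is linked to a mapped one"
        )
    return best_mn


def find_motifs_isma_recursive(
    m: MotifSpec,
    g: TypedGraph,
    induced: bool = False,
    trace: list[TraceEvent] | None = None,
) -> tuple[list[Instance], SearchStats]:
    """Recursive engine: at every step extend the motif node with the
    smallest candidate upper bound (dynamic investigation order)."""
    if not m.is_connected():
        raise DisconnectedMotifError(
            "motif is not connected through non-'0' pairs; split it into components"
        )
    auts = automorphisms(m)
    stats = SearchStats()
    seen: set[Instance] = set()
    out: list[Instance] = []
    export = _make_exporter(m, g, auts, induced, out, stats, seen, trace)
    inst: dict[int, str] = {}

    def rec() -> None:
        if len(inst) == m.k:
            export(inst)
            return
        if not inst:
            mn, candidates = select_first_motif_node(g, m)
        else:
            mn = _next_dynamic(inst, m, g)
            candidates = determine_set(inst, mn, g, m)
        if trace is not None:
            trace.append(("check", mn, list(candidates)))
        for nn in candidates:
            inst[mn] = nn
            stats.tree_nodes += 1
            if trace is not None:
                trace.append(("map", mn, nn))
            rec()
            del inst[mn]

    rec()
    return out, stats


# ---------------------------------------------------------------------------
# iterative engine
# ---------------------------------------------------------------------------

class _Cursor:
    """Forward-only cursor over a candidate list (a peekable iterator)."""

    __slots__ = ("items", "pos")

    def __init__(self, items: list[str]):
        self.items = items
        self.pos = 0

    def has_next(self) -> bool:
        return self.pos < len(self.items)

    def next(self) -> str:
        nn = self.items[self.pos]
        self.pos += 1
        return nn


def find_motifs_isma(
    m: MotifSpec,
    g: TypedGraph,
    use_symmetry: bool = True,
    induced: bool = False,
    trace: list[TraceEvent] | None = None,
) -> tuple[list[Instance], SearchStats]:
    """Iterative engine: checklist + candidate cursors + priority-queue map.

    Each drawn network node is preceded by a backtracking update covering the
    three situations: a cursor added last step (nothing to undo), a redraw
    from the same cursor (unmap the previous node, purge its priority
    objects), or a draw from an older cursor (uncheck the exhausted deeper
    motif nodes and roll back their mappings, priority objects and symmetry
    bookkeeping).  With ``use_symmetry`` the symmetry sets prune reflection-
    and rotation-equivalent branches before they are explored.
    """
    if not m.is_connected():
        raise DisconnectedMotifError(
            "motif is not connected through non-'0' pairs; split it into components"
        )
    sym = classify_symmetries(m)
    stats = SearchStats()
    seen: set[Instance] = set()
    out: list[Instance] = []
    export = _make_exporter(m, g, sym.automorphisms, induced, out, stats, seen, trace)
    k = m.k

    chosen: list[int] = []          # checklist: investigation order
    rest: set[int] = set(range(1, k + 1))
    cursors: dict[int, _Cursor] = {}
    inst: dict[int, str] = {}
    pqm: PQM = {i: [] for i in range(1, k + 1)}
    sym_sets: dict[int, set[str]] = {}

    def check(mn: int, candidates: list[str]) -> None:
        chosen.append(mn)
        rest.discard(mn)
        cursors[mn] = _Cursor(candidates)
        if use_symmetry and mn in sym.consulted_by:
            sym_sets[mn] = set(candidates)
        if trace is not None:
            trace.append(("check", mn, list(candidates)))

    mn0, start_set = select_first_motif_node(g, m)
    check(mn0, start_set)

    while True:
        # deepest checklist position whose cursor still has candidates
        d = len(chosen) - 1
        while d >= 0 and not cursors[chosen[d]].has_next():
            d -= 1
        if d < 0:
            break

        # backtrack: uncheck exhausted deeper motif nodes, then clear the
        # mapping being replaced on the draw position itself
        while len(chosen) - 1 > d:
            off = chosen.pop()
            rest.add(off)
            del cursors[off]
            if off in inst:
                del inst[off]
                _purge(pqm, off)
        top = chosen[d]
        if top in inst:
            del inst[top]
            _purge(pqm, top)

        nn = cursors[top].next()
        if use_symmetry and top in sym_sets:
            sym_sets[top].discard(nn)
        inst[top] = nn
        stats.tree_nodes += 1
        if trace is not None:
            trace.append(("map", top, nn))

        if len(inst) == k:
            export(inst)
            continue

        for i in sorted(rest):
            code = m.code_between(top, i)
            if code != "0":
                pqm[i].append((len(g.neighbors_of_type(nn, code)), top, nn))
        mn = poll_next(pqm, rest)
        candidates = determine_set(
            inst, mn, g, m,
            sym_sets if use_symmetry else None,
            sym if use_symmetry else None,
            tuple(chosen),
        )
        check(mn, candidates)

    return out, stats


ENGINES: dict[str, Callable] = {
    "rsma": find_motifs_rsma,
    "isma-recursive": find_motifs_isma_recursive,
    "isma": find_motifs_isma,
}
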