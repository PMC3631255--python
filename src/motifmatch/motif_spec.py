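"""Motif specification strings and their symmetry structure.

A motif over ``k`` ordered nodes is written as a linear string of
``K = k*(k-1)/2`` pair codes, one per unordered node pair, in the order
(1,2), (1,3), (2,3), (1,4), (2,4), (3,4), ... -- the column-wise upper
triangle of the motif's adjacency matrix.  Each code is either

* an upper-case type letter: a forward link from the lower-indexed node,
* a lower-case letter: the reverse of a directed type (link toward the
  lower-indexed node),
* ``'0'``: no link between the pair.

Motifs have at most one link per pair (no parallel or anti-parallel motif
links).  Beyond parsing, this module computes the motif's automorphism
group and classifies it into the two symmetry shapes the iterative engine
prunes directly -- reflections (mutually swappable node sets) and cyclic
rotations -- leaving everything else to residual duplicate elimination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

from .typed_graph import LinkTypeRegistry, node_key

Perm = tuple[int, ...]


class MotifSyntaxError(ValueError):
    """Malformed motif specification string."""


def _pair_index(i: int, j: int) -> int:
    # i < j; position of pair (i, j) in the column-wise upper triangle
    return (j - 1) * (j - 2) // 2 + (i - 1)


def _reverse_code(code: str) -> str:
    if code == "0" or not code.isalpha():
        return code
    if code.isupper():
        return code.lower()
    return code.upper()


class MotifSpec:
    """A parsed motif: node count ``k``, pair codes, and the type registry."""

    def __init__(self, k: int, entries: list[str], registry: LinkTypeRegistry):
        self.k = k
        self.entries = list(entries)
        self.registry = registry

    def __repr__(self) -> str:  # pragma: no cover
        return f"MotifSpec({self.to_string()!r}, k={self.k})"

    def to_string(self) -> str:
        return "".join(self.entries)

    def code_between(self, i: int, j: int) -> str:
        """Pair code oriented from node ``i`` toward node ``j``.

        The stored code of pair (i, j) with i < j is oriented from i, so a
        query in the opposite direction flips the case of directed codes.
        Undirected codes and '0' are orientation-free.
        """
        if i == j:
            raise MotifSyntaxError(f"no link code between a motif node and itself ({i})")
        if not (1 <= i <= self.k and 1 <= j <= self.k):
            raise MotifSyntaxError(f"motif index out of range: ({i},{j}) with k={self.k}")
        if i < j:
            code = self.entries[_pair_index(i, j)]
        else:
            code = self.entries[_pair_index(j, i)]
            if code != "0" and self.registry.is_directed(code.upper()):
                code = _reverse_code(code)
        return code

    def departing_codes(self, i: int) -> list[str]:
        """Oriented codes of all links departing motif node ``i`` (non-'0')."""
        return [
            self.code_between(i, j)
            for j in range(1, self.k + 1)
            if j != i and self.code_between(i, j) != "0"
        ]

    def all_codes(self) -> set[str]:
        """Every oriented code occurring in the motif, reverse keys included."""
        out: set[str] = set()
        for i in range(1, self.k + 1):
            out.update(self.departing_codes(i))
        return out

    def is_connected(self) -> bool:
        """Connectivity through non-'0' pairs."""
        if self.k == 1:
            return True
        adj: dict[int, set[int]] = {i: set() for i in range(1, self.k + 1)}
        for i, j in combinations(range(1, self.k + 1), 2):
            if self.entries[_pair_index(i, j)] != "0":
                adj[i].add(j)
                adj[j].add(i)
        seen = {1}
        stack = [1]
        while stack:
            for n in adj[stack.pop()]:
                if n not in seen:
                    seen.add(n)
                    stack.append(n)
        return len(seen) == self.k


MAX_MOTIF_NODES = 10


def parse_motif(spec: str, registry: LinkTypeRegistry) -> MotifSpec:
    """Parse a motif specification string against a type registry.

    The string length must be a triangular number k*(k-1)/2; every non-'0'
    code's base type must be declared, and lower-case codes are only legal
    for directed types.
    """
    if not spec:
        raise MotifSyntaxError("empty motif specification")
    K = len(spec)
    k = round((1 + math.sqrt(1 + 8 * K)) / 2)
    if k * (k - 1) // 2 != K:
        lo = k * (k - 1) // 2
        hi = k * (k + 1) // 2
        if lo > K:
            lo, hi = (k - 1) * (k - 2) // 2, lo
        raise MotifSyntaxError(
            f"motif length {K} is not triangular; nearest valid lengths are {lo} and {hi}"
        )
    if k > MAX_MOTIF_NODES:
        raise MotifSyntaxError(f"motif has {k} nodes; at most {MAX_MOTIF_NODES} supported")
    for pos, code in enumerate(spec):
        if code == "0":
            continue
        if not code.isalpha():
            raise MotifSyntaxError(f"invalid pair code {code!r} at position {pos}")
        base = code.upper()
        if base not in registry:
            raise MotifSyntaxError(f"unknown link type {base}")
        if code.islower() and not registry.is_directed(base):
            raise MotifSyntaxError(
                f"lower-case code {code!r} at position {pos}: type {base} is undirected"
            )
    return MotifSpec(k, list(spec), registry)


# ---------------------------------------------------------------------------
# permutations and automorphisms
# ---------------------------------------------------------------------------

def sjt_permutations(k: int) -> list[Perm]:
    """All k! permutations of 1..k in plain-changes order.

    Consecutive permutations differ by one adjacent transposition
    (Steinhaus-Johnson-Trotter); amortized constant work per permutation.
    """
    if not 1 <= k <= MAX_MOTIF_NODES:
        raise ValueError(f"k must be between 1 and {MAX_MOTIF_NODES}, got {k}")
    perm = list(range(1, k + 1))
    direction = [-1] * k
    out: list[Perm] = [tuple(perm)]
    while True:
        mobile = -1
        for i, v in enumerate(perm):
            j = i + direction[i]
            if 0 <= j < k and perm[j] < v and (mobile < 0 or v > perm[mobile]):
                mobile = i
        if mobile < 0:
            break
        v = perm[mobile]
        j = mobile + direction[mobile]
        perm[mobile], perm[j] = perm[j], perm[mobile]
        direction[mobile], direction[j] = direction[j], direction[mobile]
        for i, w in enumerate(perm):
            if w > v:
                direction[i] = -direction[i]
        out.append(tuple(perm))
    return out


def automorphisms(m: MotifSpec) -> list[Perm]:
    """Permutations of 1..k that leave the motif's pair-code table invariant.

    A permutation ``p`` (with ``p[i-1]`` the image of node ``i``) is included
    iff relabeling the nodes by ``p`` reproduces the identical motif.  The
    identity is always present and the result is a group.
    """
    k = m.k
    auts = []
    for p in sjt_permutations(k):
        ok = True
        for i, j in combinations(range(1, k + 1), 2):
            if m.code_between(p[i - 1], p[j - 1]) != m.code_between(i, j):
                ok = False
                break
        if ok:
            auts.append(p)
    return sorted(auts)


def _compose(p: Perm, q: Perm) -> Perm:
    # (p o q)(i) = p(q(i))
    return tuple(p[q[i] - 1] for i in range(len(q)))


def _closure(generators: list[Perm], k: int) -> set[Perm]:
    ident = tuple(range(1, k + 1))
    group = {ident}
    frontier = [ident]
    while frontier:
        nxt = []
        for a in frontier:
            for g in generators:
                c = _compose(g, a)
                if c not in group:
                    group.add(c)
                    nxt.append(c)
        frontier = nxt
    return group


def _cycles(p: Perm) -> list[tuple[int, ...]]:
    seen: set[int] = set()
    cycles = []
    for start in range(1, len(p) + 1):
        if start in seen:
            continue
        cyc = [start]
        seen.add(start)
        cur = p[start - 1]
        while cur != start:
            cyc.append(cur)
            seen.add(cur)
            cur = p[cur - 1]
        if len(cyc) > 1:
            cycles.append(tuple(cyc))
    return cycles


@dataclass
class SymmetryInfo:
    """The motif's automorphism group split into engine-usable pieces.

    ``reflection_classes`` are maximal sets of mutually swappable nodes;
    ``rotation_cycles`` are claimed cyclic symmetries, each cycle written
    starting at its designated 'first' node (the smallest index in the
    cycle).  ``reflection_lists`` holds, per symmetric node, the nodes it is
    recorded symmetric with: all classmates for a reflection node; for a
    rotation, the first node lists all cycle members and the others list
    only the first.  ``consulted_by`` maps a node to the nodes whose
    candidate computation must intersect with its symmetry set (directional
    for rotations: only the first node's set is consulted).  ``residual``
    holds the automorphisms not generated by the claimed structures; they
    are handled by canonical-form duplicate elimination.
    """

    automorphisms: list[Perm]
    reflection_classes: list[tuple[int, ...]] = field(default_factory=list)
    rotation_cycles: list[tuple[int, ...]] = field(default_factory=list)
    reflection_lists: dict[int, tuple[int, ...]] = field(default_factory=dict)
    consulted_by: dict[int, frozenset[int]] = field(default_factory=dict)
    residual: list[Perm] = field(default_factory=list)

    @property
    def order(self) -> int:
        return len(self.automorphisms)


def classify_symmetries(m: MotifSpec) -> SymmetryInfo:
    """Split the automorphism group into reflections, rotations and residual.

    Transposition automorphisms are grouped into reflection classes (group
    closure makes each connected component of the swap relation a clique of
    mutually swappable nodes).  Single-cycle automorphisms of length >= 3
    whose nodes are disjoint from every reflection class and every already
    claimed rotation are recorded as rotation cycles.  Automorphisms outside
    the subgroup generated by the claimed structures end up in ``residual``.
    """
    k = m.k
    auts = automorphisms(m)
    ident = tuple(range(1, k + 1))

    # reflection classes: union-find over transposition automorphisms
    parent = {i: i for i in range(1, k + 1)}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for p in auts:
        cyc = _cycles(p)
        if len(cyc) == 1 and len(cyc[0]) == 2:
            a, b = cyc[0]
            parent[find(a)] = find(b)

    groups: dict[int, list[int]] = {}
    for i in range(1, k + 1):
        groups.setdefault(find(i), []).append(i)
    reflection_classes = sorted(
        tuple(sorted(g)) for g in groups.values() if len(g) > 1
    )
    claimed = {n for cls in reflection_classes for n in cls}

    # rotation cycles: single-cycle automorphisms disjoint from everything claimed
    rotation_cycles: list[tuple[int, ...]] = []
    rotation_perms: list[Perm] = []
    for p in auts:
        if p == ident:
            continue
        cyc = _cycles(p)
        if len(cyc) != 1 or len(cyc[0]) < 3:
            continue
        nodes = set(cyc[0])
        if nodes & claimed:
            continue
        first = min(nodes)
        ordered = [first]
        cur = p[first - 1]
        while cur != first:
            ordered.append(cur)
            cur = p[cur - 1]
        rotation_cycles.append(tuple(ordered))
        rotation_perms.append(p)
        claimed |= nodes

    reflection_lists: dict[int, tuple[int, ...]] = {}
    consulted_by: dict[int, frozenset[int]] = {}
    for cls in reflection_classes:
        for n in cls:
            others = tuple(x for x in cls if x != n)
            reflection_lists[n] = others
            consulted_by[n] = frozenset(others)
    for cycle in rotation_cycles:
        first, rest = cycle[0], cycle[1:]
        reflection_lists[first] = tuple(sorted(rest))
        consulted_by[first] = frozenset(rest)
        for n in rest:
            reflection_lists[n] = (first,)

    generators: list[Perm] = []
    for cls in reflection_classes:
        for a, b in combinations(cls, 2):
            swap = list(ident)
            swap[a - 1], swap[b - 1] = b, a
            generators.append(tuple(swap))
    generators.extend(rotation_perms)
    generated = _closure(generators, k) if generators else {ident}
    residual = sorted(p for p in auts if p not in generated)

    return SymmetryInfo(
        automorphisms=auts,
        reflection_classes=reflection_classes,
        rotation_cycles=rotation_cycles,
        reflection_lists=reflection_lists,
        consulted_by=consulted_by,
        residual=residual,
    )


def canonical_instance(tup: tuple[str, ...], auts: list[Perm]) -> tuple[str, ...]:
    """Lexicographically smallest image of an instance tuple under the group.

    ``tup[i-1]`` is the network node mapped on motif node ``i``; applying an
    automorphism ``p`` moves that node to position ``p[i-1]``.  Node order is
    the numeric-aware order used everywhere else.
    """
    best: tuple[str, ...] | None = None
    best_key = None
    for p in auts:
        img: list[str] = [""] * len(tup)
        for i, nn in enumerate(tup):
            img[p[i] - 1] = nn
        key = tuple(node_key(x) for x in img)
        if best_key is None or key < best_key:
            best_key = key
            best = tuple(img)
    assert best is not None
    return best
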