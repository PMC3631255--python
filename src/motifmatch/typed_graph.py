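"""Edge-typed multigraphs with constant-time typed-adjacency lookups.

Every edge carries a declared link type.  Directed types are queried with
their upper-case name for the forward direction and the corresponding
lower-case letter for the reverse; undirected types answer the same set for
either spelling.  Two indexes are maintained incrementally so the matching
engines never scan edge lists:

* ``index_starts`` -- type key -> set of nodes from which an edge of that
  (oriented) key departs;
* ``index_neighbors`` -- (node, type key) -> set of typed neighbors.

Parallel edges between the same node pair are allowed if and only if their
types differ; an anti-parallel pair of the same directed type is stored as
two distinct edges.  Self-loops are rejected (motifs cannot match them).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Iterator


class GraphError(ValueError):
    """Invalid graph construction or query."""


class UnknownLinkTypeError(GraphError):
    """A type key was used that is not declared in the registry."""


def node_key(name: str):
    """Sort key for node identifiers: numeric-aware, deterministic.

    Purely numeric names compare by value (so "2" < "10"); everything else
    compares lexicographically after the numeric block.
    """
    if name.isdigit():
        return (0, int(name), name)
    return (1, 0, name)


def sorted_nodes(names: Iterable[str]) -> list[str]:
    return sorted(names, key=node_key)


class LinkTypeRegistry:
    """Declared link types, each a single upper-case letter plus a direction flag.

    Names are unique case-insensitively: the lower-case letter of a directed
    type always denotes its reverse and can never name a second type.
    """

    def __init__(self, entries: Iterable[tuple[str, bool]] = ()):
        self._directed: dict[str, bool] = {}
        for name, directed in entries:
            self.add(name, directed)

    def add(self, name: str, directed: bool) -> None:
        if len(name) != 1 or not name.isalpha() or not name.isupper():
            raise GraphError(
                f"link type name must be a single upper-case letter, got {name!r}"
            )
        if name in self._directed:
            raise GraphError(f"duplicate link type {name!r}")
        self._directed[name] = bool(directed)

    def names(self) -> list[str]:
        return sorted(self._directed)

    def __contains__(self, name: str) -> bool:
        return name in self._directed

    def __iter__(self) -> Iterator[tuple[str, bool]]:
        for name in self.names():
            yield name, self._directed[name]

    def is_directed(self, name: str) -> bool:
        if name not in self._directed:
            raise UnknownLinkTypeError(f"unknown link type {name}")
        return self._directed[name]

    def resolve(self, key: str) -> str:
        """Normalize a type key for index lookups.

        Upper-case keys must be declared.  Lower-case keys of directed types
        are kept as-is (they select the reverse index); lower-case keys of
        undirected types are aliased to the upper-case key with a warning.
        """
        if not key.isalpha() or len(key) != 1:
            raise UnknownLinkTypeError(f"unknown link type {key}")
        base = key.upper()
        if base not in self._directed:
            raise UnknownLinkTypeError(f"unknown link type {base}")
        if key.islower() and not self._directed[base]:
            warnings.warn(
                f"lower-case key {key!r} of undirected type {base!r}; using {base!r}",
                stacklevel=3,
            )
            return base
        return key


_EMPTY: frozenset = frozenset()


class TypedGraph:
    """A multigraph whose edges carry registered link types.

    Nodes are opaque strings.  The sets returned by :meth:`start_nodes_of_type`
    and :meth:`neighbors_of_type` are the live index entries (no copy is
    taken); callers must not mutate them.
    """

    def __init__(self, registry: LinkTypeRegistry):
        self.registry = registry
        self._nodes: set[str] = set()
        self._edges: set[tuple[str, str, str]] = set()
        self._starts: dict[str, set[str]] = {}
        self._nbrs: dict[tuple[str, str], set[str]] = {}
        self._pairs: set[frozenset[str]] = set()

    # -- construction ------------------------------------------------------

    def add_node(self, n: str) -> None:
        self._nodes.add(n)

    def add_link(self, u: str, v: str, t: str) -> bool:
        """Insert an edge of type ``t`` from ``u`` to ``v``; return True if new.

        Duplicate input edges are silently de-duplicated (idempotent); for
        undirected types both orientations denote the same edge.
        """
        if t not in self.registry:
            raise UnknownLinkTypeError(f"unknown link type {t}")
        if u == v:
            raise GraphError(f"self-loop {u!r} -> {v!r} rejected (type {t})")
        directed = self.registry.is_directed(t)
        if not directed and node_key(v) < node_key(u):
            u, v = v, u
        edge = (u, v, t)
        if edge in self._edges:
            return False
        self._edges.add(edge)
        self._nodes.add(u)
        self._nodes.add(v)
        self._pairs.add(frozenset((u, v)))
        if directed:
            self._starts.setdefault(t, set()).add(u)
            self._starts.setdefault(t.lower(), set()).add(v)
            self._nbrs.setdefault((u, t), set()).add(v)
            self._nbrs.setdefault((v, t.lower()), set()).add(u)
        else:
            self._starts.setdefault(t, set()).update((u, v))
            self._nbrs.setdefault((u, t), set()).add(v)
            self._nbrs.setdefault((v, t), set()).add(u)
        return True

    # -- queries -----------------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return self._nodes

    @property
    def edges(self) -> set[tuple[str, str, str]]:
        return self._edges

    def start_nodes_of_type(self, key: str):
        """All nodes from which an edge of the given (oriented) key departs."""
        return self._starts.get(self.registry.resolve(key), _EMPTY)

    def neighbors_of_type(self, n: str, key: str):
        """Typed neighbors of ``n``: out-neighbors for 'X', in-neighbors for
        'x', all partners for an undirected type."""
        if n not in self._nodes:
            raise GraphError(f"unknown node {n!r}")
        return self._nbrs.get((n, self.registry.resolve(key)), _EMPTY)

    def has_any_edge(self, u: str, v: str) -> bool:
        """True if any edge of any type joins ``u`` and ``v`` in either
        orientation (used by the induced matching mode)."""
        return frozenset((u, v)) in self._pairs

    def neighbor_entry_count(self) -> int:
        """Total adjacency entries; equals 2 * |edges| by construction."""
        return sum(len(s) for s in self._nbrs.values())
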