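"""Directed acyclic graph primitives shared by both network tracks.

A :class:`Dag` is the common currency of the directed-network pipeline:
structure search returns one, bootstrap model averaging thresholds into one,
and the synthetic generator is parameterized by one.  d-separation queries
let conditional-independence claims about a fitted or generating structure
be checked mechanically (chain, fork and collider motifs have distinct
blocking rules).
"""

from __future__ import annotations

import csv
import io
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "GraphInputError",
    "Dag",
    "UndirectedEdgeSet",
    "is_acyclic",
    "skeleton",
    "d_separated",
]


class GraphInputError(ValueError):
    """Raised for malformed graph inputs (undeclared nodes, cycles, ...)."""


def _check_arcs_declared(nodes: Sequence[str], arcs: Iterable[tuple[str, str]]) -> None:
    declared = set(nodes)
    for a, b in arcs:
        if a not in declared or b not in declared:
            raise GraphInputError(f"arc ({a!r}, {b!r}) references an undeclared node")


def is_acyclic(nodes: Sequence[str], arcs: Iterable[tuple[str, str]]) -> bool:
    """True iff the directed graph (nodes, arcs) contains no directed cycle.

    Kahn's algorithm; deterministic and O(V + E).
    """
    arcs = list(arcs)
    _check_arcs_declared(nodes, arcs)
    children: dict[str, list[str]] = {v: [] for v in nodes}
    indeg = {v: 0 for v in nodes}
    for a, b in arcs:
        children[a].append(b)
        indeg[b] += 1
    queue = deque(v for v in nodes if indeg[v] == 0)
    seen = 0
    while queue:
        v = queue.popleft()
        seen += 1
        for c in children[v]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    return seen == len(list(nodes))


@dataclass(frozen=True)
class UndirectedEdgeSet:
    """A set of unordered node pairs over a declared node universe."""

    nodes: tuple[str, ...]
    edges: frozenset[frozenset[str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        declared = set(self.nodes)
        for e in self.edges:
            if len(e) != 2:
                raise GraphInputError(f"edge {set(e)} is not an unordered pair")
            if not e <= declared:
                raise GraphInputError(f"edge {set(e)} references an undeclared node")

    @staticmethod
    def from_pairs(nodes: Sequence[str], pairs: Iterable[tuple[str, str]]) -> "UndirectedEdgeSet":
        return UndirectedEdgeSet(tuple(nodes), frozenset(frozenset(p) for p in pairs))

    def __contains__(self, pair: Iterable[str]) -> bool:
        return frozenset(pair) in self.edges

    def __len__(self) -> int:
        return len(self.edges)

    def sorted_pairs(self) -> list[tuple[str, str]]:
        """Edges as (a, b) tuples ordered by the declared node order."""
        order = {v: i for i, v in enumerate(self.nodes)}
        out = [tuple(sorted(e, key=order.__getitem__)) for e in self.edges]
        return sorted(out, key=lambda p: (order[p[0]], order[p[1]]))


@dataclass(frozen=True)
class Dag:
    """A directed acyclic graph over an ordered node sequence.

    The node order is canonical (it mirrors the column order of the data
    table) and is used for all deterministic tie-breaking downstream.
    Invariants checked on construction: no self-arcs, no pair present in
    both orientations, all endpoints declared, no directed cycle.
    """

    nodes: tuple[str, ...]
    arcs: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise GraphInputError("duplicate node names")
        _check_arcs_declared(self.nodes, self.arcs)
        for a, b in self.arcs:
            if a == b:
                raise GraphInputError(f"self-arc on {a!r}")
            if (b, a) in self.arcs:
                raise GraphInputError(f"both orientations present for pair ({a!r}, {b!r})")
        if not is_acyclic(self.nodes, self.arcs):
            raise GraphInputError("arc set contains a directed cycle")

    @staticmethod
    def from_arcs(nodes: Sequence[str], arcs: Iterable[tuple[str, str]]) -> "Dag":
        return Dag(tuple(nodes), frozenset(tuple(a) for a in arcs))

    # -- basic queries -------------------------------------------------

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(a for a, b in self.sorted_arcs() if b == node)

    def children(self, node: str) -> tuple[str, ...]:
        return tuple(b for a, b in self.sorted_arcs() if a == node)

    def sorted_arcs(self) -> list[tuple[str, str]]:
        order = {v: i for i, v in enumerate(self.nodes)}
        return sorted(self.arcs, key=lambda ab: (order[ab[0]], order[ab[1]]))

    def topological_order(self) -> tuple[str, ...]:
        """A topological order respecting the canonical node order among ties."""
        order = {v: i for i, v in enumerate(self.nodes)}
        indeg = {v: 0 for v in self.nodes}
        children: dict[str, list[str]] = {v: [] for v in self.nodes}
        for a, b in self.arcs:
            children[a].append(b)
            indeg[b] += 1
        ready = sorted((v for v in self.nodes if indeg[v] == 0), key=order.__getitem__)
        out: list[str] = []
        while ready:
            v = ready.pop(0)
            out.append(v)
            newly = []
            for c in children[v]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    newly.append(c)
            ready = sorted(ready + newly, key=order.__getitem__)
        return tuple(out)

    # -- serialization -------------------------------------------------

    def to_edgelist_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["parent", "child"])
        for a, b in self.sorted_arcs():
            w.writerow([a, b])
        return buf.getvalue()

    @staticmethod
    def from_edgelist_csv(text: str, nodes: Sequence[str]) -> "Dag":
        rows = list(csv.reader(io.StringIO(text)))
        if not rows or rows[0] != ["parent", "child"]:
            raise GraphInputError("expected header 'parent,child'")
        return Dag.from_arcs(nodes, [(r[0], r[1]) for r in rows[1:] if r])

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.sorted_arcs())
        return g

    def to_graphml(self, path: str) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def to_dot(self) -> str:
        lines = ["digraph {"] + [f'  "{v}";' for v in self.nodes]
        lines += [f'  "{a}" -> "{b}";' for a, b in self.sorted_arcs()]
        lines.append("}")
        return "\n".join(lines)


def skeleton(dag: Dag) -> UndirectedEdgeSet:
    """Direction-blind edge set of a DAG; one unordered pair per arc."""
    return UndirectedEdgeSet.from_pairs(dag.nodes, dag.arcs)


def d_separated(dag: Dag, x: str, y: str, conditioning_set: Iterable[str] = ()) -> bool:
    """Standard d-separation query on ``dag``.

    True iff every path between ``x`` and ``y`` is blocked given the
    conditioning set: chains and forks are blocked when their middle node is
    conditioned on; a collider opens only when the collider or one of its
    descendants is conditioned on.  Implemented as a reachability traversal
    over (node, direction-of-entry) states (Bayes-ball style), linear in the
    number of arcs per query.
    """
    z = set(conditioning_set)
    declared = set(dag.nodes)
    for v in (x, y, *z):
        if v not in declared:
            raise GraphInputError(f"unknown node {v!r}")
    if x == y:
        raise GraphInputError("x and y must differ")
    if x in z or y in z:
        raise GraphInputError("query nodes may not appear in the conditioning set")

    parents: dict[str, list[str]] = {v: [] for v in dag.nodes}
    children: dict[str, list[str]] = {v: [] for v in dag.nodes}
    for a, b in dag.arcs:
        children[a].append(b)
        parents[b].append(a)

    # nodes with a descendant (or themselves) in Z: these open colliders
    opens_collider = set(z)
    frontier = deque(z)
    while frontier:
        v = frontier.popleft()
        for p in parents[v]:
            if p not in opens_collider:
                opens_collider.add(p)
                frontier.append(p)

    # state: (node, came_from_child). Start at x as if entered from a child,
    # which permits leaving along both arc directions.
    start = (x, True)
    visited = {start}
    queue = deque([start])
    while queue:
        v, from_child = queue.popleft()
        if v == y:
            return False
        moves: list[tuple[str, bool]] = []
        if from_child:
            # entered against arc direction (or start): may go to parents and,
            # if not conditioned on, to children
            if v not in z:
                moves += [(c, False) for c in children[v]]
                moves += [(p, True) for p in parents[v]]
        else:
            # entered along arc direction (from a parent)
            if v not in z:
                moves += [(c, False) for c in children[v]]
            if v in opens_collider:
                moves += [(p, True) for p in parents[v]]
        for state in moves:
            if state not in visited:
                visited.add(state)
                queue.append(state)
    return True
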