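"""Labelled directed graphs and their Laplacian dynamics.

The central object is :class:`LinGraph`: vertices with labelled, directed
edges and no self-loops.  Treating every edge as a first-order mass-action
reaction with the label as rate constant gives the linear dynamics

    dx/dt = L(G) . x

where ``L(G)`` is the Laplacian matrix.  Sign convention (documented and
used everywhere in this package): for i != j, ``L[i, j]`` is the label of
edge j -> i, and ``L[j, j]`` is minus the sum of labels leaving j.  With
this orientation every *column* of L sums to zero, which expresses
conservation of the total amount of matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import sympy

from .labels import (
    LabelError,
    concentration_symbols,
    species_name,
    validate_label,
)

__all__ = [
    "LinGraph",
    "GraphError",
    "build_graph",
    "laplacian",
    "numeric_laplacian",
    "SCCDecomposition",
    "scc_decompose",
    "is_strongly_connected",
    "validate_uncoupling",
]


class GraphError(ValueError):
    """Raised for structurally invalid graphs."""


@dataclass(frozen=True)
class LinGraph:
    """A labelled directed graph with no self-loops.

    ``vertices`` is an ordered tuple of string identifiers; ``edges`` maps
    ordered pairs ``(source, target)`` to sympy label expressions.  At most
    one edge exists per ordered pair (parallel edges are merged by summing
    their labels at construction, since first-order fluxes are additive).
    """

    vertices: tuple[str, ...]
    edges: dict[tuple[str, str], sympy.Expr] = field(default_factory=dict)

    # -- basic queries -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.vertices)

    def index(self, v: str) -> int:
        return self.vertices.index(v)

    def label(self, source: str, target: str) -> sympy.Expr:
        return self.edges[(source, target)]

    def out_edges(self, v: str) -> list[tuple[str, str, sympy.Expr]]:
        return [(s, t, l) for (s, t), l in self.edges.items() if s == v]

    def in_edges(self, v: str) -> list[tuple[str, str, sympy.Expr]]:
        return [(s, t, l) for (s, t), l in self.edges.items() if t == v]

    def has_edge(self, source: str, target: str) -> bool:
        return (source, target) in self.edges

    def is_numeric(self) -> bool:
        return all(not l.free_symbols for l in self.edges.values())

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.vertices)
        for (s, t), l in self.edges.items():
            g.add_edge(s, t, label=l)
        return g

    def substitute(self, subs: Mapping) -> "LinGraph":
        """A new graph with symbol substitutions applied to every label."""
        new = {k: sympy.sympify(l).subs(subs) for k, l in self.edges.items()}
        return LinGraph(self.vertices, new)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"LinGraph({self.n} vertices, {len(self.edges)} edges)"


def build_graph(
    vertices: Sequence[str],
    edge_triples: Iterable[tuple[str, str, object]],
    *,
    validate: bool = True,
) -> LinGraph:
    """Construct a :class:`LinGraph` from vertex names and edge triples.

    Parallel edges are merged by summing labels.  Self-loops and edges to
    undeclared vertices are construction errors.  Labels are validated for
    sampled positivity unless ``validate=False`` (used internally for
    graphs whose labels are positive by construction).
    """
    vertices = tuple(str(v) for v in vertices)
    if len(set(vertices)) != len(vertices):
        raise GraphError("duplicate vertex identifiers")
    vset = set(vertices)
    edges: dict[tuple[str, str], sympy.Expr] = {}
    for s, t, lab in edge_triples:
        s, t = str(s), str(t)
        if s == t:
            raise GraphError(f"self-loop at vertex {s!r} is not allowed")
        if s not in vset or t not in vset:
            raise GraphError(f"edge ({s!r}, {t!r}) has an undeclared endpoint")
        expr = sympy.sympify(lab, rational=True)
        key = (s, t)
        edges[key] = edges[key] + expr if key in edges else expr
    if validate:
        for key, expr in edges.items():
            try:
                validate_label(expr)
            except LabelError as exc:
                raise GraphError(f"invalid label on edge {key}: {exc}") from None
    return LinGraph(vertices, edges)


# -- Laplacian ---------------------------------------------------------


def laplacian(G: LinGraph) -> sympy.Matrix:
    """The Laplacian matrix of ``G`` (columns sum to zero).

    Edge j -> i with label a contributes +a to L[i, j] and -a to L[j, j],
    so that dx/dt = L.x is the mass-action dynamics of the edges.
    """
    n = G.n
    idx = {v: i for i, v in enumerate(G.vertices)}
    L = sympy.zeros(n, n)
    for (s, t), lab in G.edges.items():
        j, i = idx[s], idx[t]
        L[i, j] += lab
        L[j, j] -= lab
    return L


def numeric_laplacian(G: LinGraph, subs: Mapping | None = None) -> np.ndarray:
    """Float Laplacian; all labels must be numeric after ``subs``."""
    n = G.n
    idx = {v: i for i, v in enumerate(G.vertices)}
    L = np.zeros((n, n))
    for (s, t), lab in G.edges.items():
        if subs:
            lab = sympy.sympify(lab).subs(subs)
        val = float(lab)
        j, i = idx[s], idx[t]
        L[i, j] += val
        L[j, j] -= val
    return L


# -- strongly connected components ------------------------------------


@dataclass(frozen=True)
class SCCDecomposition:
    """Partition of the vertices into strongly connected components.

    ``components`` are ordered by their smallest contained vertex index;
    ``condensation`` is the acyclic SCC-level digraph (edges as index
    pairs into ``components``); ``terminal_flags[k]`` is True iff
    component k has no outgoing condensation edge.
    """

    components: tuple[tuple[str, ...], ...]
    condensation: tuple[tuple[int, int], ...]
    terminal_flags: tuple[bool, ...]

    @property
    def terminal_components(self) -> tuple[tuple[str, ...], ...]:
        return tuple(
            c for c, t in zip(self.components, self.terminal_flags) if t
        )


def scc_decompose(G: LinGraph) -> SCCDecomposition:
    g = G.to_networkx()
    order = {v: i for i, v in enumerate(G.vertices)}
    comps = [
        tuple(sorted(c, key=order.get))
        for c in nx.strongly_connected_components(g)
    ]
    comps.sort(key=lambda c: order[c[0]])
    comp_of = {v: k for k, c in enumerate(comps) for v in c}
    cond = sorted(
        {
            (comp_of[s], comp_of[t])
            for (s, t) in G.edges
            if comp_of[s] != comp_of[t]
        }
    )
    outgoing = {a for a, _ in cond}
    terminal = tuple(k not in outgoing for k in range(len(comps)))
    return SCCDecomposition(tuple(comps), tuple(cond), terminal)


def is_strongly_connected(G: LinGraph) -> bool:
    """True iff any vertex reaches any other along directed edges (a
    single-vertex graph counts as strongly connected)."""
    if G.n <= 1:
        return True
    return nx.is_strongly_connected(G.to_networkx())


# -- uncoupling condition ---------------------------------------------


def validate_uncoupling(
    G: LinGraph, species_of_vertex: Mapping[str, str]
) -> list[tuple[tuple[str, str], str]]:
    """Check the uncoupling condition.

    A concentration appearing in an edge label must not be the
    concentration of a species represented by a graph vertex; otherwise
    the Laplacian dynamics would not be linear.  Returns every violating
    ``(edge, species)`` pair; an empty list means the condition holds.
    """
    vertex_species = set(species_of_vertex.values())
    violations = []
    for key, lab in G.edges.items():
        for sym in sorted(concentration_symbols(lab), key=lambda s: s.name):
            sp = species_name(sym)
            if sp in vertex_species:
                violations.append((key, sp))
    return violations
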