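"""Detailed balance: cycle condition, path equilibria, free energies.

At thermodynamic equilibrium every edge must be reversible and every
pair of reversible edges i <-> j balances independently:
x_j * a = x_i * b, where a labels i -> j and b labels j -> i.  The
equilibrium constant of the pair is K_ij = a / b.  Detailed balance cuts
the rooted trees of the Matrix-Tree Theorem down to a single path: the
equilibrium ratio x_i / x_ref is the product of equilibrium constants
along any reversible path from the reference, and path-independence is
equivalent to the *cycle condition* -- around every cycle the product of
clockwise rate constants equals the product of counterclockwise ones.

Free energies enter through van't Hoff's relation.  Convention used
throughout (a self-consistent choice, documented rather than imposed):

    K_ij = exp(-(G_j - G_i) / RT)

so lower-energy microstates get higher equilibrium occupancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import sympy

from .graph import GraphError, LinGraph, is_strongly_connected
from .steady_state import SteadyState

__all__ = [
    "check_all_reversible",
    "CycleReport",
    "check_cycle_condition",
    "equilibrium_via_path",
    "EnergyModel",
    "labels_from_energies",
    "energies_from_equilibrium",
]


def check_all_reversible(G: LinGraph) -> bool:
    """True iff every edge i -> j has a partner j -> i."""
    return all((t, s) in G.edges for (s, t) in G.edges)


def equilibrium_constant(G: LinGraph, i: str, j: str) -> sympy.Expr:
    """K_ij = label(i -> j) / label(j -> i) for a reversible pair."""
    if not (G.has_edge(i, j) and G.has_edge(j, i)):
        raise GraphError(f"edge pair {i!r} <-> {j!r} is not reversible")
    return sympy.cancel(G.label(i, j) / G.label(j, i))


@dataclass(frozen=True)
class CycleReport:
    """Result of a cycle-condition check over a fundamental cycle basis."""

    cycles: tuple[tuple[str, ...], ...]
    ratios: tuple[sympy.Expr, ...]
    passed: bool
    failures: tuple[int, ...] = ()


def _undirected_pair_graph(G: LinGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(G.vertices)
    for (s, t) in G.edges:
        if (t, s) in G.edges:
            g.add_edge(*sorted((s, t), key=G.vertices.index))
    return g


def check_cycle_condition(G: LinGraph, tolerance: float = 1e-9) -> CycleReport:
    """Verify the cycle condition over a fundamental cycle basis.

    A spanning forest of the (undirected) reversible-pair graph induces
    one fundamental cycle per non-tree pair; any cycle is a composition
    of basis cycles, so checking the basis suffices.  Symbolic labels
    are compared exactly, numeric ones to relative ``tolerance``.
    """
    if not check_all_reversible(G):
        raise GraphError("cycle condition requires an all-reversible graph")
    und = _undirected_pair_graph(G)
    tree_edges: set[frozenset] = set()
    parent: dict[str, str | None] = {}
    for comp in nx.connected_components(und):
        root = min(comp, key=G.vertices.index)
        parent[root] = None
        for u, v in nx.bfs_edges(und, root):
            parent[v] = u
            tree_edges.add(frozenset((u, v)))

    def path_to_root(v: str) -> list[str]:
        path = [v]
        while parent[path[-1]] is not None:
            path.append(parent[path[-1]])
        return path

    cycles, ratios, failures = [], [], []
    for u, v in sorted(und.edges, key=lambda e: tuple(map(G.vertices.index, e))):
        if frozenset((u, v)) in tree_edges:
            continue
        pu, pv = path_to_root(u), path_to_root(v)
        common = set(pu) & set(pv)
        pu = pu[: next(i for i, x in enumerate(pu) if x in common) + 1]
        anchor = pu[-1]
        pv = pv[: pv.index(anchor) + 1]
        # fundamental cycle as a vertex sequence: u .. anchor .. v, closed by v -> u
        seq = pu + pv[-2::-1]
        seq.append(u)
        ratio = sympy.Integer(1)
        for a, b in zip(seq[:-1], seq[1:]):
            ratio *= G.label(a, b) / G.label(b, a)
        ratio = sympy.cancel(ratio)
        cycles.append(tuple(seq))
        ratios.append(ratio)
        if ratio.free_symbols:
            ok = sympy.simplify(ratio - 1) == 0
        else:
            ok = abs(float(ratio) - 1.0) <= tolerance
        if not ok:
            failures.append(len(cycles) - 1)
    return CycleReport(
        tuple(cycles), tuple(ratios), passed=not failures, failures=tuple(failures)
    )


def equilibrium_via_path(
    G: LinGraph, reference_vertex: str | None = None, tolerance: float = 1e-9
) -> SteadyState:
    """Equilibrium state by multiplying K along paths from the reference.

    Requires an all-reversible, strongly connected graph satisfying the
    cycle condition (otherwise the result would depend on the path).
    Returns the reference-normalised steady state whose entries are
    single-monomial ratios, in contrast to the MTT's polynomial sums.
    """
    if not is_strongly_connected(G):
        raise GraphError("equilibrium_via_path requires strong connectivity")
    report = check_cycle_condition(G, tolerance)
    if not report.passed:
        bad = [report.cycles[i] for i in report.failures]
        raise GraphError(
            f"cycle condition fails (path-dependent result) on cycles: {bad}"
        )
    ref = reference_vertex if reference_vertex is not None else G.vertices[0]
    und = _undirected_pair_graph(G)
    values = {ref: sympy.Integer(1)}
    for u, v in nx.bfs_edges(und, ref):
        values[v] = sympy.cancel(values[u] * G.label(u, v) / G.label(v, u))
    vals = tuple(values[v] for v in G.vertices)
    return SteadyState(G.vertices, vals, "reference", vals, reference_vertex=ref)


@dataclass(frozen=True)
class EnergyModel:
    """Gibbs free energies of microstates relative to a reference.

    ``energies`` maps each vertex to its free energy (units of RT if
    ``RT == 1``, else energy/mol); the reference vertex has energy 0.
    """

    energies: Mapping[str, float]
    RT: float = 1.0
    reference: str | None = None

    def __post_init__(self):
        ref = self.reference
        if ref is None:
            ref = min(self.energies, key=lambda v: abs(self.energies[v]))
        if abs(self.energies[ref]) > 1e-12:
            raise GraphError("reference microstate must have zero free energy")


def labels_from_energies(
    model: EnergyModel,
    kinetic_scales: Mapping[tuple[str, str], float],
    vertices: Sequence[str] | None = None,
) -> LinGraph:
    """Build a reversible graph whose equilibrium is the Boltzmann one.

    Detailed balance fixes only label *ratios*; each reversible pair
    (i, j) additionally needs a positive kinetic scale omega.  The pair
    is labelled symmetrically,

        a(i->j) = omega * exp(-(G_j - G_i) / 2RT)
        b(j->i) = omega * exp(+(G_j - G_i) / 2RT)

    so K_ij = exp(-(G_j - G_i)/RT) and the cycle condition holds by
    construction (the labels derive from a vertex potential).
    """
    if vertices is None:
        vertices = list(model.energies)
    missing = [v for v in vertices if v not in model.energies]
    if missing:
        raise GraphError(f"missing free energies for vertices: {missing}")
    triples = []
    for (i, j), omega in kinetic_scales.items():
        if omega <= 0:
            raise GraphError(f"kinetic scale for pair ({i}, {j}) must be positive")
        dG = (model.energies[j] - model.energies[i]) / model.RT
        triples.append((i, j, sympy.Float(omega * math.exp(-dG / 2))))
        triples.append((j, i, sympy.Float(omega * math.exp(+dG / 2))))
    return LinGraph(
        tuple(vertices),
        {(s, t): l for s, t, l in triples},
    )


def energies_from_equilibrium(
    state: SteadyState, RT: float = 1.0
) -> dict[str, float]:
    """Read free energies back from a reference-normalised equilibrium:
    G_i = -RT ln(x_i / x_ref), zero at the reference."""
    out = {}
    for v, val in state.as_dict().items():
        out[v] = -RT * math.log(float(val))
    return out
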