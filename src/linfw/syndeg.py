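"""Zero-order synthesis and first-order degradation: the ∗-graph trick.

A *partial graph* is a core labelled directed graph G whose vertices may
additionally carry synthesis half-edges (zero-order rate s_i, units
concentration/time) and/or degradation half-edges (first-order rate d_i,
1/time).  The dynamics is non-homogeneous,

    dx/dt = L(G).x + S - Delta.x,

with S the synthesis vector and Delta = diag(d).  Adding a new vertex
``*`` with edges * -> i (label s_i) and i -> * (label d_i) turns the
partial graph into an ordinary labelled directed graph whose Laplacian
dynamics reproduce the partial dynamics on the slice x_* = 1.  When the
augmented graph is strongly connected, no component blows up and the
unique steady state is

    x_i = rho#_i / rho#_*

with rho# the MTT kernel vector of the augmented graph.  At any steady
state, synthesis and degradation balance overall: sum_i s_i =
sum_i d_i x_i (a consequence of the columns of L summing to zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import sympy

from .graph import (
    GraphError,
    LinGraph,
    is_strongly_connected,
    numeric_laplacian,
    scc_decompose,
)
from .matrix_tree import rho_mtt

__all__ = [
    "STAR",
    "PartialGraph",
    "augment",
    "steady_state_syn_deg",
    "check_balance",
    "detect_unbounded",
]

STAR = "*"


@dataclass(frozen=True)
class PartialGraph:
    """Core graph plus synthesis/degradation half-edges.

    Any vertex may have synthesis, degradation, both or neither; rates
    must be positive where present.  ``*`` is reserved for the
    augmentation vertex.
    """

    core: LinGraph
    synthesis: dict[str, sympy.Expr] = field(default_factory=dict)
    degradation: dict[str, sympy.Expr] = field(default_factory=dict)

    def __post_init__(self):
        if STAR in self.core.vertices:
            raise GraphError(f"vertex name {STAR!r} is reserved")
        for table, what in ((self.synthesis, "synthesis"),
                            (self.degradation, "degradation")):
            for v, r in table.items():
                if v not in self.core.vertices:
                    raise GraphError(f"{what} rate on unknown vertex {v!r}")
                expr = sympy.sympify(r)
                if not expr.free_symbols and float(expr) <= 0:
                    raise GraphError(
                        f"{what} rate at {v!r} must be positive (omit the "
                        "half-edge instead of using zero)"
                    )


def augment(pg: PartialGraph) -> LinGraph:
    """The augmented ∗-graph: core edges plus * -> i (s_i), i -> * (d_i).

    Removing ``*`` and its edges recovers the core.  The augmented graph
    is strongly connected whenever the core is and at least one
    synthesis and one degradation edge exist -- but it may be strongly
    connected even when the core is not.
    """
    vertices = pg.core.vertices + (STAR,)
    edges = dict(pg.core.edges)
    for v, s in pg.synthesis.items():
        edges[(STAR, v)] = sympy.sympify(s)
    for v, d in pg.degradation.items():
        edges[(v, STAR)] = sympy.sympify(d)
    return LinGraph(vertices, edges)


def steady_state_syn_deg(pg: PartialGraph) -> dict[str, sympy.Expr]:
    """The unique steady state x_i = rho#_i / rho#_* of the partial
    dynamics, via the MTT on the augmented graph.

    Requires the augmented graph to be strongly connected (the
    sufficient condition for boundedness); all entries are positive and
    x satisfies L(G).x + S - Delta.x = 0.
    """
    aug = augment(pg)
    if not is_strongly_connected(aug):
        raise GraphError(
            "augmented graph is not strongly connected; boundedness of the "
            "steady state cannot be certified by this construction"
        )
    rho = rho_mtt(aug)
    star = rho[aug.index(STAR)]
    return {
        v: sympy.cancel(rho[aug.index(v)] / star)
        for v in pg.core.vertices
    }


def check_balance(
    pg: PartialGraph, x: Mapping[str, float], tol: float = 1e-9
) -> bool:
    """Overall balance sum_i s_i = sum_i d_i * x_i at a candidate steady
    state (holds automatically for :func:`steady_state_syn_deg` output)."""
    syn = sum(float(sympy.sympify(s)) for s in pg.synthesis.values())
    deg = sum(
        float(sympy.sympify(d)) * float(x[v]) for v, d in pg.degradation.items()
    )
    scale = max(abs(syn), abs(deg), 1.0)
    return abs(syn - deg) <= tol * scale


def detect_unbounded(pg: PartialGraph) -> dict:
    """Diagnose whether the partial dynamics has a bounded positive
    steady state (numeric rates required).

    If the augmented graph is strongly connected the state is bounded
    (sufficient condition).  Otherwise a spectral check is applied to
    L - Delta restricted to the synthesis-reachable vertices: an
    eigenvalue with nonnegative real part there means degradation cannot
    absorb the inflow and some component grows without bound.  The
    spectral branch extends the strong-connectivity criterion and is
    flagged as such in the report.
    """
    aug = augment(pg)
    if is_strongly_connected(aug):
        return {"bounded": True, "criterion": "augmented strong connectivity"}
    import networkx as nx

    if not pg.synthesis:
        # no inflow: pure Laplacian + decay, always bounded
        return {"bounded": True, "criterion": "no synthesis"}
    g = pg.core.to_networkx()
    reachable: set[str] = set()
    for v in pg.synthesis:
        reachable |= {v} | nx.descendants(g, v)
    order = [v for v in pg.core.vertices if v in reachable]
    idx = {v: i for i, v in enumerate(pg.core.vertices)}
    L = numeric_laplacian(pg.core)
    sel = [idx[v] for v in order]
    M = L[np.ix_(sel, sel)]
    for j, v in enumerate(order):
        if v in pg.degradation:
            M[j, j] -= float(sympy.sympify(pg.degradation[v]))
    eigs = np.linalg.eigvals(M)
    unbounded = bool(np.max(eigs.real) > -1e-12)
    return {
        "bounded": not unbounded,
        "criterion": "spectral check on synthesis-reachable subsystem "
                     "(extension beyond the strong-connectivity condition)",
        "max_real_eigenvalue": float(np.max(eigs.real)),
        "reachable_vertices": order,
    }
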