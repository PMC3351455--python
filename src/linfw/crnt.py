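"""Chemical reaction network theory: the complex graph and the
Laplacian decomposition of mass-action kinetics.

A network N of reactions under mass-action kinetics has species-level
dynamics dx/dt = f(x).  Treating each reaction side as a "complex" gives
a labelled directed graph G_N on the distinct complexes, and f factors
through its Laplacian:

    f(x) = Y . L(G_N) . Psi(x)

where Y records the stoichiometry of each species in each complex and
Psi(x) is the vector of mass-action monomials, one per complex.  A state
x with L(G_N).Psi(x) = 0 is *complex-balanced*; it is automatically a
steady state (Y.0 = 0) but not conversely.

This module doubles as the package's mass-action ODE engine: the
enzyme-kinetics, PTM and ligand-binding oracles assemble their full
nonlinear dynamics as a :class:`ReactionNetwork` and integrate it here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.integrate
import sympy

from .graph import GraphError, LinGraph, numeric_laplacian

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "build_complex_graph",
    "mass_action_field",
    "verify_decomposition",
    "check_complex_balanced",
    "integrate_to_steady_state",
]


@dataclass(frozen=True)
class Reaction:
    """reactants -> products with mass-action rate constant k.

    Stoichiometries are nonnegative-integer maps; either side may be
    empty (zero-order synthesis / plain degradation)."""

    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    k: float

    @staticmethod
    def make(reactants: Mapping[str, int], products: Mapping[str, int], k: float):
        r = tuple(sorted((s, int(c)) for s, c in reactants.items() if c))
        p = tuple(sorted((s, int(c)) for s, c in products.items() if c))
        if any(c < 0 for _, c in r + p):
            raise GraphError("stoichiometries must be nonnegative integers")
        if r == p:
            raise GraphError(
                f"reaction with identical reactant and product complex {dict(r)}"
            )
        return Reaction(r, p, float(k))


@dataclass(frozen=True)
class ReactionNetwork:
    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]

    @staticmethod
    def make(
        species: Sequence[str],
        reactions: Sequence[tuple[Mapping[str, int], Mapping[str, int], float]],
    ) -> "ReactionNetwork":
        species = tuple(species)
        known = set(species)
        rxns = []
        for reac, prod, k in reactions:
            for s in list(reac) + list(prod):
                if s not in known:
                    raise GraphError(f"undeclared species {s!r} in reaction")
            rxns.append(Reaction.make(reac, prod, k))
        return ReactionNetwork(species, tuple(rxns))


def _complex_name(stoich: tuple[tuple[str, int], ...]) -> str:
    if not stoich:
        return "0"
    return "+".join(s if c == 1 else f"{c}{s}" for s, c in stoich)


def build_complex_graph(net: ReactionNetwork):
    """The complex graph G_N, the stoichiometry map Y and the monomial
    map Psi.

    Returns ``(G, Y, psi)``: G is a :class:`LinGraph` whose vertices are
    the distinct complexes (named like ``"E+S"``, ``"2A"``, ``"0"`` for
    the empty complex), Y is the (n_species x n_complexes) integer
    matrix, and ``psi(x)`` maps a species-concentration vector to the
    vector of mass-action monomials prod_s x_s^(stoich of s).
    """
    complexes: list[tuple[tuple[str, int], ...]] = []
    seen: dict[tuple, int] = {}
    for rx in net.reactions:
        for side in (rx.reactants, rx.products):
            if side not in seen:
                seen[side] = len(complexes)
                complexes.append(side)
    names = [_complex_name(c) for c in complexes]
    if len(set(names)) != len(names):  # pragma: no cover - defensive
        raise GraphError("complex naming collision")
    triples = [
        (
            names[seen[rx.reactants]],
            names[seen[rx.products]],
            sympy.Float(rx.k) if isinstance(rx.k, float) else sympy.sympify(rx.k),
        )
        for rx in net.reactions
    ]
    # parallel reactions between the same complexes merge additively
    edges: dict[tuple[str, str], sympy.Expr] = {}
    for s, t, l in triples:
        edges[(s, t)] = edges.get((s, t), sympy.Integer(0)) + l
    G = LinGraph(tuple(names), edges)
    sidx = {s: i for i, s in enumerate(net.species)}
    Y = np.zeros((len(net.species), len(complexes)))
    for j, comp in enumerate(complexes):
        for s, c in comp:
            Y[sidx[s], j] = c
    exponents = np.zeros_like(Y)
    exponents[:, :] = Y

    def psi(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.prod(x[:, None] ** exponents, axis=0)

    return G, Y, psi


def mass_action_field(net: ReactionNetwork):
    """f(x): the species-level mass-action vector field, assembled
    reaction by reaction (independently of the Laplacian route)."""
    sidx = {s: i for i, s in enumerate(net.species)}
    terms = []
    for rx in net.reactions:
        order = [(sidx[s], c) for s, c in rx.reactants]
        delta = np.zeros(len(net.species))
        for s, c in rx.reactants:
            delta[sidx[s]] -= c
        for s, c in rx.products:
            delta[sidx[s]] += c
        terms.append((rx.k, order, delta))

    def f(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for k, order, delta in terms:
            v = k
            for i, c in order:
                v *= x[i] ** c
            out += v * delta
        return out

    return f


def verify_decomposition(
    net: ReactionNetwork,
    *,
    n_points: int = 100,
    rng: np.random.Generator | None = None,
    tol: float = 1e-10,
) -> dict:
    """Check f(x) = Y.L(G_N).Psi(x) at random positive states.

    The left side is assembled directly from the reactions; the right
    side goes through the complex graph.  Returns a report with the
    worst absolute deviation (relative to the magnitude of f) and the
    worst-case state.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    f = mass_action_field(net)
    G, Y, psi = build_complex_graph(net)
    L = numeric_laplacian(G)
    worst, worst_x = 0.0, None
    for _ in range(n_points):
        x = 10.0 ** rng.uniform(-1, 1, size=len(net.species))
        lhs = f(x)
        rhs = Y @ (L @ psi(x))
        scale = max(np.abs(lhs).max(), 1.0)
        dev = np.abs(lhs - rhs).max() / scale
        if dev > worst:
            worst, worst_x = dev, x
    return {
        "passed": worst < tol,
        "max_relative_deviation": worst,
        "worst_state": worst_x,
        "n_points": n_points,
    }


def check_complex_balanced(
    net: ReactionNetwork, x: Sequence[float], tol: float = 1e-8
) -> bool:
    """True iff L(G_N).Psi(x) vanishes (to relative ``tol``) at x."""
    G, _, psi = build_complex_graph(net)
    L = numeric_laplacian(G)
    v = psi(np.asarray(x, dtype=float))
    scale = max(np.abs(L).max() * np.abs(v).max(), 1.0)
    return bool(np.abs(L @ v).max() <= tol * scale)


def integrate_to_steady_state(
    net: ReactionNetwork,
    x0: Sequence[float],
    *,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    deriv_tol: float = 1e-10,
    t_max: float = 1e10,
) -> np.ndarray:
    """Integrate the full nonlinear mass-action ODE until the derivative
    is negligible.  Used as the independent oracle throughout."""
    f = mass_action_field(net)
    x = np.asarray(x0, dtype=float)
    t = 1.0
    while t <= t_max:
        sol = scipy.integrate.solve_ivp(
            lambda _, y: f(y), (0.0, t), x, method="LSODA", rtol=rtol, atol=atol
        )
        if not sol.success:
            raise RuntimeError(f"ODE integration failed: {sol.message}")
        x = sol.y[:, -1]
        if np.abs(f(x)).max() < deriv_tol * max(np.abs(x).max(), 1.0):
            return x
        t *= 10.0
    raise RuntimeError("mass-action integration did not reach steady state")
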