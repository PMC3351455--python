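"""Steady-state normalisations and the numeric ODE oracle.

A strongly connected graph has a one-dimensional kernel spanned by the
MTT vector rho, so any steady state is x = lambda * rho.  The free
scalar is removed in one of two ways:

1. *reference normalisation* -- divide by the entry at a reference
   vertex (conventionally vertex 1): x_i / x_ref = rho_i / rho_ref;
2. *total normalisation* -- divide by the sum and multiply by the total
   amount x_tot: x_i = x_tot * rho_i / sum_j rho_j.

Both turn the symbolic kernel vector into the rational expressions that
appear in every elimination formula downstream (rate laws, mod-form
distributions, microstate probabilities).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.integrate
import sympy

from .graph import GraphError, LinGraph, numeric_laplacian

__all__ = [
    "SteadyState",
    "normalize_reference",
    "normalize_total",
    "steady_state_numeric",
]


@dataclass(frozen=True)
class SteadyState:
    """A normalised symbolic steady state over a vertex order."""

    vertices: tuple[str, ...]
    raw: tuple[sympy.Expr, ...]
    mode: str  # "reference" | "total"
    values: tuple[sympy.Expr, ...]
    reference_vertex: str | None = None
    total_symbol: sympy.Expr | None = None

    def __getitem__(self, vertex: str) -> sympy.Expr:
        return self.values[self.vertices.index(vertex)]

    def as_dict(self) -> dict[str, sympy.Expr]:
        return dict(zip(self.vertices, self.values))


def normalize_reference(
    rho: Sequence[sympy.Expr],
    vertices: Sequence[str],
    reference_vertex: str | None = None,
) -> SteadyState:
    """x_i / x_ref = rho_i / rho_ref, simplified by cancellation.

    The reference defaults to the first vertex.  A zero reference entry
    (possible only for non-strongly-connected inputs) is an error.
    """
    vertices = tuple(vertices)
    rho = tuple(sympy.sympify(r) for r in rho)
    ref = reference_vertex if reference_vertex is not None else vertices[0]
    ref_val = rho[vertices.index(ref)]
    if ref_val == 0:
        raise GraphError(
            f"reference vertex {ref!r} has zero kernel entry; pick a vertex "
            "inside a terminal SCC or use the total normalisation"
        )
    values = tuple(sympy.cancel(r / ref_val) for r in rho)
    return SteadyState(vertices, rho, "reference", values, reference_vertex=ref)


def normalize_total(
    rho: Sequence[sympy.Expr],
    vertices: Sequence[str],
    x_tot: sympy.Expr | float = sympy.Symbol("x_tot", positive=True),
) -> SteadyState:
    """x_i = x_tot * rho_i / sum_j rho_j; the values sum to x_tot."""
    vertices = tuple(vertices)
    rho = tuple(sympy.sympify(r) for r in rho)
    total = sympy.Add(*rho)
    if total == 0:
        raise GraphError("kernel vector sums to zero; invalid input")
    x_tot = sympy.sympify(x_tot)
    values = tuple(sympy.cancel(x_tot * r / total) for r in rho)
    return SteadyState(vertices, rho, "total", values, total_symbol=x_tot)


def steady_state_numeric(
    G: LinGraph,
    initial_amounts: Sequence[float],
    *,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    deriv_tol: float = 1e-10,
    t_max: float = 1e12,
) -> np.ndarray:
    """Long-time integration of dx/dt = L.x from a nonnegative state.

    This is the package's independent numeric oracle: it never touches
    the Matrix-Tree machinery.  Integration proceeds in doubling time
    windows with a stiff-capable solver until the infinity norm of the
    derivative drops below ``deriv_tol`` times the norm of the state.
    """
    L = numeric_laplacian(G)
    x = np.asarray(initial_amounts, dtype=float)
    if x.shape != (G.n,):
        raise GraphError("initial_amounts length does not match vertex count")
    if np.any(x < 0):
        raise GraphError("initial amounts must be nonnegative")
    rates = np.abs(np.diag(L))
    scale = rates[rates > 0].max() if np.any(rates > 0) else 1.0
    t = 1.0 / scale
    while t <= t_max:
        sol = scipy.integrate.solve_ivp(
            lambda _, y: L @ y,
            (0.0, t),
            x,
            method="LSODA",
            jac=lambda _, y: L,
            rtol=rtol,
            atol=atol,
        )
        if not sol.success:
            raise RuntimeError(f"steady-state integration failed: {sol.message}")
        x = sol.y[:, -1]
        xnorm = np.abs(x).max()
        if np.abs(L @ x).max() < deriv_tol * max(xnorm, 1.0):
            return x
        t *= 8.0
    raise RuntimeError(
        "steady-state integration did not converge within the time cap"
    )
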