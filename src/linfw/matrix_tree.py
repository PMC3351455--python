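"""Matrix-Tree Theorem machinery.

For a strongly connected graph the kernel of the Laplacian is
one-dimensional and a canonical basis element rho is given by the
Matrix-Tree Theorem (Tutte's version): rho_i is the sum, over all
spanning trees rooted at vertex i, of the product of the edge labels in
the tree.  A spanning tree rooted at i contains every vertex, has no
cycles when edge directions are ignored, and i is its only vertex
without an outgoing tree edge.

Two independent routes are provided and each is the other's oracle:

* :func:`rho_mtt` -- explicit rooted-spanning-tree enumeration;
* :func:`rho_minor` -- the signed principal minor of the Laplacian.

For a general graph the kernel dimension equals the number of terminal
strongly connected components, and :func:`kernel_basis_general` builds
one basis vector per terminal SCC by applying the MTT to that SCC in
isolation and padding with zeros elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import sympy

from .graph import (
    GraphError,
    LinGraph,
    is_strongly_connected,
    laplacian,
    scc_decompose,
)

__all__ = [
    "RootedSpanningTree",
    "TreeCountError",
    "enumerate_rooted_spanning_trees",
    "rho_mtt",
    "rho_minor",
    "KernelBasis",
    "kernel_basis_general",
    "exprs_equal",
]


@dataclass(frozen=True)
class RootedSpanningTree:
    root: str
    edges: tuple[tuple[str, str], ...]


class TreeCountError(RuntimeError):
    """Raised when spanning-tree enumeration exceeds the configured cap."""


def enumerate_rooted_spanning_trees(
    G: LinGraph, root: str, *, cap: int = 10**6
) -> list[RootedSpanningTree]:
    """All spanning trees of ``G`` rooted at ``root``.

    Backtracking search: every non-root vertex picks exactly one of its
    out-edges; a partial assignment is rejected as soon as following the
    chosen pointers from the newly assigned vertex returns to it (which
    would close a cycle).  Complete, duplicate-free, and returned in a
    deterministic (lexicographic) order.  Returns the empty list when no
    tree exists (e.g. non-strongly-connected graphs for some roots).
    """
    if root not in G.vertices:
        raise GraphError(f"unknown root {root!r}")
    order = {v: i for i, v in enumerate(G.vertices)}
    non_root = [v for v in G.vertices if v != root]
    out: dict[str, list[str]] = {
        v: sorted((t for (s, t) in G.edges if s == v), key=order.get)
        for v in non_root
    }
    trees: list[RootedSpanningTree] = []
    choice: dict[str, str] = {}

    def closes_cycle(v: str, target: str) -> bool:
        seen = v
        cur = target
        while cur in choice:
            cur = choice[cur]
            if cur == seen:
                return True
        return False

    def recurse(k: int) -> None:
        if k == len(non_root):
            edges = tuple(
                sorted(choice.items(), key=lambda e: (order[e[0]], order[e[1]]))
            )
            trees.append(RootedSpanningTree(root, edges))
            if len(trees) > cap:
                raise TreeCountError(
                    f"more than {cap} spanning trees rooted at {root!r}"
                )
            return
        v = non_root[k]
        for t in out[v]:
            if not closes_cycle(v, t):
                choice[v] = t
                recurse(k + 1)
                del choice[v]

    recurse(0)
    return trees


def rho_mtt(G: LinGraph, *, cap: int = 10**6) -> list[sympy.Expr]:
    """The canonical kernel element of L(G) by rooted-tree enumeration.

    Requires strong connectivity; each entry is a polynomial in the
    labels with positive coefficients.
    """
    if not is_strongly_connected(G):
        raise GraphError(
            "rho_mtt requires a strongly connected graph; "
            "use kernel_basis_general for general graphs"
        )
    if G.n == 1:
        return [sympy.Integer(1)]
    rho = []
    for v in G.vertices:
        trees = enumerate_rooted_spanning_trees(G, v, cap=cap)
        total = sympy.Integer(0)
        for tree in trees:
            prod = sympy.Integer(1)
            for e in tree.edges:
                prod *= G.edges[e]
            total += prod
        rho.append(sympy.expand(total))
    return rho


def rho_minor(G: LinGraph, vertex: str) -> sympy.Expr:
    """Kernel entry at ``vertex`` as a signed principal minor of L(G).

    Deleting row and column i from the Laplacian and multiplying the
    determinant by (-1)^(n-1) yields rho_i; it agrees identically with
    the tree-enumeration route.
    """
    if not is_strongly_connected(G):
        raise GraphError(
            "rho_minor requires a strongly connected graph; "
            "use kernel_basis_general for general graphs"
        )
    if G.n == 1:
        return sympy.Integer(1)
    i = G.index(vertex)
    # float labels are lifted to exact rationals (losslessly) before the
    # Laplacian is assembled: the alternating signs of a determinant
    # cancel catastrophically in floating point for labels spanning many
    # decades, while tree sums never subtract
    L = laplacian(_rationalized(G))
    minor = L.minor_submatrix(i, i)
    return sympy.expand(sympy.Integer(-1) ** (G.n - 1) * minor.det(method="berkowitz"))


def _rationalized(G: LinGraph) -> LinGraph:
    return LinGraph(
        G.vertices,
        {
            k: l.xreplace({f: sympy.Rational(f) for f in l.atoms(sympy.Float)})
            for k, l in G.edges.items()
        },
    )


@dataclass(frozen=True)
class KernelBasis:
    """A basis of ker L(G): one vector per terminal SCC.

    Each vector is strictly positive (a positive-coefficient polynomial
    in the labels) on its terminal SCC and identically zero elsewhere.
    """

    vertices: tuple[str, ...]
    vectors: tuple[tuple[sympy.Expr, ...], ...]
    terminal_sccs: tuple[tuple[str, ...], ...]

    @property
    def dimension(self) -> int:
        return len(self.vectors)


def kernel_basis_general(G: LinGraph, *, cap: int = 10**6) -> KernelBasis:
    """Kernel basis for an arbitrary graph via terminal SCCs.

    The MTT is applied to each terminal SCC in isolation (only edges with
    both endpoints inside the SCC; a terminal SCC has no outgoing edges
    and incoming edges do not belong to it).  For a strongly connected
    graph this reduces to ``[rho_mtt(G)]``.
    """
    dec = scc_decompose(G)
    vectors = []
    terms = []
    for comp, terminal in zip(dec.components, dec.terminal_flags):
        if not terminal:
            continue
        cset = set(comp)
        sub = LinGraph(
            tuple(comp),
            {k: l for k, l in G.edges.items() if k[0] in cset and k[1] in cset},
        )
        sub_rho = dict(zip(sub.vertices, rho_mtt(sub, cap=cap)))
        vec = tuple(
            sub_rho.get(v, sympy.Integer(0)) for v in G.vertices
        )
        vectors.append(vec)
        terms.append(comp)
    return KernelBasis(G.vertices, tuple(vectors), tuple(terms))


def exprs_equal(a: sympy.Expr, b: sympy.Expr, *, term_cap: int = 2000) -> bool:
    """Symbolic equality of rational expressions.

    Small expressions (raw operation count <= ``term_cap``) are compared
    exactly by clearing denominators and expanding to canonical
    polynomial form.  Larger ones fall back to a documented exact-
    arithmetic probabilistic check: evaluation at random rational points
    (a nonzero rational function vanishes at a random point with
    probability ~0).
    """
    diff = sympy.sympify(a) - sympy.sympify(b)
    if sympy.count_ops(diff) <= term_cap:
        num, _ = sympy.fraction(sympy.together(diff))
        return sympy.expand(num) == 0
    rng = np.random.default_rng(12345)
    syms = sorted(diff.free_symbols, key=lambda s: s.name)
    for _ in range(4):
        pt = {
            s: sympy.Rational(int(rng.integers(1, 10**4)), int(rng.integers(1, 10**4)))
            for s in syms
        }
        val = diff.xreplace(pt)
        if not val.is_number:  # pragma: no cover - defensive
            val = sympy.simplify(val)
        if val != 0:
            return False
    return True
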