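"""Enzyme mechanisms, intermediate elimination and symbolic rate laws.

An enzyme mechanism is built from three basic reaction shapes:

* **bind**        E + S -> Y       (creation of an intermediate complex)
* **release**     Y -> E + S'      (break-up, releasing substrate or product)
* **convert**     Y -> Y'          (interconversion of intermediates)

Compiling a mechanism gives a labelled directed graph on the enzyme
states {free enzyme} + {intermediates}: edges leaving the free-enzyme
vertex absorb the concentrations of the slow substrate forms
(label k * [S]); all other edges carry bare rate constants.  The
uncoupling condition holds by construction.  Because bound states
release the enzyme eventually, the graph is strongly connected and the
Matrix-Tree Theorem eliminates the intermediates, which is exactly the
King-Altman procedure.  For the irreversible one-intermediate scheme
the familiar Michaelis-Menten law emerges:

    rate = k3 * E_tot * [S] / (K_M + [S]),   K_M = (k2 + k3)/k1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import sympy

from .crnt import ReactionNetwork
from .graph import GraphError, LinGraph, build_graph, is_strongly_connected, scc_decompose
from .labels import conc, concentration_symbols, rate, species_name
from .matrix_tree import rho_mtt
from .steady_state import normalize_reference, normalize_total

__all__ = [
    "EnzymeReaction",
    "MechanismSpec",
    "RateLaw",
    "compile_enzyme_graph",
    "steady_state_rate",
    "effective_rate_coefficient",
    "michaelis_menten_mechanism",
    "mechanism_network",
]


@dataclass(frozen=True)
class EnzymeReaction:
    """One basic reaction of a mechanism.

    kind = "bind":    source = free-enzyme state, target = intermediate,
                      species = bound substrate form (appears in the label);
    kind = "release": source = intermediate, target = free-enzyme state,
                      species = released substrate/product form;
    kind = "convert": source and target are intermediates, species is None.
    """

    kind: str
    source: str
    target: str
    k: str
    species: str | None = None


@dataclass(frozen=True)
class MechanismSpec:
    """An enzyme mechanism: enzyme name, intermediates and reactions."""

    enzyme: str
    intermediates: tuple[str, ...]
    reactions: tuple[EnzymeReaction, ...]

    def __post_init__(self):
        states = {self.enzyme, *self.intermediates}
        if self.enzyme in self.intermediates:
            raise GraphError("free enzyme cannot also be an intermediate")
        for rx in self.reactions:
            if rx.kind == "bind":
                ok = (
                    rx.source == self.enzyme
                    and rx.target in self.intermediates
                    and rx.species is not None
                )
            elif rx.kind == "release":
                ok = (
                    rx.source in self.intermediates
                    and rx.target == self.enzyme
                    and rx.species is not None
                )
            elif rx.kind == "convert":
                ok = (
                    rx.source in self.intermediates
                    and rx.target in self.intermediates
                    and rx.source != rx.target
                    and rx.species is None
                )
            else:
                raise GraphError(f"unknown reaction kind {rx.kind!r}")
            if not ok:
                raise GraphError(
                    f"reaction {rx} does not match the basic "
                    "bind/release/convert shapes"
                )

    def substrates(self) -> tuple[str, ...]:
        return tuple(
            sorted({rx.species for rx in self.reactions if rx.kind == "bind"})
        )


def michaelis_menten_mechanism(
    enzyme: str = "E",
    substrate: str = "S",
    product: str = "P",
    intermediate: str | None = None,
    ks: tuple[str, str, str] = ("k1", "k2", "k3"),
) -> MechanismSpec:
    """The irreversible one-intermediate scheme
    E + S <-> ES -> E + P with rate constants (k1, k2, k3)."""
    Y = intermediate if intermediate is not None else enzyme + substrate
    k1, k2, k3 = ks
    return MechanismSpec(
        enzyme,
        (Y,),
        (
            EnzymeReaction("bind", enzyme, Y, k1, substrate),
            EnzymeReaction("release", Y, enzyme, k2, substrate),
            EnzymeReaction("release", Y, enzyme, k3, product),
        ),
    )


def compile_enzyme_graph(mech: MechanismSpec) -> LinGraph:
    """Compile a mechanism into its enzyme-state graph.

    Parallel edges (e.g. the two break-up routes of the Michaelis-Menten
    intermediate) merge by label summation.  Non-strong-connectivity
    means some complex is a dead end formed irreversibly; this is a
    compile error naming the offending intermediates.
    """
    vertices = (mech.enzyme, *mech.intermediates)
    triples = []
    for rx in mech.reactions:
        if rx.kind == "bind":
            lab = rate(rx.k) * conc(rx.species)
        else:
            lab = rate(rx.k)
        triples.append((rx.source, rx.target, lab))
    G = build_graph(vertices, triples, validate=False)
    if not is_strongly_connected(G):
        dec = scc_decompose(G)
        dead = [
            c for c, t in zip(dec.components, dec.terminal_flags)
            if t and mech.enzyme not in c
        ]
        names = sorted(v for c in dead for v in c) or list(G.vertices)
        raise GraphError(
            "enzyme graph is not strongly connected; dead-end complexes "
            f"must be formed reversibly: {names}"
        )
    return G


@dataclass(frozen=True)
class RateLaw:
    """A symbolic net-conversion rate with aggregated parameters when
    the Michaelis-Menten pattern v = Vmax*[S]/(K_M + [S]) is present."""

    rate: sympy.Expr
    vmax: sympy.Expr | None = None
    km: sympy.Expr | None = None


def _detect_mm(rate_expr: sympy.Expr, substrate: str):
    """Match rate = Vmax*[S]/(K_M + [S]) (numerator and denominator
    degree 1 in [S], numerator with zero constant term)."""
    s = conc(substrate)
    num, den = sympy.fraction(sympy.cancel(rate_expr))
    num_p, den_p = sympy.Poly(num, s), sympy.Poly(den, s)
    if num_p.degree() != 1 or den_p.degree() != 1:
        return None, None
    if num_p.coeff_monomial(1) != 0:
        return None, None
    lead = den_p.coeff_monomial(s)
    vmax = sympy.cancel(num_p.coeff_monomial(s) / lead)
    km = sympy.cancel(den_p.coeff_monomial(1) / lead)
    return vmax, km


def steady_state_rate(
    mech: MechanismSpec,
    product: str,
    e_tot: sympy.Expr | None = None,
) -> RateLaw:
    """Net rate of product formation after eliminating the intermediates.

    The intermediates are eliminated via the MTT and the total
    normalisation with E_tot (free enzyme plus all bound states); the
    rate sums (rate constant) * (steady-state intermediate) over every
    release step that produces ``product``.
    """
    if e_tot is None:
        e_tot = sympy.Symbol(f"{mech.enzyme}_tot", positive=True)
    G = compile_enzyme_graph(mech)
    rho = rho_mtt(G)
    ss = normalize_total(rho, G.vertices, e_tot)
    producing = [
        rx for rx in mech.reactions
        if rx.kind == "release" and rx.species == product
    ]
    if not producing:
        raise GraphError(f"mechanism has no release step producing {product!r}")
    rate_expr = sympy.cancel(
        sympy.Add(*(rate(rx.k) * ss[rx.source] for rx in producing))
    )
    vmax, km = None, None
    subs = mech.substrates()
    if len(subs) == 1:
        vmax, km = _detect_mm(rate_expr, subs[0])
    return RateLaw(rate_expr, vmax, km)


def effective_rate_coefficient(
    mech: MechanismSpec, source: str, product: str
) -> sympy.Expr:
    """The coefficient c with conversion rate = c * [E_free] * [source].

    Eliminating the intermediates with the *reference* normalisation at
    the free enzyme gives [Y]/[E] = rho_Y/rho_E; the gross rate of
    releasing ``product`` is then linear in [source], and c is the
    (rational, rate-constant-only) coefficient.  Used to label mod-form
    graph edges in multisite modification systems.
    """
    G = compile_enzyme_graph(mech)
    rho = rho_mtt(G)
    ss = normalize_reference(rho, G.vertices, mech.enzyme)
    producing = [
        rx for rx in mech.reactions
        if rx.kind == "release" and rx.species == product
    ]
    if not producing:
        raise GraphError(
            f"mechanism has no route from {source!r} to releasing {product!r}"
        )
    gross = sympy.cancel(
        sympy.Add(*(rate(rx.k) * ss[rx.source] for rx in producing))
    )
    # gross release rate per unit [E] is linear in each substrate-form
    # concentration; c is the [source] coefficient (terms in other forms
    # belong to other mod-form edges, the [product] term to the null
    # bind-and-release-back event)
    s = conc(source)
    num, den = sympy.fraction(gross)
    for csym in concentration_symbols(num):
        if sympy.degree(num, csym) > 1:
            raise GraphError(
                f"conversion rate is not linear in [{species_name(csym)}]"
            )
    if concentration_symbols(den):
        raise GraphError("denominator of the eliminated rate contains "
                         "substrate concentrations; mechanism not supported")
    c = sympy.cancel(num.coeff(s, 1) / den)
    if c == 0:
        raise GraphError(
            f"no conversion route from {source!r} to {product!r} in mechanism"
        )
    return c


def mechanism_network(
    mech: MechanismSpec,
    k_values: dict[str, float],
    extra_species: Sequence[str] = (),
) -> ReactionNetwork:
    """The full nonlinear mass-action network of a mechanism (enzyme,
    substrate forms and intermediates all explicit) -- the ODE oracle
    against which eliminated rate laws are validated."""
    species = [mech.enzyme, *mech.intermediates]
    for rx in mech.reactions:
        if rx.species is not None and rx.species not in species:
            species.append(rx.species)
    for s in extra_species:
        if s not in species:
            species.append(s)
    reactions = []
    for rx in mech.reactions:
        k = k_values[rx.k]
        if rx.kind == "bind":
            reactions.append(({rx.source: 1, rx.species: 1}, {rx.target: 1}, k))
        elif rx.kind == "release":
            reactions.append(({rx.source: 1}, {rx.target: 1, rx.species: 1}, k))
        else:
            reactions.append(({rx.source: 1}, {rx.target: 1}, k))
    return ReactionNetwork.make(species, reactions)
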