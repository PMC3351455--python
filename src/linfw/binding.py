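"""Ligand binding to scaffolds, at and away from thermodynamic equilibrium.

A scaffold (allosteric protein, receptor, promoter, chromatin...) has m
conformations and n binding sites, each with a cognate ligand.  A
*microstate* is a (conformation, binding-bitstring) pair; bit i set
means site i is occupied by its ligand.  Edges come in exactly two
shapes:

* conformational transitions -- change the conformation, no bits
  (rate constant k1; may be irreversible in dissipative systems);
* binding/unbinding -- flip exactly one bit, same conformation
  (binding labelled k2 * [L], unbinding k3).

Binding constants may depend on conformation, site and the occupancy of
the other sites, giving arbitrary cooperativity.  At equilibrium (all
edges reversible, cycle condition) microstate probabilities come from
single paths of equilibrium constants; away from equilibrium the
Matrix-Tree Theorem does the elimination, provided the graph is
strongly connected.  Averages over the probabilities give fractional
saturation (allostery) and gene-regulation functions (thermodynamic
formalism and its dissipative generalisation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.optimize
import sympy

from .crnt import ReactionNetwork, integrate_to_steady_state
from .equilibrium import check_all_reversible, check_cycle_condition, equilibrium_via_path
from .graph import GraphError, LinGraph, build_graph, is_strongly_connected
from .labels import conc, rate
from .matrix_tree import rho_mtt
from .steady_state import SteadyState

__all__ = [
    "BindingSystem",
    "microstate_name",
    "build_binding_graph",
    "microstate_probabilities",
    "fractional_saturation",
    "regulation_function",
    "free_ligand_correction",
    "binding_network",
]


def microstate_name(conformation: str, bits: str) -> str:
    return f"{conformation}:{bits}"


@dataclass(frozen=True)
class BindingSystem:
    """A scaffold with conformations, sites and cognate ligands.

    ``site_ligands[i]`` names the ligand of site i.  Rate-constant keys
    use a fallback hierarchy so input stays small while allowing full
    context dependence:

    * conformational transitions: ``(c_from, c_to, bits)`` then
      ``(c_from, c_to)``;
    * binding/unbinding constants: ``(conf, site, context)`` -- context
      is the bitstring with the site's own position masked with ``'-'``
      -- then ``(conf, site)``, then ``(site,)``.

    Values are label strings/numbers/sympy expressions (rate constants
    only; the ligand concentration is attached automatically on binding
    edges).  ``pruned`` lists microstates (names) excluded as
    biologically irrelevant.
    """

    conformations: tuple[str, ...]
    site_ligands: tuple[str, ...]
    conf_transitions: Mapping = field(default_factory=dict)
    on_constants: Mapping = field(default_factory=dict)
    off_constants: Mapping = field(default_factory=dict)
    pruned: frozenset[str] = frozenset()

    @property
    def n_sites(self) -> int:
        return len(self.site_ligands)

    @property
    def ligands(self) -> tuple[str, ...]:
        seen: list[str] = []
        for l in self.site_ligands:
            if l not in seen:
                seen.append(l)
        return tuple(seen)

    def microstates(self) -> tuple[tuple[str, str], ...]:
        """(conformation, bits) pairs, conformation-major, bits as
        binary integers (site 0 = lowest bit)."""
        out = []
        for c in self.conformations:
            for code in range(2**self.n_sites):
                bits = "".join(
                    str((code >> i) & 1) for i in range(self.n_sites)
                )
                if microstate_name(c, bits) not in self.pruned:
                    out.append((c, bits))
        return tuple(out)

    def _lookup(self, table: Mapping, keys: Sequence[tuple]):
        for k in keys:
            if k in table:
                return table[k]
        return None

    def on_rate(self, conf: str, site: int, bits: str):
        ctx = bits[:site] + "-" + bits[site + 1:]
        return self._lookup(
            self.on_constants, [(conf, site, ctx), (conf, site), (site,)]
        )

    def off_rate(self, conf: str, site: int, bits: str):
        ctx = bits[:site] + "-" + bits[site + 1:]
        return self._lookup(
            self.off_constants, [(conf, site, ctx), (conf, site), (site,)]
        )

    def conf_rate(self, c_from: str, c_to: str, bits: str):
        return self._lookup(
            self.conf_transitions, [(c_from, c_to, bits), (c_from, c_to)]
        )


def _as_expr(v) -> sympy.Expr:
    if isinstance(v, str):
        from .labels import parse_label

        return parse_label(v)
    return sympy.sympify(v)


def build_binding_graph(system: BindingSystem) -> LinGraph:
    """The microstate graph with the two sanctioned edge shapes.

    Binding edges are labelled k_on * [L], unbinding edges k_off,
    conformational edges by their bare rate constant.  The reference
    microstate (first conformation, no ligands bound) comes first in
    the vertex order.
    """
    states = system.microstates()
    names = [microstate_name(c, b) for c, b in states]
    present = set(names)
    triples = []
    for c, bits in states:
        me = microstate_name(c, bits)
        # conformational transitions: same bits, different conformation
        for c2 in system.conformations:
            if c2 == c:
                continue
            k = system.conf_rate(c, c2, bits)
            other = microstate_name(c2, bits)
            if k is not None and other in present:
                triples.append((me, other, _as_expr(k)))
        # binding / unbinding: flip one bit, same conformation
        for site in range(system.n_sites):
            flipped = (
                bits[:site] + ("1" if bits[site] == "0" else "0") + bits[site + 1:]
            )
            other = microstate_name(c, flipped)
            if other not in present:
                continue
            if bits[site] == "0":
                k = system.on_rate(c, site, bits)
                if k is not None:
                    lab = _as_expr(k) * conc(system.site_ligands[site])
                    triples.append((me, other, lab))
            else:
                k = system.off_rate(c, site, bits)
                if k is not None:
                    triples.append((me, other, _as_expr(k)))
    return build_graph(names, triples, validate=False)


def microstate_probabilities(
    system: BindingSystem, method: str = "auto"
) -> SteadyState:
    """Normalised steady-state microstate probabilities.

    At equilibrium (all edges reversible and the cycle condition holds)
    the probabilities are computed by multiplying equilibrium constants
    along paths from the reference microstate (no ligands bound); away
    from equilibrium the MTT applies, provided the graph is strongly
    connected.  ``method`` forces ``"path"`` or ``"mtt"``.
    """
    G = build_binding_graph(system)
    if not is_strongly_connected(G):
        raise GraphError(
            "binding graph is not strongly connected; microstates cannot "
            "be eliminated (check for missing reverse transitions)"
        )
    ref = G.vertices[0]
    if method == "auto":
        use_path = check_all_reversible(G) and check_cycle_condition(G).passed
    elif method in ("path", "mtt"):
        use_path = method == "path"
    else:
        raise ValueError(f"unknown method {method!r}")
    if use_path:
        raw = equilibrium_via_path(G, ref).values
    else:
        raw = rho_mtt(G)
    total = sympy.Add(*raw)
    values = tuple(sympy.cancel(r / total) for r in raw)
    return SteadyState(G.vertices, tuple(raw), "total", values,
                       total_symbol=sympy.Integer(1))


def _bound_count(vertex: str) -> int:
    return vertex.split(":", 1)[1].count("1")


def fractional_saturation(system: BindingSystem, probs: SteadyState | None = None) -> sympy.Expr:
    """Expected fraction of occupied sites,
    sum_microstates (bound bits / n) * P(microstate)."""
    if probs is None:
        probs = microstate_probabilities(system)
    n = system.n_sites
    return sympy.cancel(
        sympy.Add(
            *(
                sympy.Rational(_bound_count(v), n) * p
                for v, p in zip(probs.vertices, probs.values)
            )
        )
    )


def regulation_function(
    system: BindingSystem,
    weights: Mapping[str, sympy.Expr] | Sequence[sympy.Expr],
    probs: SteadyState | None = None,
) -> sympy.Expr:
    """Average output over the microstate probabilities, e.g. the rate
    of transcription as a function of the TF-binding pattern."""
    if probs is None:
        probs = microstate_probabilities(system)
    if isinstance(weights, Mapping):
        missing = [v for v in probs.vertices if v not in weights]
        if missing:
            raise GraphError(f"missing weights for microstates: {missing}")
        wlist = [weights[v] for v in probs.vertices]
    else:
        if len(weights) != len(probs.vertices):
            raise GraphError(
                f"{len(weights)} weights for {len(probs.vertices)} microstates"
            )
        wlist = list(weights)
    return sympy.cancel(
        sympy.Add(
            *(sympy.sympify(w) * p for w, p in zip(wlist, probs.values))
        )
    )


def binding_network(
    system: BindingSystem, k_values: Mapping[str, float] | None = None
) -> ReactionNetwork:
    """Full mass-action network with explicit ligand species (the ODE
    oracle; also used to solve ligand conservation exactly)."""
    G = build_binding_graph(system)
    subs = {rate(k): float(v) for k, v in (k_values or {}).items()}
    species = list(G.vertices) + list(system.ligands)
    reactions = []
    for (s, t), lab in G.edges.items():
        lab = sympy.sympify(lab).subs(subs)
        s_bits = s.split(":", 1)[1]
        t_bits = t.split(":", 1)[1]
        flipped = [i for i, (x, y) in enumerate(zip(s_bits, t_bits)) if x != y]
        if not flipped:  # conformational transition, no ligand involved
            reactions.append(({s: 1}, {t: 1}, float(lab)))
            continue
        (site,) = flipped
        lig = system.site_ligands[site]
        if s_bits[site] == "0":  # binding: consumes free ligand
            k = float(lab / conc(lig))
            reactions.append(({s: 1, lig: 1}, {t: 1}, k))
        else:  # unbinding: releases the ligand
            reactions.append(({s: 1}, {t: 1, lig: 1}, float(lab)))
    return ReactionNetwork.make(species, reactions)


def free_ligand_correction(
    system: BindingSystem,
    ligand_totals: Mapping[str, float],
    scaffold_total: float,
    k_values: Mapping[str, float] | None = None,
    *,
    residual_tol: float = 1e-10,
    seed: int = 0,
    n_random_starts: int = 20,
) -> dict[str, float]:
    """Free ligand concentrations from the ligand conservation laws.

    [L_k]_tot = [L_k] + scaffold_total * E[sites bound by L_k | free
    ligands], solved by multi-start root finding on log coordinates.  In
    the ligand-excess regime (scaffold_total -> 0) the free
    concentrations equal the totals.
    """
    ligands = system.ligands
    if scaffold_total == 0:
        return {l: float(ligand_totals[l]) for l in ligands}
    probs = microstate_probabilities(system)
    subs = {rate(k): float(v) for k, v in (k_values or {}).items()}
    lsyms = [conc(l) for l in ligands]
    bound = []
    for k, lig in enumerate(ligands):
        expr = sympy.Integer(0)
        for v, p in zip(probs.vertices, probs.values):
            bits = v.split(":", 1)[1]
            cnt = sum(
                1
                for site, b in enumerate(bits)
                if b == "1" and system.site_ligands[site] == lig
            )
            if cnt:
                expr += cnt * p
        bound.append(sympy.sympify(expr).subs(subs))
    bound_fn = sympy.lambdify(lsyms, bound, "numpy")
    totals = np.array([float(ligand_totals[l]) for l in ligands])

    def residuals(u):
        free = np.exp(u)
        b = np.asarray(bound_fn(*free), dtype=float)
        return free + scaffold_total * b - totals

    rng = np.random.default_rng(seed)
    starts = [np.log(totals), np.log(totals * 1e-3)]
    for _ in range(n_random_starts):
        starts.append(np.log(totals * 10.0 ** rng.uniform(-6, 0, len(ligands))))
    for u0 in starts:
        sol = scipy.optimize.root(residuals, u0, method="hybr", tol=1e-13)
        if sol.success and np.abs(residuals(sol.x) / totals).max() < residual_tol:
            return dict(zip(ligands, map(float, np.exp(sol.x))))
    raise RuntimeError(
        "no positive solution of the ligand conservation equations found; "
        f"best residual {np.abs(residuals(starts[0])).max():.3g}"
    )
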