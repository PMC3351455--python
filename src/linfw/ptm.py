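"""Multisite post-translational modification systems.

A substrate with n binary modification sites has N = 2^n "mod-forms",
encoded as bitstrings.  Forward and reverse enzymes interconvert the
mod-forms through mechanisms built from the bind/release/convert grammar
of :mod:`linfw.enzymes`.  Elimination is hierarchical: the enzyme-bound
intermediates are eliminated first, yielding an effective first-order
coefficient c^E_ij for each conversion, so the mod-form graph carries
labels

    label(i -> j) = sum over enzymes E of  c^E_ij * [E].

The Matrix-Tree Theorem on this graph gives the steady-state *mod-form
distribution* -- relative concentrations that are rational in the p free
enzyme concentrations only, however many sites there are.  The free
enzyme concentrations themselves are pinned down by nonlinear
conservation equations (one per enzyme, plus one for the substrate,
since intermediates sequester both); these can have multiple positive
solutions, which is the origin of multistability in covalent
modification cycles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.optimize
import sympy

from .crnt import ReactionNetwork, integrate_to_steady_state
from .enzymes import MechanismSpec, mechanism_network
from .graph import GraphError, LinGraph, build_graph, is_strongly_connected
from .labels import conc, concentration_symbols, rate, species_name
from .matrix_tree import rho_mtt
from .steady_state import normalize_reference

__all__ = [
    "PTMEnzyme",
    "PTMSystem",
    "ModFormDistribution",
    "conversion_coefficients",
    "build_modform_graph",
    "modform_distribution",
    "average_response",
    "ConservationSolution",
    "solve_conservation",
    "ptm_network",
    "steady_state_oracle",
    "bitstring_modforms",
]


def bitstring_modforms(n_sites: int, prefix: str = "S") -> tuple[str, ...]:
    """Mod-form names ``S00, S10, S01, S11, ...`` (site 0 is the lowest
    bit, names list the bits site by site)."""
    forms = []
    for code in range(2**n_sites):
        bits = "".join(str((code >> i) & 1) for i in range(n_sites))
        forms.append(f"{prefix}{bits}")
    return tuple(forms)


@dataclass(frozen=True)
class PTMEnzyme:
    """An enzyme with one mechanism per (set of) conversions it performs.

    Each mechanism's bind/release species must be mod-form names; a
    single mechanism may implicate several edges (processivity)."""

    name: str
    mechanisms: tuple[MechanismSpec, ...]

    def __post_init__(self):
        for m in self.mechanisms:
            if m.enzyme != self.name:
                raise GraphError(
                    f"mechanism enzyme {m.enzyme!r} does not match {self.name!r}"
                )


@dataclass(frozen=True)
class PTMSystem:
    modforms: tuple[str, ...]
    enzymes: tuple[PTMEnzyme, ...]

    def __post_init__(self):
        forms = set(self.modforms)
        enames = {e.name for e in self.enzymes}
        if enames & forms:
            raise GraphError(
                "an enzyme is also a substrate mod-form; the uncoupling "
                "condition fails and enzyme cascades are out of scope: "
                f"{sorted(enames & forms)}"
            )
        seen_intermediates: set[str] = set()
        for e in self.enzymes:
            for m in e.mechanisms:
                for rx in m.reactions:
                    if rx.species is not None and rx.species not in forms:
                        raise GraphError(
                            f"mechanism of {e.name!r} references unknown "
                            f"mod-form {rx.species!r}"
                        )
                clash = seen_intermediates & set(m.intermediates)
                if clash:
                    raise GraphError(
                        f"intermediate names shared across mechanisms: {sorted(clash)}"
                    )
                seen_intermediates |= set(m.intermediates)


def _gross_release(mech: MechanismSpec):
    """Per released species: the gross release rate per unit free
    enzyme, as (expanded numerator, denominator) with the denominator
    free of concentrations."""
    from .enzymes import compile_enzyme_graph

    G = compile_enzyme_graph(mech)
    rho = rho_mtt(G)
    ss = normalize_reference(rho, G.vertices, mech.enzyme)
    out = {}
    for rx in mech.reactions:
        if rx.kind != "release":
            continue
        term = rate(rx.k) * ss[rx.source]
        if rx.species in out:
            out[rx.species] = out[rx.species] + term
        else:
            out[rx.species] = term
    result = {}
    for sp, expr in out.items():
        num, den = sympy.fraction(sympy.cancel(expr))
        if concentration_symbols(den):
            raise GraphError("eliminated rate has concentrations in its "
                             "denominator; mechanism not supported")
        result[sp] = (sympy.expand(num), den)
    return result


def conversion_coefficients(mech: MechanismSpec) -> dict[tuple[str, str], sympy.Expr]:
    """All effective first-order coefficients of one mechanism:
    {(source mod-form, product mod-form): c} with conversion rate
    c * [E] * [source]."""
    coeffs = {}
    for product, (num, den) in _gross_release(mech).items():
        for csym in sorted(concentration_symbols(num), key=lambda s: s.name):
            src = species_name(csym)
            if src == product:
                continue  # bind-and-release-back, not a conversion
            c = sympy.cancel(num.coeff(csym, 1) / den)
            if c != 0:
                coeffs[(src, product)] = c
    return coeffs


def build_modform_graph(system: PTMSystem) -> LinGraph:
    """The mod-form graph: edge i -> j labelled sum_E c^E_ij * [E].

    Labels carry only enzyme concentrations and rate constants, so the
    uncoupling condition holds as long as no enzyme is a mod-form
    (enforced at system construction).  Errors if the graph is not
    strongly connected, listing unreachable mod-form pairs.
    """
    triples = []
    for enz in system.enzymes:
        esym = conc(enz.name)
        for mech in enz.mechanisms:
            for (src, prod), c in conversion_coefficients(mech).items():
                triples.append((src, prod, c * esym))
    G = build_graph(system.modforms, triples, validate=False)
    if not is_strongly_connected(G):
        import networkx as nx

        g = G.to_networkx()
        missing = [
            (a, b)
            for a in G.vertices
            for b in G.vertices
            if a != b and not nx.has_path(g, a, b)
        ]
        raise GraphError(
            "mod-form graph is not strongly connected; unreachable pairs: "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}"
        )
    return G


@dataclass(frozen=True)
class ModFormDistribution:
    """Relative mod-form concentrations [S_i]/S_tot, rational in the
    free-enzyme concentrations; entries sum to 1 symbolically."""

    modforms: tuple[str, ...]
    values: tuple[sympy.Expr, ...]
    enzyme_symbols: tuple[sympy.Symbol, ...]

    def __getitem__(self, form: str) -> sympy.Expr:
        return self.values[self.modforms.index(form)]

    def lambdified(self):
        return sympy.lambdify(self.enzyme_symbols, list(self.values), "numpy")


def modform_distribution(system: PTMSystem) -> ModFormDistribution:
    """Steady-state mod-form distribution by MTT on the mod-form graph."""
    G = build_modform_graph(system)
    rho = rho_mtt(G)
    total = sympy.Add(*rho)
    # ratios are left uncancelled: clearing the per-mechanism
    # denominators into one big rational form explodes combinatorially
    # for many sites and gains nothing (the MTT polynomials are kept in
    # `raw` form by construction)
    values = tuple(r / total for r in rho)
    esyms = tuple(conc(e.name) for e in system.enzymes)
    return ModFormDistribution(G.vertices, values, esyms)


def average_response(
    dist: ModFormDistribution, effect_levels: Sequence[sympy.Expr]
) -> sympy.Expr:
    """Overall response = sum_i f_i * ([S_i]/S_tot), the average of the
    per-mod-form effect levels over the distribution."""
    if len(effect_levels) != len(dist.values):
        raise GraphError(
            f"{len(effect_levels)} effect levels for {len(dist.values)} mod-forms"
        )
    return sympy.cancel(
        sympy.Add(*(sympy.sympify(f) * v for f, v in zip(effect_levels, dist.values)))
    )


@dataclass(frozen=True)
class ConservationSolution:
    """One positive solution of the conservation equations."""

    free_enzymes: dict[str, float]
    free_substrate_total: float
    modform_concentrations: dict[str, float]
    residual: float


def _sequestration_coefficients(
    system: PTMSystem, k_values: Mapping[str, float]
):
    """For every enzyme: numeric gamma[Y][mod-form] with intermediate
    concentration [Y] = [E] * sum_i gamma_(Y,i) * [S_i]."""
    from .enzymes import compile_enzyme_graph

    per_enzyme = []
    for enz in system.enzymes:
        gammas = []  # list of (modform-index coeff vector)
        for mech in enz.mechanisms:
            G = compile_enzyme_graph(mech)
            rho = rho_mtt(G)
            ss = normalize_reference(rho, G.vertices, mech.enzyme)
            for Y in mech.intermediates:
                expr = sympy.expand(
                    sympy.cancel(ss[Y]).subs(
                        {rate(k): float(v) for k, v in k_values.items()}
                    )
                )
                vec = np.zeros(len(system.modforms))
                for idx, form in enumerate(system.modforms):
                    vec[idx] = float(expr.coeff(conc(form), 1))
                gammas.append(vec)
        per_enzyme.append(np.array(gammas) if gammas else np.zeros((0, len(system.modforms))))
    return per_enzyme


def solve_conservation(
    system: PTMSystem,
    enzyme_totals: Mapping[str, float],
    substrate_total: float,
    k_values: Mapping[str, float],
    *,
    n_random_starts: int = 40,
    grid_points: int = 4,
    seed: int = 0,
    residual_tol: float = 1e-10,
    merge_tol: float = 1e-6,
) -> list[ConservationSolution]:
    """All positive solutions of the steady-state conservation equations.

    Unknowns are the p free-enzyme concentrations and the total free
    (unsequestered) substrate; equations are one conservation law per
    enzyme and one for the substrate, with intermediates expressed
    through the eliminated mechanisms and mod-forms through the
    distribution.  Multi-start damped root finding on log-concentration
    coordinates; a deterministic log-spaced grid is augmented with a
    seeded random batch, converged roots are validated by relative
    residual and merged at relative distance ``merge_tol``.
    """
    p = len(system.enzymes)
    enames = [e.name for e in system.enzymes]
    etot = np.array([float(enzyme_totals[e]) for e in enames])
    s_tot = float(substrate_total)
    ksubs = {rate(k): float(v) for k, v in k_values.items()}

    dist = modform_distribution(system)
    dist_num = [sympy.sympify(v).subs(ksubs) for v in dist.values]
    dist_fn = sympy.lambdify(list(dist.enzyme_symbols), dist_num, "numpy")
    gammas = _sequestration_coefficients(system, k_values)

    def residuals(u: np.ndarray) -> np.ndarray:
        with np.errstate(over="ignore", invalid="ignore"):
            vals = np.exp(np.clip(u, -700, 700))
            e, sf = vals[:p], vals[p]
            share = np.asarray(dist_fn(*e), dtype=float)
            s_vec = sf * share
            res = np.empty(p + 1)
            seq_substrate = 0.0
            for k in range(p):
                y = e[k] * gammas[k] @ s_vec if len(gammas[k]) else np.zeros(0)
                res[k] = e[k] + y.sum() - etot[k]
                seq_substrate += y.sum()
            res[p] = sf + seq_substrate - s_tot
        return np.nan_to_num(res, nan=1e300)

    scale = np.concatenate([etot, [s_tot]])
    rng = np.random.default_rng(seed)
    starts = []
    grid = np.logspace(-6, 0, grid_points)
    for g_e in grid:
        for g_s in grid:
            starts.append(np.log(np.concatenate([etot * g_e, [s_tot * g_s]])))
    for _ in range(n_random_starts):
        frac = 10.0 ** rng.uniform(-6, 0, size=p + 1)
        starts.append(np.log(scale * frac))

    found: list[np.ndarray] = []
    for u0 in starts:
        sol = scipy.optimize.root(residuals, u0, method="hybr", tol=1e-13)
        if not sol.success:
            continue
        res = residuals(sol.x)
        if np.abs(res / scale).max() > residual_tol:
            continue
        vals = np.exp(sol.x)
        if not np.all(np.isfinite(vals)):
            continue
        if any(
            np.abs(vals - f).max() / np.abs(f).max() < merge_tol for f in found
        ):
            continue
        found.append(vals)

    out = []
    for vals in sorted(found, key=lambda v: tuple(v)):
        e, sf = vals[:p], vals[p]
        share = np.asarray(dist_fn(*e), dtype=float)
        out.append(
            ConservationSolution(
                free_enzymes=dict(zip(enames, map(float, e))),
                free_substrate_total=float(sf),
                modform_concentrations={
                    f: float(sf * s) for f, s in zip(system.modforms, share)
                },
                residual=float(np.abs(residuals(np.log(vals)) / scale).max()),
            )
        )
    return out


def solution_full_state(
    system: PTMSystem,
    sol: ConservationSolution,
    k_values: Mapping[str, float],
) -> dict[str, float]:
    """Reconstruct the full network state (mod-forms, free enzymes and
    every intermediate) corresponding to a conservation solution, for
    ODE cross-checks and stability probes."""
    gammas = _sequestration_coefficients(system, k_values)
    s_vec = np.array(
        [sol.modform_concentrations[f] for f in system.modforms]
    )
    state = dict(sol.modform_concentrations)
    for enz, gam in zip(system.enzymes, gammas):
        e = sol.free_enzymes[enz.name]
        state[enz.name] = e
        names = [
            Y for mech in enz.mechanisms for Y in mech.intermediates
        ]
        for Y, g in zip(names, gam):
            state[Y] = float(e * g @ s_vec)
    return state


def ptm_network(
    system: PTMSystem, k_values: Mapping[str, float]
) -> ReactionNetwork:
    """The full nonlinear mass-action network (mod-forms, free enzymes
    and every intermediate explicit) -- the end-to-end ODE oracle."""
    species = list(system.modforms)
    reactions = []
    for enz in system.enzymes:
        if enz.name not in species:
            species.append(enz.name)
        for mech in enz.mechanisms:
            net = mechanism_network(mech, dict(k_values))
            for s in net.species:
                if s not in species:
                    species.append(s)
            for rx in net.reactions:
                reactions.append((dict(rx.reactants), dict(rx.products), rx.k))
    return ReactionNetwork.make(species, reactions)


def steady_state_oracle(
    system: PTMSystem,
    enzyme_totals: Mapping[str, float],
    substrate_total: float,
    k_values: Mapping[str, float],
    *,
    initial_modform: str | None = None,
    x0: Mapping[str, float] | None = None,
    deriv_tol: float = 1e-11,
) -> dict[str, float]:
    """Long-time full-network integration from an all-free initial state
    (or a caller-specified one); returns species concentrations."""
    net = ptm_network(system, k_values)
    init = np.zeros(len(net.species))
    sidx = {s: i for i, s in enumerate(net.species)}
    if x0 is not None:
        for s, v in x0.items():
            init[sidx[s]] = v
    else:
        form = initial_modform or system.modforms[0]
        init[sidx[form]] = substrate_total
        for e in system.enzymes:
            init[sidx[e.name]] = float(enzyme_totals[e.name])
    x = integrate_to_steady_state(net, init, deriv_tol=deriv_tol)
    return dict(zip(net.species, map(float, x)))
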