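"""Deterministic generators for every input family the tests exercise.

All randomness flows from a single integer seed through named
sub-streams (``SeedSequence`` spawned per family + call counter), so a
fixture is bit-reproducible from its configuration alone and adding a
new generator call does not perturb existing ones.  Numeric labels are
log-uniform over [1e-3, 1e3], spanning the decades a stiff biochemical
system realistically covers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import sympy

from .binding import BindingSystem
from .crnt import ReactionNetwork
from .enzymes import EnzymeReaction, MechanismSpec, michaelis_menten_mechanism
from .graph import LinGraph, build_graph
from .ptm import PTMEnzyme, PTMSystem, bitstring_modforms
from .syndeg import PartialGraph

__all__ = [
    "FixtureConfig",
    "random_strongly_connected_graph",
    "random_digraph",
    "random_detailed_balanced_graph",
    "random_ptm_system",
    "sequential_double_modification_system",
    "random_binding_system",
    "random_partial_graph",
    "random_reaction_network",
    "two_cycle",
    "three_cycle",
    "cascade_graph",
]

_FAMILY_IDS = {
    "strong": 1,
    "digraph": 2,
    "db": 3,
    "ptm": 4,
    "binding": 5,
    "partial": 6,
    "network": 7,
}


@dataclass(frozen=True)
class FixtureConfig:
    seed: int = 0
    n: int = 4
    n_sites: int = 1
    n_enzymes: int = 2
    n_conformations: int = 1
    symbolic: bool = False
    extra_edge_prob: float = 0.35


def _rng(cfg: FixtureConfig, family: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([cfg.seed, _FAMILY_IDS[family]])
    )


def _label(rng: np.random.Generator, symbolic: bool, counter: itertools.count):
    if symbolic:
        return sympy.Symbol(f"a{next(counter)}", positive=True)
    return sympy.Float(10.0 ** rng.uniform(-3, 3))


# -- tiny named graphs -------------------------------------------------


def _expr(v):
    from .labels import parse_label

    return parse_label(v) if isinstance(v, str) else sympy.sympify(v)


def two_cycle(a="a", b="b") -> LinGraph:
    """1 <-> 2, the smallest reversible graph."""
    return build_graph(["1", "2"], [("1", "2", _expr(a)), ("2", "1", _expr(b))])


def three_cycle(a="a", b="b", c="c") -> LinGraph:
    """1 -> 2 -> 3 -> 1."""
    return build_graph(
        ["1", "2", "3"],
        [("1", "2", _expr(a)), ("2", "3", _expr(b)), ("3", "1", _expr(c))],
    )


def cascade_graph(a="a", b="b", c="c") -> LinGraph:
    """1 <-> 2 -> 3: not strongly connected, terminal SCC {3}."""
    return build_graph(
        ["1", "2", "3"],
        [("1", "2", _expr(a)), ("2", "1", _expr(b)), ("2", "3", _expr(c))],
    )


# -- random graphs -----------------------------------------------------


def random_strongly_connected_graph(cfg: FixtureConfig) -> LinGraph:
    """A random Hamiltonian cycle plus random extra edges: strongly
    connected by construction."""
    rng = _rng(cfg, "strong")
    n = cfg.n
    counter = itertools.count(1)
    verts = [str(i) for i in range(1, n + 1)]
    perm = list(rng.permutation(n))
    triples = []
    for i in range(n):
        s, t = verts[perm[i]], verts[perm[(i + 1) % n]]
        triples.append((s, t, _label(rng, cfg.symbolic, counter)))
    existing = {(s, t) for s, t, _ in triples}
    for s in verts:
        for t in verts:
            if s != t and (s, t) not in existing:
                if rng.random() < cfg.extra_edge_prob:
                    triples.append((s, t, _label(rng, cfg.symbolic, counter)))
    return build_graph(verts, triples, validate=False)


def random_digraph(cfg: FixtureConfig) -> LinGraph:
    """An Erdos-Renyi-style digraph (no connectivity guarantee); edge
    probability ``extra_edge_prob``, at least one edge."""
    rng = _rng(cfg, "digraph")
    n = cfg.n
    counter = itertools.count(1)
    verts = [str(i) for i in range(1, n + 1)]
    triples = [
        (s, t, _label(rng, cfg.symbolic, counter))
        for s in verts
        for t in verts
        if s != t and rng.random() < cfg.extra_edge_prob
    ]
    return build_graph(verts, triples, validate=False)


def random_detailed_balanced_graph(cfg: FixtureConfig) -> LinGraph:
    """All-reversible graph whose labels derive from a random vertex
    potential, so the cycle condition holds by construction."""
    rng = _rng(cfg, "db")
    n = cfg.n
    verts = [str(i) for i in range(1, n + 1)]
    potential = rng.uniform(-3, 3, size=n)  # energies in RT units
    pairs = {(i, (i + 1) % n) for i in range(n)}  # ring keeps it connected
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) not in pairs and (j, i) not in pairs:
                if rng.random() < cfg.extra_edge_prob:
                    pairs.add((i, j))
    triples = []
    for i, j in sorted(pairs):
        omega = 10.0 ** rng.uniform(-2, 2)
        dg = potential[j] - potential[i]
        triples.append((verts[i], verts[j], sympy.Float(omega * np.exp(-dg / 2))))
        triples.append((verts[j], verts[i], sympy.Float(omega * np.exp(+dg / 2))))
    return build_graph(verts, triples, validate=False)


# -- application-level fixtures ----------------------------------------


def _mm_like_mechanism(enzyme: str, src: str, dst: str, tag: str) -> MechanismSpec:
    """One-intermediate irreversible mechanism E + src <-> Y -> E + dst."""
    Y = f"Y{tag}"
    return MechanismSpec(
        enzyme,
        (Y,),
        (
            EnzymeReaction("bind", enzyme, Y, f"kon{tag}", src),
            EnzymeReaction("release", Y, enzyme, f"koff{tag}", src),
            EnzymeReaction("release", Y, enzyme, f"kcat{tag}", dst),
        ),
    )


def random_ptm_system(cfg: FixtureConfig):
    """A distributive kinase/phosphatase system on ``n_sites`` binary
    sites with random rate constants.

    Returns ``(system, k_values)``.  The kinase flips 0 -> 1 one site at
    a time, the phosphatase 1 -> 0; every single-bit conversion gets its
    own one-intermediate mechanism.  With n_sites=1 this is the classic
    futile modification cycle.
    """
    rng = _rng(cfg, "ptm")
    forms = bitstring_modforms(cfg.n_sites)
    k_values: dict[str, float] = {}

    def mechs(enzyme: str, bit_from: str, bit_to: str):
        out = []
        for form in forms:
            bits = form[1:]
            for site, b in enumerate(bits):
                if b != bit_from:
                    continue
                dst_bits = bits[:site] + bit_to + bits[site + 1:]
                tag = f"_{enzyme}_{bits}_{site}"
                out.append(_mm_like_mechanism(enzyme, form, "S" + dst_bits, tag))
                for kname in (f"kon{tag}", f"koff{tag}", f"kcat{tag}"):
                    k_values[kname] = 10.0 ** rng.uniform(-1.5, 1.5)
        return tuple(out)

    kin = PTMEnzyme("K", mechs("K", "0", "1"))
    pho = PTMEnzyme("P", mechs("P", "1", "0"))
    return PTMSystem(forms, (kin, pho)), k_values


def sequential_double_modification_system(
    params: dict | None = None,
):
    """The two-site distributive modification futile cycle with ordered
    sites: S0 -> S1 -> S2 by a kinase K, S2 -> S1 -> S0 by a
    phosphatase P, each step an irreversible one-intermediate
    mechanism.  Default rate constants (nM, 1/s) sit in the
    literature-standard bistable regime of the dual modification cycle:
    the second kinase step is fast and the kinase near saturation, so
    with comparable enzyme totals the conservation equations admit
    three positive solutions.  Returns ``(system, k_values)``.
    """
    p = {
        "a1": 0.02, "d1": 1.0, "c1": 0.01,   # K: S0 -> S1
        "a2": 0.032, "d2": 1.0, "c2": 15.0,  # K: S1 -> S2
        "a3": 0.045, "d3": 1.0, "c3": 0.092, # P: S2 -> S1
        "a4": 0.01, "d4": 1.0, "c4": 0.5,    # P: S1 -> S0
    }
    if params:
        p.update(params)
    k_values: dict[str, float] = {}

    def step(enzyme, src, dst, a, d, c, tag):
        k_values[f"kon{tag}"] = a
        k_values[f"koff{tag}"] = d
        k_values[f"kcat{tag}"] = c
        return _mm_like_mechanism(enzyme, src, dst, tag)

    m1 = step("K", "S0", "S1", p["a1"], p["d1"], p["c1"], "_k1")
    m2 = step("K", "S1", "S2", p["a2"], p["d2"], p["c2"], "_k2")
    m3 = step("P", "S2", "S1", p["a3"], p["d3"], p["c3"], "_p1")
    m4 = step("P", "S1", "S0", p["a4"], p["d4"], p["c4"], "_p2")
    system = PTMSystem(
        ("S0", "S1", "S2"),
        (PTMEnzyme("K", (m1, m2)), PTMEnzyme("P", (m3, m4))),
    )
    return system, k_values


def random_binding_system(cfg: FixtureConfig):
    """A binding system with ``n_conformations`` conformations and
    ``n_sites`` sites, one ligand per site, reversible transitions with
    random constants.  Returns ``(system, k_values)``."""
    rng = _rng(cfg, "binding")
    confs = tuple(f"C{i}" for i in range(1, cfg.n_conformations + 1))
    site_ligands = tuple(f"L{i + 1}" for i in range(cfg.n_sites))
    k_values: dict[str, float] = {}
    on, off, trans = {}, {}, {}
    for ci, c in enumerate(confs):
        for site in range(cfg.n_sites):
            kon, koff = f"kon_{c}_{site}", f"koff_{c}_{site}"
            k_values[kon] = 10.0 ** rng.uniform(-1, 1)
            k_values[koff] = 10.0 ** rng.uniform(-1, 1)
            on[(c, site)] = sympy.Symbol(kon, positive=True)
            off[(c, site)] = sympy.Symbol(koff, positive=True)
    for a, b in zip(confs, confs[1:]):
        kf, kr = f"kc_{a}_{b}", f"kc_{b}_{a}"
        k_values[kf] = 10.0 ** rng.uniform(-1, 1)
        k_values[kr] = 10.0 ** rng.uniform(-1, 1)
        trans[(a, b)] = sympy.Symbol(kf, positive=True)
        trans[(b, a)] = sympy.Symbol(kr, positive=True)
    system = BindingSystem(confs, site_ligands, trans, on, off)
    return system, k_values


def random_partial_graph(cfg: FixtureConfig) -> PartialGraph:
    """A strongly connected core with random synthesis/degradation
    half-edges (at least one of each, so the augmented graph is
    strongly connected)."""
    core = random_strongly_connected_graph(cfg)
    rng = _rng(cfg, "partial")
    syn, deg = {}, {}
    for v in core.vertices:
        if rng.random() < 0.5:
            syn[v] = sympy.Float(10.0 ** rng.uniform(-1, 1))
        if rng.random() < 0.5:
            deg[v] = sympy.Float(10.0 ** rng.uniform(-1, 1))
    if not syn:
        syn[core.vertices[0]] = sympy.Float(1.0)
    if not deg:
        deg[core.vertices[-1]] = sympy.Float(1.0)
    return PartialGraph(core, syn, deg)


def random_reaction_network(cfg: FixtureConfig) -> ReactionNetwork:
    """A random mass-action network: <=6 species, ``n`` reactions with
    reactant/product complexes of total stoichiometry <= 2."""
    rng = _rng(cfg, "network")
    n_species = int(min(6, max(2, cfg.n)))
    species = [chr(ord("A") + i) for i in range(n_species)]
    n_reactions = int(min(6, max(2, cfg.n)))

    def random_complex():
        size = rng.integers(0, 3)
        comp: dict[str, int] = {}
        for _ in range(size):
            s = species[rng.integers(0, n_species)]
            comp[s] = comp.get(s, 0) + 1
        return comp

    reactions = []
    while len(reactions) < n_reactions:
        r, p = random_complex(), random_complex()
        if r == p:
            continue
        reactions.append((r, p, 10.0 ** rng.uniform(-1, 1)))
    return ReactionNetwork.make(species, reactions)
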