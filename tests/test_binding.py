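"""Microstate graphs, probabilities, saturation, regulation functions."""

import numpy as np
import pytest
import sympy

from linfw.binding import (
    BindingSystem,
    binding_network,
    build_binding_graph,
    fractional_saturation,
    free_ligand_correction,
    microstate_probabilities,
    regulation_function,
)
from linfw.crnt import integrate_to_steady_state
from linfw.graph import GraphError
from linfw.labels import conc, rate
from linfw.fixtures import FixtureConfig, random_binding_system


def single_site():
    return BindingSystem(
        ("C1",), ("L",), {}, {("C1", 0): rate("kon")}, {("C1", 0): rate("koff")}
    )


def tf_square():
    """Two TFs on two promoter sites, no conformational changes."""
    return BindingSystem(
        ("C1",), ("L1", "L2"), {},
        {("C1", 0): rate("a1"), ("C1", 1): rate("a2")},
        {("C1", 0): rate("b1"), ("C1", 1): rate("b2")},
    )


def mwc_homodimer(l_ratio=1000.0, c_factor=0.01):
    """Concerted two-conformation (R/T) homodimer at equilibrium.

    T binds the ligand weaker by ``c_factor``; the R -> T transition
    constant for a microstate with m bound sites is l_ratio * c^m
    (detailed balance fixes the occupancy dependence, since the
    conformations differ in affinity)."""
    on = {("R", s): rate("kR") for s in (0, 1)}
    on.update({("T", s): rate("kT") for s in (0, 1)})
    off = {("R", s): rate("uR") for s in (0, 1)}
    off.update({("T", s): rate("uT") for s in (0, 1)})
    trans = {}
    for bits in ("00", "10", "01", "11"):
        m = bits.count("1")
        trans[("R", "T", bits)] = sympy.Float(l_ratio * c_factor**m)
        trans[("T", "R", bits)] = sympy.Float(1.0)
    kv = {"kR": 1.0, "uR": 1.0, "kT": c_factor, "uT": 1.0}
    return BindingSystem(("R", "T"), ("L", "L"), trans, on, off), kv


class TestGraphConstruction:
    def test_tf_square_is_four_vertex_diamond(self):
        G = build_binding_graph(tf_square())
        assert G.vertices == ("C1:00", "C1:10", "C1:01", "C1:11")
        assert sympy.expand(
            G.label("C1:00", "C1:10") - rate("a1") * conc("L1")
        ) == 0
        assert G.label("C1:10", "C1:00") == rate("b1")
        assert not G.has_edge("C1:00", "C1:11")  # one bit per edge

    def test_homodimer_has_eight_microstates(self):
        system, _ = mwc_homodimer()
        G = build_binding_graph(system)
        assert len(G.vertices) == 8
        # conformational edges preserve bits
        assert G.has_edge("R:00", "T:00") and G.has_edge("T:11", "R:11")

    def test_irreversible_remodelling_accepted_when_strongly_connected(self):
        # chromatin-remodelling-style irreversible conformational step:
        # not all-reversible, still strongly connected
        trans = {("C1", "C2", "1"): rate("r"), ("C2", "C1", "0"): rate("q")}
        system = BindingSystem(
            ("C1", "C2"), ("L",), trans,
            {("C1", 0): rate("a"), ("C2", 0): rate("c")},
            {("C1", 0): rate("b"), ("C2", 0): rate("d")},
        )
        G = build_binding_graph(system)
        from linfw.equilibrium import check_all_reversible
        from linfw.graph import is_strongly_connected

        assert not check_all_reversible(G)
        assert is_strongly_connected(G)
        probs = microstate_probabilities(system)  # MTT route
        assert abs(float(sympy.Add(*probs.values).subs(
            {rate(k): 1.0 for k in "abcdqr"} | {conc("L"): 2.0}
        )) - 1.0) < 1e-12

    def test_pruned_microstates_are_excluded(self):
        system = BindingSystem(
            ("C1",), ("L1", "L2"), {},
            {("C1", 0): rate("a1"), ("C1", 1): rate("a2")},
            {("C1", 0): rate("b1"), ("C1", 1): rate("b2")},
            pruned=frozenset({"C1:11"}),
        )
        G = build_binding_graph(system)
        assert len(G.vertices) == 3


class TestProbabilities:
    def test_single_site_closed_form(self):
        probs = microstate_probabilities(single_site())
        K = rate("kon") / rate("koff")
        L = conc("L")
        assert sympy.simplify(probs["C1:1"] - K * L / (1 + K * L)) == 0

    def test_zero_ligand_concentrates_reference(self):
        probs = microstate_probabilities(tf_square())
        subs = {conc("L1"): 0, conc("L2"): 0,
                rate("a1"): 1, rate("a2"): 1, rate("b1"): 1, rate("b2"): 1}
        assert float(probs["C1:00"].subs(subs)) == 1.0

    def test_probabilities_sum_to_one_symbolically(self):
        probs = microstate_probabilities(tf_square())
        assert sympy.simplify(sympy.Add(*probs.values) - 1) == 0

    def test_equilibrium_path_equals_mtt(self):
        system, kv = random_binding_system(
            FixtureConfig(seed=9, n_sites=2, n_conformations=1)
        )
        p_path = microstate_probabilities(system, method="path")
        p_mtt = microstate_probabilities(system, method="mtt")
        subs = {rate(k): v for k, v in kv.items()}
        subs.update({conc("L1"): 0.7, conc("L2"): 1.9})
        for a, b in zip(p_path.values, p_mtt.values):
            assert abs(float(a.subs(subs)) - float(b.subs(subs))) < 1e-12

    def test_nonequilibrium_probabilities_match_ode(self):
        trans = {("C1", "C2", "1"): rate("r"), ("C2", "C1", "0"): rate("q")}
        system = BindingSystem(
            ("C1", "C2"), ("L",), trans,
            {("C1", 0): rate("a"), ("C2", 0): rate("c")},
            {("C1", 0): rate("b"), ("C2", 0): rate("d")},
        )
        kv = {"a": 1.3, "b": 0.4, "c": 0.8, "d": 2.0, "r": 1.7, "q": 0.6}
        L_conc = 1.5
        probs = microstate_probabilities(system)
        subs = {rate(k): v for k, v in kv.items()} | {conc("L"): L_conc}
        predicted = np.array([float(p.subs(subs)) for p in probs.values])
        net = binding_network(system, kv)
        x0 = np.zeros(len(net.species))
        x0[net.species.index("C1:0")] = 1e-6  # scaffold scarce: [L] fixed
        x0[net.species.index("L")] = L_conc
        x = integrate_to_steady_state(net, x0)
        scaffold = np.array(
            [x[net.species.index(v)] for v in probs.vertices]
        )
        np.testing.assert_allclose(
            scaffold / scaffold.sum(), predicted, rtol=1e-6
        )


class TestSaturation:
    def test_single_site_equals_bound_probability(self):
        sat = fractional_saturation(single_site())
        K, L = rate("kon") / rate("koff"), conc("L")
        assert sympy.simplify(sat - K * L / (1 + K * L)) == 0

    @pytest.mark.parametrize("n", [2, 3])
    def test_independent_identical_sites_factorise(self, n):
        # n independent sites with one shared ligand: saturation is the
        # single-site hyperbola (binomial factorisation)
        system = BindingSystem(
            ("C1",), tuple("L" for _ in range(n)), {},
            {(s,): rate("kon") for s in range(n)},
            {(s,): rate("koff") for s in range(n)},
        )
        sat = fractional_saturation(system)
        K, L = rate("kon") / rate("koff"), conc("L")
        assert sympy.simplify(sat - K * L / (1 + K * L)) == 0

    def test_mwc_homodimer_sigmoidal_and_monotone(self):
        system, kv = mwc_homodimer()
        sat = fractional_saturation(system)
        subs = {rate(k): v for k, v in kv.items()}
        f = sympy.lambdify(conc("L"), sat.subs(subs))
        grid = np.logspace(-3, 3, 60)
        vals = np.array([f(x) for x in grid])
        assert (np.diff(vals) > -1e-12).all()  # monotone increasing
        # sigmoidal: Hill coefficient above 1 at half-saturation
        half = grid[np.argmin(np.abs(vals - 0.5))]
        h = 1e-4
        slope = (np.log(f(half * (1 + h)) / (1 - f(half * (1 + h))))
                 - np.log(f(half) / (1 - f(half)))) / np.log(1 + h)
        assert slope > 1.2


class TestRegulation:
    def test_constant_weights_give_constant(self):
        w = sympy.Symbol("w", positive=True)
        g = regulation_function(tf_square(), [w, w, w, w])
        assert sympy.simplify(g - w) == 0

    def test_doubly_bound_weight_gives_and_logic(self):
        probs = microstate_probabilities(tf_square())
        w = {v: 0 for v in probs.vertices}
        w["C1:11"] = 1
        g = regulation_function(tf_square(), w, probs)
        L1, L2 = conc("L1"), conc("L2")
        # low-concentration leading term is the product L1*L2 (AND)
        series = g.subs({L1: sympy.Symbol("eps") * L1, L2: sympy.Symbol("eps") * L2})
        eps = sympy.Symbol("eps")
        lead = sympy.limit(series / eps**2, eps, 0)
        assert sympy.simplify(
            lead - rate("a1") * rate("a2") * L1 * L2 / (rate("b1") * rate("b2"))
        ) == 0

    def test_weight_count_mismatch_rejected(self):
        with pytest.raises(GraphError):
            regulation_function(tf_square(), [1, 2, 3])

    def test_dissipative_regulation_matches_ode_average(self):
        trans = {("C1", "C2", "1"): rate("r"), ("C2", "C1", "0"): rate("q")}
        system = BindingSystem(
            ("C1", "C2"), ("L",), trans,
            {("C1", 0): rate("a"), ("C2", 0): rate("c")},
            {("C1", 0): rate("b"), ("C2", 0): rate("d")},
        )
        kv = {"a": 0.9, "b": 1.1, "c": 2.0, "d": 0.3, "r": 1.0, "q": 0.5}
        weights = {"C1:0": 0.0, "C1:1": 0.2, "C2:0": 0.1, "C2:1": 1.0}
        g = regulation_function(system, weights)
        subs = {rate(k): v for k, v in kv.items()} | {conc("L"): 0.8}
        predicted = float(g.subs(subs))
        net = binding_network(system, kv)
        x0 = np.zeros(len(net.species))
        x0[net.species.index("C1:0")] = 1e-6
        x0[net.species.index("L")] = 0.8
        x = integrate_to_steady_state(net, x0)
        occ = np.array([x[net.species.index(v)] for v in weights])
        observed = sum(w * o for w, o in zip(weights.values(), occ)) / occ.sum()
        assert abs(observed - predicted) < 1e-6 * predicted


class TestFreeLigand:
    def test_zero_scaffold_returns_totals(self):
        free = free_ligand_correction(
            single_site(), {"L": 2.5}, 0.0, {"kon": 1.0, "koff": 1.0}
        )
        assert free == {"L": 2.5}

    def test_single_site_quadratic_closed_form(self):
        kon, koff, s_tot, l_tot = 2.0, 1.0, 1.5, 2.0
        K = kon / koff
        free = free_ligand_correction(
            single_site(), {"L": l_tot}, s_tot, {"kon": kon, "koff": koff}
        )["L"]
        # conservation: L + S_tot*K*L/(1+K*L) = L_tot, a quadratic in L
        aq, bq, cq = K, 1 + K * (s_tot - l_tot), -l_tot
        closed = (-bq + np.sqrt(bq**2 - 4 * aq * cq)) / (2 * aq)
        assert abs(free - closed) < 1e-9 * closed

    def test_two_ligand_square_matches_ode(self):
        system = tf_square()
        kv = {"a1": 1.2, "a2": 0.5, "b1": 0.9, "b2": 1.7}
        totals, s_tot = {"L1": 1.0, "L2": 0.6}, 0.8
        free = free_ligand_correction(system, totals, s_tot, kv)
        net = binding_network(system, kv)
        x0 = np.zeros(len(net.species))
        x0[net.species.index("C1:00")] = s_tot
        x0[net.species.index("L1")] = totals["L1"]
        x0[net.species.index("L2")] = totals["L2"]
        x = integrate_to_steady_state(net, x0)
        for lig in ("L1", "L2"):
            assert abs(x[net.species.index(lig)] - free[lig]) < 1e-6
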