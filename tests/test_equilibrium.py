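"""Detailed balance: reversibility, the cycle condition, path
equilibria and the free-energy parameterisation."""

import itertools
import math

import numpy as np
import pytest
import sympy

from linfw.equilibrium import (
    EnergyModel,
    check_all_reversible,
    check_cycle_condition,
    energies_from_equilibrium,
    equilibrium_via_path,
    labels_from_energies,
)
from linfw.graph import GraphError, build_graph
from linfw.labels import rate
from linfw.matrix_tree import rho_mtt
from linfw.steady_state import normalize_reference
from linfw.fixtures import (
    FixtureConfig,
    random_detailed_balanced_graph,
    three_cycle,
    two_cycle,
)


def all_simple_cycle_ratios(G):
    """Oracle: forward/backward label products around every simple
    cycle (length >= 3) of the reversible-pair graph."""
    verts = G.vertices
    ratios = []
    for r in range(3, len(verts) + 1):
        for combo in itertools.permutations(verts, r):
            if combo[0] != min(combo, key=verts.index):
                continue  # fix rotation
            cyc = list(combo) + [combo[0]]
            if all(G.has_edge(s, t) and G.has_edge(t, s)
                   for s, t in zip(cyc[:-1], cyc[1:])):
                ratio = 1.0
                for s, t in zip(cyc[:-1], cyc[1:]):
                    ratio *= float(G.label(s, t)) / float(G.label(t, s))
                ratios.append(ratio)
    return ratios


class TestReversibility:
    def test_two_cycle_reversible(self, two_cycle_graph):
        assert check_all_reversible(two_cycle_graph)

    def test_mm_graph_structurally_reversible_after_merging(self, mm_mechanism):
        # the chemistry has an irreversible product step, but merging
        # the two ES -> E routes leaves a structurally reversible
        # 2-vertex graph; structural reversibility is necessary but not
        # sufficient for detailed balance
        from linfw.enzymes import compile_enzyme_graph

        assert check_all_reversible(compile_enzyme_graph(mm_mechanism))

    def test_one_way_cycle_not_reversible(self, three_cycle_graph):
        assert not check_all_reversible(three_cycle_graph)


class TestCycleCondition:
    def make_square(self, perturb=1.0):
        # 4-cycle with labels from a vertex potential; perturb one
        # forward constant to break detailed balance
        g_pot = {"1": 0.0, "2": 0.7, "3": -0.4, "4": 1.1}
        triples = []
        pairs = [("1", "2"), ("2", "3"), ("3", "4"), ("4", "1")]
        for i, (u, v) in enumerate(pairs):
            dg = g_pot[v] - g_pot[u]
            f = math.exp(-dg / 2) * (perturb if i == 0 else 1.0)
            triples.append((u, v, sympy.Float(f)))
            triples.append((v, u, sympy.Float(math.exp(dg / 2))))
        return build_graph(["1", "2", "3", "4"], triples)

    def test_potential_labels_pass(self):
        report = check_cycle_condition(self.make_square())
        assert report.passed and len(report.cycles) == 1

    def test_perturbed_constant_detected_with_ratio(self):
        report = check_cycle_condition(self.make_square(perturb=2.0))
        assert not report.passed
        r = float(report.ratios[report.failures[0]])
        assert abs(max(r, 1 / r) - 2.0) < 1e-9  # orientation-free ratio

    def test_requires_reversible_graph(self, three_cycle_graph):
        with pytest.raises(GraphError):
            check_cycle_condition(three_cycle_graph)

    @pytest.mark.parametrize("seed", range(10))
    def test_basis_verdict_matches_all_simple_cycles(self, seed):
        G = random_detailed_balanced_graph(FixtureConfig(seed=seed, n=5))
        report = check_cycle_condition(G)
        oracle = all(
            abs(r - 1) < 1e-9 for r in all_simple_cycle_ratios(G)
        )
        assert report.passed == oracle == True

    def test_independent_random_labels_fail(self):
        rng = np.random.default_rng(7)
        G = build_graph(
            ["1", "2", "3"],
            [(s, t, sympy.Float(10.0 ** rng.uniform(-1, 1)))
             for s, t in [("1", "2"), ("2", "1"), ("2", "3"), ("3", "2"),
                          ("3", "1"), ("1", "3")]],
        )
        report = check_cycle_condition(G)
        assert not report.passed


class TestPathEquilibrium:
    def test_two_cycle_single_edge_path(self, two_cycle_graph):
        ss = equilibrium_via_path(two_cycle_graph)
        assert ss.values == (1, rate("a") / rate("b"))

    def test_binding_square_path_independence(self):
        # 4-microstate binding square from a potential: both routes
        # 00 -> 10 -> 11 and 00 -> 01 -> 11 agree
        g_pot = {"00": 0.0, "10": -0.5, "01": -0.9, "11": -2.0}
        pairs = [("00", "10"), ("10", "11"), ("00", "01"), ("01", "11")]
        triples = []
        for u, v in pairs:
            dg = g_pot[v] - g_pot[u]
            triples.append((u, v, sympy.Float(math.exp(-dg / 2))))
            triples.append((v, u, sympy.Float(math.exp(dg / 2))))
        G = build_graph(["00", "10", "01", "11"], triples)
        ss = equilibrium_via_path(G, "00")
        via_10 = float(G.label("00", "10") / G.label("10", "00")) * float(
            G.label("10", "11") / G.label("11", "10")
        )
        via_01 = float(G.label("00", "01") / G.label("01", "00")) * float(
            G.label("01", "11") / G.label("11", "01")
        )
        assert abs(via_10 - via_01) < 1e-12
        assert abs(float(ss["11"]) - via_10) < 1e-12
        # Boltzmann ratio exp(-dG)
        assert abs(float(ss["11"]) - math.exp(2.0)) < 1e-9

    def test_path_dependent_graph_rejected(self):
        report_graph = build_graph(
            ["1", "2", "3"],
            [("1", "2", sympy.Float(2.0)), ("2", "1", sympy.Float(1.0)),
             ("2", "3", sympy.Float(1.0)), ("3", "2", sympy.Float(1.0)),
             ("3", "1", sympy.Float(1.0)), ("1", "3", sympy.Float(1.0))],
        )
        with pytest.raises(GraphError, match="cycle condition"):
            equilibrium_via_path(report_graph)

    @pytest.mark.parametrize("seed", range(12))
    def test_equivalence_with_mtt(self, seed):
        # detailed balance cuts the MTT's rooted trees to a single path
        G = random_detailed_balanced_graph(FixtureConfig(seed=seed, n=5))
        path = equilibrium_via_path(G)
        mtt = normalize_reference(rho_mtt(G), G.vertices)
        for pv, mv in zip(path.values, mtt.values):
            assert abs(float(pv) - float(mv)) < 1e-9 * max(abs(float(pv)), 1)

    @pytest.mark.parametrize("seed", range(6))
    def test_pairwise_detailed_balance_at_equilibrium(self, seed):
        G = random_detailed_balanced_graph(FixtureConfig(seed=seed, n=5))
        x = equilibrium_via_path(G).as_dict()
        for (s, t), lab in G.edges.items():
            lhs = float(x[s]) * float(lab)
            rhs = float(x[t]) * float(G.label(t, s))
            assert abs(lhs - rhs) < 1e-9 * max(lhs, rhs)


class TestEnergyModel:
    def test_equal_energies_give_unit_constant(self):
        model = EnergyModel({"1": 0.0, "2": 0.0})
        G = labels_from_energies(model, {("1", "2"): 1.0})
        K = float(G.label("1", "2") / G.label("2", "1"))
        assert abs(K - 1.0) < 1e-12

    def test_vant_hoff_closed_form(self):
        # bound state lower by RT*ln 2 => K = 2
        model = EnergyModel({"u": 0.0, "b": -math.log(2.0)})
        G = labels_from_energies(model, {("u", "b"): 3.7})
        K = float(G.label("u", "b") / G.label("b", "u"))
        assert abs(K - 2.0) < 1e-12

    def test_round_trip_energies_to_boltzmann(self):
        energies = {"1": 0.0, "2": 1.3, "3": -0.8, "4": 0.4}
        model = EnergyModel(energies, reference="1")
        scales = {("1", "2"): 1.0, ("2", "3"): 2.0, ("3", "4"): 0.5,
                  ("4", "1"): 1.5, ("1", "3"): 0.9}
        G = labels_from_energies(model, scales)
        assert check_cycle_condition(G).passed
        ss = equilibrium_via_path(G, "1")
        for v, gv in energies.items():
            assert abs(float(ss[v]) - math.exp(-gv)) < 1e-10
        back = energies_from_equilibrium(ss)
        for v, gv in energies.items():
            assert abs(back[v] - gv) < 1e-10

    def test_missing_energy_rejected(self):
        model = EnergyModel({"1": 0.0})
        with pytest.raises(GraphError):
            labels_from_energies(model, {("1", "2"): 1.0}, vertices=["1", "2"])
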