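"""Mod-form graphs, distributions, conservation equations,
multistability."""

import numpy as np
import pytest
import sympy

from linfw.crnt import integrate_to_steady_state, mass_action_field
from linfw.enzymes import EnzymeReaction, MechanismSpec
from linfw.graph import GraphError
from linfw.labels import conc, rate
from linfw.ptm import (
    PTMEnzyme,
    PTMSystem,
    average_response,
    bitstring_modforms,
    build_modform_graph,
    modform_distribution,
    ptm_network,
    solution_full_state,
    solve_conservation,
    steady_state_oracle,
)
from linfw.fixtures import (
    FixtureConfig,
    random_ptm_system,
    sequential_double_modification_system,
)


def make_futile_cycle():
    """1-site kinase/phosphatase cycle, both one-intermediate."""

    def mech(E, src, dst, tag):
        Y = f"Y{tag}"
        return MechanismSpec(E, (Y,), (
            EnzymeReaction("bind", E, Y, f"a{tag}", src),
            EnzymeReaction("release", Y, E, f"d{tag}", src),
            EnzymeReaction("release", Y, E, f"c{tag}", dst),
        ))

    kin = PTMEnzyme("K", (mech("K", "S0", "S1", "K"),))
    pho = PTMEnzyme("P", (mech("P", "S1", "S0", "P"),))
    return PTMSystem(("S0", "S1"), (kin, pho))


class TestSystemValidation:
    def test_enzyme_as_substrate_rejected(self):
        mech = MechanismSpec("S1", ("Y",), (
            EnzymeReaction("bind", "S1", "Y", "a", "S0"),
            EnzymeReaction("release", "Y", "S1", "c", "S0"),
        ))
        with pytest.raises(GraphError, match="cascade"):
            PTMSystem(("S0", "S1"), (PTMEnzyme("S1", (mech,)),))

    def test_unknown_modform_rejected(self):
        mech = MechanismSpec("K", ("Y",), (
            EnzymeReaction("bind", "K", "Y", "a", "S9"),
            EnzymeReaction("release", "Y", "K", "c", "S9"),
        ))
        with pytest.raises(GraphError, match="S9"):
            PTMSystem(("S0", "S1"), (PTMEnzyme("K", (mech,)),))

    def test_non_strongly_connected_modform_graph_rejected(self):
        # kinase only: S1 cannot be undone
        def mech(E, src, dst, tag):
            Y = f"Y{tag}"
            return MechanismSpec(E, (Y,), (
                EnzymeReaction("bind", E, Y, f"a{tag}", src),
                EnzymeReaction("release", Y, E, f"c{tag}", dst),
            ))
        system = PTMSystem(
            ("S0", "S1"), (PTMEnzyme("K", (mech("K", "S0", "S1", "K"),)),)
        )
        with pytest.raises(GraphError, match="unreachable"):
            build_modform_graph(system)


class TestModformGraph:
    def test_futile_cycle_labels(self):
        G = build_modform_graph(make_futile_cycle())
        cK = rate("aK") * rate("cK") / (rate("dK") + rate("cK"))
        assert sympy.simplify(G.label("S0", "S1") - cK * conc("K")) == 0

    def test_two_site_distributive_diamond(self):
        system, _ = random_ptm_system(FixtureConfig(seed=1, n_sites=2))
        G = build_modform_graph(system)
        assert set(G.vertices) == set(bitstring_modforms(2))
        # diamond: each single-bit flip present in both directions
        assert ("S00", "S10") in G.edges and ("S10", "S00") in G.edges
        assert ("S00", "S01") in G.edges and ("S11", "S10") in G.edges
        assert ("S00", "S11") not in G.edges

    def test_processive_kinase_adds_chord(self):
        # a 2-intermediate mechanism releasing at the doubly-modified
        # form puts a direct S00 -> S11 edge into the diamond
        proc = MechanismSpec("K", ("Ya", "Yb"), (
            EnzymeReaction("bind", "K", "Ya", "a1", "S00"),
            EnzymeReaction("release", "Ya", "K", "d1", "S00"),
            EnzymeReaction("convert", "Ya", "Yb", "q"),
            EnzymeReaction("release", "Yb", "K", "c1", "S11"),
        ))
        def mech(E, src, dst, tag):
            Y = f"Y{tag}"
            return MechanismSpec(E, (Y,), (
                EnzymeReaction("bind", E, Y, f"a{tag}", src),
                EnzymeReaction("release", Y, E, f"c{tag}", dst),
            ))
        pho = PTMEnzyme("P", (
            mech("P", "S11", "S01", "p1"), mech("P", "S01", "S00", "p2"),
            mech("P", "S10", "S00", "p3"), mech("P", "S11", "S10", "p4"),
        ))
        system = PTMSystem(bitstring_modforms(2), (PTMEnzyme("K", (proc,)), pho))
        G = build_modform_graph(system)
        assert ("S00", "S11") in G.edges


class TestDistribution:
    def test_futile_cycle_closed_form(self):
        dist = modform_distribution(make_futile_cycle())
        cK = rate("aK") * rate("cK") / (rate("dK") + rate("cK"))
        cP = rate("aP") * rate("cP") / (rate("dP") + rate("cP"))
        K, P = conc("K"), conc("P")
        denom = cK * K + cP * P
        assert sympy.simplify(dist["S0"] - cP * P / denom) == 0
        assert sympy.simplify(dist["S1"] - cK * K / denom) == 0

    def test_symmetric_two_site_uniform(self):
        # all rate constants equal and [K] = [P]: quarter each
        system, kv = random_ptm_system(FixtureConfig(seed=0, n_sites=2))
        dist = modform_distribution(system)
        subs = {rate(k): 1.0 for k in kv}
        subs[conc("K")] = 1.0
        subs[conc("P")] = 1.0
        for v in dist.values:
            assert abs(float(v.subs(subs)) - 0.25) < 1e-12

    def test_sums_to_one_symbolically(self):
        from linfw.matrix_tree import exprs_equal

        for n in (1, 2):
            system, _ = random_ptm_system(FixtureConfig(seed=2, n_sites=n))
            dist = modform_distribution(system)
            assert exprs_equal(sympy.Add(*dist.values), sympy.Integer(1))

    @pytest.mark.parametrize("n_sites", [1, 2])
    def test_complexity_depends_on_enzymes_not_sites(self, n_sites):
        # free symbols of the distribution: the 2 enzyme concentrations
        # plus rate constants, regardless of the number of sites
        system, _ = random_ptm_system(FixtureConfig(seed=4, n_sites=n_sites))
        dist = modform_distribution(system)
        concs = {
            s for v in dist.values for s in v.free_symbols
            if s.name.startswith("[")
        }
        assert concs == {conc("K"), conc("P")}

    def test_three_site_labels_carry_only_enzyme_concentrations(self):
        # at three sites the same two enzyme concentrations are the
        # only concentrations in the 8-vertex mod-form graph's labels
        system, _ = random_ptm_system(FixtureConfig(seed=4, n_sites=3))
        G = build_modform_graph(system)
        concs = {
            s for lab in G.edges.values() for s in lab.free_symbols
            if s.name.startswith("[")
        }
        assert concs == {conc("K"), conc("P")}
        assert len(G.vertices) == 8

    def test_average_response(self):
        dist = modform_distribution(make_futile_cycle())
        assert sympy.simplify(average_response(dist, [1, 1]) - 1) == 0
        assert sympy.simplify(
            average_response(dist, [0, 1]) - dist["S1"]
        ) == 0
        with pytest.raises(GraphError):
            average_response(dist, [1.0])


class TestConservation:
    def test_futile_cycle_matches_ode(self):
        system, kv = random_ptm_system(FixtureConfig(seed=3, n_sites=1))
        totals = {"K": 0.8, "P": 1.1}
        sols = solve_conservation(system, totals, 4.0, kv)
        assert len(sols) == 1
        oracle = steady_state_oracle(system, totals, 4.0, kv)
        for f in system.modforms:
            assert (
                abs(sols[0].modform_concentrations[f] - oracle[f])
                / oracle[f] < 1e-6
            )
        for e in ("K", "P"):
            assert abs(sols[0].free_enzymes[e] - oracle[e]) / oracle[e] < 1e-6

    def test_two_site_matches_ode(self):
        system, kv = random_ptm_system(FixtureConfig(seed=11, n_sites=2))
        totals = {"K": 0.5, "P": 0.7}
        sols = solve_conservation(system, totals, 3.0, kv)
        assert len(sols) >= 1
        oracle = steady_state_oracle(system, totals, 3.0, kv)
        best = min(
            sols,
            key=lambda s: max(
                abs(s.modform_concentrations[f] - oracle[f]) for f in system.modforms
            ),
        )
        for f in system.modforms:
            assert (
                abs(best.modform_concentrations[f] - oracle[f])
                / max(oracle[f], 1e-12) < 1e-4
            )

    def test_vanishing_totals_leave_enzyme_free(self):
        system, kv = random_ptm_system(FixtureConfig(seed=3, n_sites=1))
        totals = {"K": 1e-9, "P": 1e-9}
        sols = solve_conservation(system, totals, 1e-9, kv)
        assert len(sols) == 1
        for e, t in totals.items():
            assert abs(sols[0].free_enzymes[e] - t) / t < 1e-3

    def test_conserved_quantities_in_oracle(self):
        system, kv = random_ptm_system(FixtureConfig(seed=5, n_sites=1))
        totals = {"K": 0.6, "P": 0.9}
        s_tot = 2.5
        oracle = steady_state_oracle(system, totals, s_tot, kv)
        net = ptm_network(system, kv)
        # substrate total: mod-forms plus intermediates
        inter = [s for s in net.species
                 if s not in system.modforms and s not in ("K", "P")]
        assert abs(
            sum(oracle[f] for f in system.modforms)
            + sum(oracle[y] for y in inter) - s_tot
        ) < 1e-8
        for e in ("K", "P"):
            bound = sum(oracle[y] for y in inter if f"_{e}_" in y)
            assert abs(oracle[e] + bound - totals[e]) < 1e-8


class TestMultistability:
    def test_three_solutions_two_stable(self):
        system, kv = sequential_double_modification_system()
        totals = {"K": 100.0, "P": 100.0}
        sols = solve_conservation(
            system, totals, 500.0, kv, n_random_starts=60, grid_points=5
        )
        assert len(sols) == 3
        net = ptm_network(system, kv)
        f = mass_action_field(net)
        idx = {s: i for i, s in enumerate(net.species)}
        stability = []
        for sol in sols:
            full = solution_full_state(system, sol, kv)
            x0 = np.array([full[s] for s in net.species])
            assert np.abs(f(x0)).max() < 1e-8  # solutions are steady states
            stable = True
            for sign in (+1, -1):
                xp = x0.copy()
                d = 0.02 * min(xp[idx["S0"]], xp[idx["S2"]]) + 1e-3
                xp[idx["S0"]] += sign * d
                xp[idx["S2"]] -= sign * d
                xs = integrate_to_steady_state(net, xp, deriv_tol=1e-9)
                if abs(xs[idx["S0"]] - x0[idx["S0"]]) > 0.05 * max(
                    x0[idx["S0"]], 1e-6
                ):
                    stable = False
            stability.append(stable)
        assert sum(stability) == 2
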