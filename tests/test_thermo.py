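import dataclasses

import numpy as np
import pytest

import teraflux as tf
from teraflux.thermo import RT_DEFAULT
from conftest import solve_sampled


class TestPotentialsFromDuals:
    def test_dual_routes_agree(self, fig1_thermo):
        """-2RT S^T lambda and RT ln(v_r/v_f) + 2RT alpha give the same dG."""
        np.testing.assert_allclose(
            fig1_thermo.delta_g, fig1_thermo.delta_g_from_ratio, atol=1e-4
        )

    def test_active_reaction_runs_downhill(self, fig1_solution, fig1_thermo):
        dg = dict(zip(fig1_thermo.reaction_ids, fig1_thermo.delta_g))
        assert dg["v2"] < 0  # carries forward flux

    def test_blocked_reaction_dg_equals_unspent_driving_force(self, fig1_solution, fig1_thermo):
        """At v_f = v_r the log-ratio vanishes, so dG = 2RT alpha >= 0: the
        reverse direction is favourable but kinetically forbidden."""
        j = fig1_thermo.reaction_ids.index("v3")
        alpha = dict(zip(fig1_solution.internal_ids, fig1_solution.alpha))["v3"]
        assert fig1_thermo.delta_g[j] == pytest.approx(2 * RT_DEFAULT * alpha, abs=1e-6)
        assert fig1_thermo.delta_g[j] > 0

    def test_delta_g_is_stoichiometric_combination_of_mu(self, fig1_thermo, fig1_constrained):
        np.testing.assert_allclose(
            fig1_thermo.delta_g, fig1_constrained.S.T @ fig1_thermo.mu, atol=1e-12
        )

    def test_second_law_dissipation(self, fig1_solution, fig1_thermo):
        assert float(fig1_solution.v @ fig1_thermo.delta_g) <= 1e-9

    def test_missing_duals_rejected(self, fig1_solution):
        bad = dataclasses.replace(fig1_solution, lambda_=None)
        with pytest.raises(ValueError, match="duals"):
            tf.potentials_from_duals(bad, tf.build_fig1_network())


@pytest.mark.parametrize("kind,seed", [("fig1", 0), ("infeasible_pair", 1),
                                       ("feasible_coupled_loop", 0), ("random_loopy", 7)])
def test_dual_consistency_on_fixture_solves(kind, seed):
    """On every fixture solve: dual-route agreement within 1e-4 kJ/mol,
    nonpositive total dissipation and zero flux-force violations."""
    net, _, weights, sol = solve_sampled(kind, seed)
    thermo = tf.potentials_from_duals(sol, net)
    clean = np.isfinite(thermo.delta_g_from_ratio)
    np.testing.assert_allclose(
        thermo.delta_g[clean], thermo.delta_g_from_ratio[clean], atol=1e-4
    )
    assert float(sol.v @ thermo.delta_g) <= 1e-8
    audit = tf.flux_force_audit(sol, thermo, net=net)
    assert audit.n_violations == 0


class TestFluxForceAudit:
    def make(self, v, dg, alpha=None):
        n = len(v)
        v = np.asarray(v, float)
        sol = tf.FluxSolution(
            internal_ids=[f"r{i}" for i in range(n)], exchange_ids=[],
            v_f=np.where(v >= 0, np.abs(v) + 1.0, 1.0),
            v_r=np.where(v >= 0, 1.0, np.abs(v) + 1.0),
            v_e=np.zeros(0), lambda_=np.zeros(1),
            alpha=np.asarray(alpha if alpha is not None else np.zeros(n), float),
            objective_value=0.0, status="optimal", iterations=0, mode="teraflux",
            options=tf.SolverOptions(),
        )
        thermo = tf.ThermoState(
            metabolite_ids=[], reaction_ids=list(sol.internal_ids), mu=np.zeros(0),
            delta_g=np.asarray(dg, float), delta_g_from_ratio=np.asarray(dg, float),
            RT=RT_DEFAULT, active_mask=np.abs(v) > 1e-6,
            consistent=np.zeros(n, bool),
        )
        return sol, thermo

    def test_flux_against_gradient_is_violation(self):
        sol, thermo = self.make([1.0], [5.0])
        report = tf.flux_force_audit(sol, thermo)
        assert report.n_violations == 1 and report.violations == ["r0"]

    def test_reverse_flux_with_positive_dg_is_consistent(self):
        sol, thermo = self.make([-2.0], [5.0])
        assert tf.flux_force_audit(sol, thermo).n_violations == 0

    def test_subthreshold_flux_not_classified(self):
        sol, thermo = self.make([1e-9], [5.0])
        report = tf.flux_force_audit(sol, thermo)
        assert report.quadrant == ["inactive"] and report.n_active == 0

    def test_blocked_reported_with_alpha(self, fig1_solution, fig1_thermo, fig1_constrained):
        report = tf.flux_force_audit(fig1_solution, fig1_thermo, net=fig1_constrained)
        assert "v3" in report.blocked and report.blocked["v3"] > 0


class TestInfeasibleCycleOracle:
    def test_antiparallel_pair_witnessed(self):
        net = tf.make_network(tf.FixtureSpec(kind="infeasible_pair"))
        y = tf.find_infeasible_cycle(net, np.array([100.0, 95.0]))
        assert y is not None
        assert np.sum(np.abs(y)) == pytest.approx(1.0)
        np.testing.assert_allclose(net.S @ y, 0.0, atol=1e-9)

    def test_fig1_solution_is_cycle_free(self, fig1_solution, fig1_constrained):
        assert tf.find_infeasible_cycle(fig1_constrained, fig1_solution.v) is None

    def test_cofactor_coupled_cycle_is_feasible(self):
        """Boundary turnover of the cofactor breaks the pure circulation."""
        net = tf.make_network(tf.FixtureSpec(kind="feasible_coupled_loop"))
        assert tf.find_infeasible_cycle(net, np.array([15.0, 10.0])) is None

    def test_through_flux_is_not_a_cycle(self):
        net = tf.make_single_reaction_network(5.0)
        assert tf.find_infeasible_cycle(net, np.array([5.0])) is None

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_agrees_with_graph_cycle_enumeration(self, seed):
        """Independent oracle: on unimolecular networks, a sign-aligned
        circulation exists iff the flux-oriented reaction graph has a
        directed cycle (flow decomposition)."""
        import networkx as nx

        spec = tf.FixtureSpec(kind="random_loopy", seed=seed)
        net = tf.make_network(spec)
        rng = np.random.default_rng(seed)
        v = rng.uniform(-20.0, 20.0, size=net.n_internal)
        v[rng.uniform(size=net.n_internal) < 0.3] = 0.0
        G = nx.DiGraph()
        for j in range(net.n_internal):
            if abs(v[j]) <= 1e-6:
                continue
            sub = np.flatnonzero(net.S[:, j] < 0)[0]
            prod = np.flatnonzero(net.S[:, j] > 0)[0]
            if v[j] > 0:
                G.add_edge(sub, prod)
            else:
                G.add_edge(prod, sub)
        has_cycle = any(True for _ in nx.simple_cycles(G))
        witness = tf.find_infeasible_cycle(net, v)
        assert (witness is not None) == has_cycle


class TestTVA:
    def toy(self, gamma, sigma=1.0, forward=True):
        net = tf.make_single_reaction_network(1.0)
        return tf.TVAProblem(
            net=net, gamma={"conv": gamma}, sigma={"conv": sigma},
            directions={"conv": 1} if forward else {},
        )

    def test_closed_form_bounds(self):
        """gamma = -10, sigma = 1, forward-active: the box LP has the
        analytic solution [-41.118, -0.001] kJ/mol."""
        res = tf.tva_bounds(self.toy(-10.0))
        rt = RT_DEFAULT
        expected_min = -10.0 - 2.58 + rt * np.log(1e-6 / 1e-1)
        assert res.dg_min[0] == pytest.approx(expected_min, abs=1e-6)
        assert res.dg_min[0] == pytest.approx(-41.12, abs=0.01)
        assert res.dg_max[0] == pytest.approx(-1e-3, abs=1e-9)

    def test_strongly_positive_gamma_infeasible(self):
        res = tf.tva_bounds(self.toy(50.0))
        assert not res.feasible
        assert np.isnan(res.dg_min[0])

    def test_without_direction_constraint_feasible(self):
        res = tf.tva_bounds(self.toy(50.0, forward=False))
        assert res.feasible
        assert res.dg_max[0] == pytest.approx(50.0 + 2.58 - RT_DEFAULT * np.log(1e-6 / 1e-1),
                                              abs=1e-6)

    def test_zero_sigma_pinned_concentrations_collapse_to_gamma(self):
        net = tf.make_single_reaction_network(1.0)
        prob = tf.TVAProblem(
            net=net, gamma={"conv": -10.0}, sigma={"conv": 0.0},
            conc_overrides={"A": (np.log(1e-3), np.log(1e-3)),
                            "B": (np.log(1e-3), np.log(1e-3))},
        )
        res = tf.tva_bounds(prob)
        assert res.dg_min[0] == pytest.approx(-10.0, abs=1e-9)
        assert res.dg_max[0] == pytest.approx(-10.0, abs=1e-9)

    def test_wider_concentration_bounds_widen_intervals(self):
        narrow = tf.tva_bounds(self.toy(-10.0))
        wide_prob = dataclasses.replace(self.toy(-10.0),
                                        ln_conc_bounds=(np.log(1e-7), np.log(1.0)))
        wide = tf.tva_bounds(wide_prob)
        assert wide.dg_min[0] <= narrow.dg_min[0] + 1e-12
        assert wide.dg_max[0] >= narrow.dg_max[0] - 1e-12

    def test_missing_gamma_rejected(self):
        net = tf.make_single_reaction_network(1.0)
        with pytest.raises(ValueError, match="missing gamma"):
            tf.TVAProblem(net=net, gamma={}, sigma={})

    def test_excluded_metabolites_have_no_concentration_freedom(self):
        net = tf.make_single_reaction_network(1.0)
        prob = tf.TVAProblem(net=net, gamma={"conv": -10.0}, sigma={"conv": 0.0},
                             excluded_metabolites=("A", "B"))
        res = tf.tva_bounds(prob)
        assert res.dg_min[0] == pytest.approx(-10.0) and res.dg_max[0] == pytest.approx(-10.0)


class TestTVAConsistency:
    def make_state(self, dgs, active=None):
        n = len(dgs)
        return tf.ThermoState(
            metabolite_ids=[], reaction_ids=[f"r{i}" for i in range(n)],
            mu=np.zeros(0), delta_g=np.asarray(dgs, float),
            delta_g_from_ratio=np.asarray(dgs, float), RT=RT_DEFAULT,
            active_mask=np.ones(n, bool) if active is None else np.asarray(active, bool),
            consistent=np.ones(n, bool),
        )

    def test_all_within(self):
        res = tf.TVAResult([f"r{i}" for i in range(3)],
                           np.array([-5.0] * 3), np.array([5.0] * 3), feasible=True)
        assert tf.tva_consistency(res, self.make_state([0.0, 1.0, -1.0])) == 1.0

    def test_partial_counting(self):
        res = tf.TVAResult([f"r{i}" for i in range(4)],
                           np.array([-5.0] * 4), np.array([5.0] * 4), feasible=True)
        frac = tf.tva_consistency(res, self.make_state([0.0, 1.0, -1.0, 9.0]))
        assert frac == pytest.approx(0.75)

    def test_excluded_transport_not_scored(self):
        res = tf.TVAResult([f"r{i}" for i in range(2)],
                           np.array([-5.0] * 2), np.array([5.0] * 2), feasible=True)
        frac = tf.tva_consistency(res, self.make_state([0.0, 99.0]), exclude=("r1",))
        assert frac == 1.0

    def test_infeasible_result_rejected(self):
        res = tf.TVAResult(["r0"], np.array([np.nan]), np.array([np.nan]), feasible=False)
        with pytest.raises(ValueError, match="infeasible"):
            tf.tva_consistency(res, self.make_state([0.0]))
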