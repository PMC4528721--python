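"""Solver primitives vs brute-force oracles on small networks."""

import numpy as np
import pytest

from storflux.fba import (LinearConstraint, apply_environment,
                          fba_max_growth, fva_range, l1_minimize,
                          linear_flux_objective, moma_qp, solve_lp)
from storflux.synthetic import toy_environments

from conftest import build_mini_model, mini_env
from _oracles import (l1_sign_pattern_oracle, lp_vertex_oracle,
                      moma_active_set_oracle)


def chain_model():
    """a_e -> a -> b -> c -> c_e, plus a futile cycle b <-> d."""
    return build_mini_model({
        "EX_a": {"stoich": {"a": -1}, "lb": -10, "ub": 0, "kind": "exchange"},
        "R1": {"stoich": {"a": -1, "b": 1}, "ub": 20},
        "R2": {"stoich": {"b": -1, "c": 1}, "ub": 20},
        "CYC_F": {"stoich": {"b": -1, "d": 1}, "ub": 5},
        "CYC_B": {"stoich": {"d": -1, "b": 1}, "ub": 5},
        "EX_c": {"stoich": {"c": -1}, "lb": 0, "ub": 20, "kind": "exchange"},
    }, extracellular=())


def branched_model():
    """Substrate splits into two products with different yields."""
    return build_mini_model({
        "EX_s": {"stoich": {"s": -1}, "lb": -10, "ub": 0, "kind": "exchange"},
        "R_p": {"stoich": {"s": -1, "p": 2}, "ub": 100},
        "R_q": {"stoich": {"s": -1, "q": 1}, "ub": 100},
        "EX_p": {"stoich": {"p": -1}, "lb": 0, "ub": 100, "kind": "exchange"},
        "EX_q": {"stoich": {"q": -1}, "lb": 0, "ub": 100, "kind": "exchange"},
    })


def _arrays(model, env):
    prob = apply_environment(model, env)
    return prob, prob.S, prob.lb, prob.ub


class TestLinearProgramming:
    def test_branched_lp_matches_vertex_enumeration_oracle(self):
        model = branched_model()
        env = mini_env("EX_s", 10.0)
        prob, S, lb, ub = _arrays(model, env)
        c = np.zeros(prob.n)
        c[prob.reaction_index["EX_p"]] = 1.0
        got = solve_lp(prob, c, sense="max")
        want = lp_vertex_oracle(S, lb, ub, c, "max")
        assert got.objective_value == pytest.approx(want, rel=1e-8)
        assert got.objective_value == pytest.approx(20.0)

    def test_weighted_objective_matches_oracle(self):
        model = branched_model()
        env = mini_env("EX_s", 7.0)
        prob, S, lb, ub = _arrays(model, env)
        c = np.zeros(prob.n)
        c[prob.reaction_index["EX_p"]] = 1.0
        c[prob.reaction_index["EX_q"]] = 3.0
        got = solve_lp(prob, c, sense="max")
        want = lp_vertex_oracle(S, lb, ub, c, "max")
        assert got.objective_value == pytest.approx(want, rel=1e-8)

    def test_zero_uptake_gives_zero_growth(self, toy_model):
        env = toy_environments("glucose", storage_in_growth=False)[0]
        from dataclasses import replace
        env = replace(env, substrate_uptake=0.0, ngam=0.0,
                      fixed_rates={"GNG": 0.0})
        sol = fba_max_growth(toy_model, env)
        assert sol.optimal
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_lp_homogeneity_doubling_uptake_doubles_growth(self, toy_model):
        from dataclasses import replace
        env = toy_environments("glucose", storage_in_growth=False)[0]
        env = replace(env, ngam=0.0, nh4_uptake=1e4, pi_uptake=1e4)
        mu1 = fba_max_growth(toy_model, env).objective_value
        mu2 = fba_max_growth(
            toy_model, replace(env, substrate_uptake=2 * env.substrate_uptake)
        ).objective_value
        assert mu2 == pytest.approx(2 * mu1, rel=1e-7)

    def test_steady_state_invariant_on_toy_solutions(self, toy_model):
        env_growth, env_limited = toy_environments("glucose")
        for sol in (fba_max_growth(toy_model, env_growth),
                    l1_minimize(toy_model, env_limited)):
            prob = apply_environment(toy_model, env_growth)
            x = sol.as_array(prob.reaction_ids)
            assert prob.check_steady_state(x) <= 1e-6


class TestL1Minimization:
    def test_linear_chain_carries_demanded_flux_only(self):
        model = chain_model()
        env = mini_env("EX_a", 1.0)
        sol = l1_minimize(model, env)
        assert sol["R1"] == pytest.approx(1.0, abs=1e-8)
        assert sol["R2"] == pytest.approx(1.0, abs=1e-8)
        assert sol["CYC_F"] == pytest.approx(0.0, abs=1e-8)
        assert sol["CYC_B"] == pytest.approx(0.0, abs=1e-8)

    def test_futile_cycle_inactive_at_optimum(self):
        model = chain_model()
        env = mini_env("EX_a", 3.0)
        sol = l1_minimize(model, env)
        assert abs(sol["CYC_F"]) + abs(sol["CYC_B"]) < 1e-8

    def test_matches_exhaustive_sign_pattern_oracle(self):
        model = branched_model()
        env = mini_env("EX_s", 5.0)
        prob, S, lb, ub = _arrays(model, env)
        got = l1_minimize(model, env)
        want = l1_sign_pattern_oracle(S, lb, ub)
        assert got.objective_value == pytest.approx(want, rel=1e-8)

    def test_matches_oracle_with_pinned_demand(self):
        model = chain_model()
        env = mini_env("EX_a", 4.0, fixed={"EX_c": 4.0})
        prob, S, lb, ub = _arrays(model, env)
        got = l1_minimize(model, env)
        want = l1_sign_pattern_oracle(S, lb, ub)
        assert got.objective_value == pytest.approx(want, rel=1e-8)


class TestMomaQP:
    def test_feasible_reference_projects_to_itself(self):
        model = chain_model()
        env = mini_env("EX_a", 2.0)
        base = l1_minimize(model, env)
        sol = moma_qp(model, env, base)
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)
        for rid in base.values:
            assert sol[rid] == pytest.approx(base[rid], abs=1e-6)

    def test_matches_active_set_kkt_oracle_on_small_instance(self):
        model = branched_model()
        ref_env = mini_env("EX_s", 10.0)
        ref = l1_minimize(model, ref_env,
                          constraints=[LinearConstraint({"EX_p": 1.0},
                                                        20.0, "eq")])
        env = mini_env("EX_s", 3.0)  # tightened uptake forces adjustment
        got = moma_qp(model, env, ref)
        prob, S, lb, ub = _arrays(model, env)
        want = moma_active_set_oracle(S, lb, ub,
                                      ref.as_array(prob.reaction_ids))
        got_x = got.as_array(prob.reaction_ids)
        np.testing.assert_allclose(got_x, want, atol=1e-6)

    def test_distance_nondecreasing_as_bounds_tighten(self):
        model = branched_model()
        ref = l1_minimize(model, mini_env("EX_s", 10.0),
                          constraints=[LinearConstraint({"EX_p": 1.0},
                                                        20.0, "eq")])
        dists = [moma_qp(model, mini_env("EX_s", u), ref).objective_value
                 for u in (8.0, 5.0, 2.0)]
        assert dists == sorted(dists)

    def test_infeasible_environment_reported(self):
        model = chain_model()
        env = mini_env("EX_a", 1.0, fixed={"EX_c": 5.0})  # demands > supply
        ref = l1_minimize(model, mini_env("EX_a", 1.0))
        sol = moma_qp(model, env, ref)
        assert sol.status == "infeasible"


class TestFVA:
    def test_fully_determined_chain_has_point_ranges(self):
        model = chain_model()
        env = mini_env("EX_a", 2.0, fixed={"EX_c": 2.0})
        lo, hi = fva_range(model, env, "R1")
        assert lo == pytest.approx(hi, abs=1e-8)
        assert lo == pytest.approx(2.0, abs=1e-8)

    def test_free_cycle_range_equals_cycle_capacity(self):
        model = chain_model()
        env = mini_env("EX_a", 2.0, fixed={"EX_c": 2.0})
        lo, hi = fva_range(model, env, "CYC_F")
        assert (lo, hi) == pytest.approx((0.0, 5.0), abs=1e-8)

    def test_relaxing_a_fixed_rate_never_shrinks_ranges(self):
        model = branched_model()
        fixed_env = mini_env("EX_s", 6.0, fixed={"EX_p": 4.0})
        free_env = mini_env("EX_s", 6.0)
        for rid in ("R_p", "R_q", "EX_q"):
            lo_f, hi_f = fva_range(model, fixed_env, rid)
            lo_r, hi_r = fva_range(model, free_env, rid)
            assert lo_r <= lo_f + 1e-9
            assert hi_r >= hi_f - 1e-9

    def test_conflicting_fixed_rates_raise_with_diagnosis(self):
        model = chain_model()
        env = mini_env("EX_a", 1.0, fixed={"EX_c": 9.0})
        with pytest.raises(RuntimeError, match="fixed"):
            fva_range(model, env, "R1")


def test_environment_rejects_negative_uptakes():
    from storflux.fba import Environment
    with pytest.raises(ValueError):
        Environment(substrate_exchange="EX_s", substrate_uptake=-1.0)


def test_apply_environment_missing_exchange_errors(toy_model):
    from storflux.fba import Environment
    env = Environment(substrate_exchange="EX_nope", substrate_uptake=1.0)
    with pytest.raises(KeyError, match="EX_nope"):
        apply_environment(toy_model, env)


def test_nh4_shutoff_blocks_uptake(toy_model):
    env_growth, env_limited = toy_environments("glucose")
    prob = apply_environment(toy_model, env_limited)
    j = prob.reaction_index["EX_nh4"]
    assert prob.lb[j] == 0.0  # no uptake direction left


def test_ngam_forced_as_equality(toy_model):
    env = toy_environments("glucose", ngam_limited=0.5)[1]
    prob = apply_environment(toy_model, env)
    j = prob.reaction_index["MAINT"]
    assert prob.lb[j] == prob.ub[j] == 0.5
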