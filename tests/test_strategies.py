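"""Strategy optimization: DP vs exhaustive enumeration, dominance, accounting."""

import itertools

import numpy as np
import pytest

from chdopt.economics import (
    EconomicParameters,
    EndStateValues,
    StateValue,
    endstate_values,
    treatment_threshold,
)
from chdopt.risk_update import LikelihoodTable
from chdopt.strategies import (
    STRATEGIES,
    RiskDistribution,
    StrategyModel,
    default_risk_grid,
    evaluate_strategies,
    evaluate_strategy,
    rank_strategies,
    solve_strategy,
    treat_stage_value,
)


def _endstates_from_nmbs(n1, n2, n3, n4, wtp=1.0):
    mk = lambda v: StateValue(cost=0.0, qaly=v / wtp, nmb=v)
    return EndStateValues(mk(n1), mk(n2), mk(n3), mk(n4), wtp=wtp)


def _two_bin(l1, l0, name):
    return LikelihoodTable(
        name, np.array([-np.inf, 0.0, np.inf]), np.asarray(l1, float), np.asarray(l0, float)
    )


def _enumerate_two_test_value(p, nmbs, lik_a, lik_b, cost_a, cost_b):
    """Exhaustive enumeration over all deterministic test-then-treat policies.

    Independent oracle for the two-test optimized strategy: the first action
    is no-treat, treat, or test A; after each A result, no-treat, treat, or
    test B; after each B result, treat or not.  Expectations are taken
    directly over (state, result-A, result-B).
    """
    n1, n2, n3, n4 = nmbs

    def terminal(state, treat):
        return (n4 if treat else n3) if state else (n2 if treat else n1)

    def cont_value(state, option):
        if option in (False, True):
            return terminal(state, option)
        b_map = option  # tuple of treat decisions per B bin
        probs = lik_b.p_result_given_chd if state else lik_b.p_result_given_no_chd
        return -cost_b + sum(probs[b] * terminal(state, b_map[b]) for b in range(len(probs)))

    b_policies = list(itertools.product([False, True], repeat=lik_b.n_bins))
    a_options = [False, True] + b_policies
    values = [
        p * terminal(1, False) + (1 - p) * terminal(0, False),
        p * terminal(1, True) + (1 - p) * terminal(0, True),
    ]
    for assignment in itertools.product(a_options, repeat=lik_a.n_bins):
        val = -cost_a
        for state, p_state in ((1, p), (0, 1 - p)):
            probs = lik_a.p_result_given_chd if state else lik_a.p_result_given_no_chd
            val += p_state * sum(
                probs[a] * cont_value(state, assignment[a]) for a in range(lik_a.n_bins)
            )
        values.append(val)
    return max(values)


@pytest.fixture()
def toy_model():
    endstates = _endstates_from_nmbs(100.0, 92.0, 20.0, 70.0)
    lik_a = _two_bin([0.2, 0.8], [0.8, 0.2], "trs")
    lik_b = _two_bin([0.3, 0.7], [0.7, 0.3], "grs")
    params = EconomicParameters(wtp=1.0, cost_trs=1.0, cost_grs=0.8)
    return StrategyModel(endstates, lik_a, lik_b, params), endstates, lik_a, lik_b


class TestTreatStage:
    def test_extreme_beliefs_forced(self, base_params, base_endstates):
        action0, nmb0, _, _ = treat_stage_value(0.0, base_endstates, base_params)
        assert action0 == "no_treat" and nmb0 == pytest.approx(base_endstates.no_chd_untreated.nmb)
        action1, nmb1, _, _ = treat_stage_value(1.0, base_endstates, base_params)
        assert action1 == "treat" and nmb1 == pytest.approx(base_endstates.chd_treated.nmb)

    def test_action_switches_at_closed_form_threshold(self, base_params, base_endstates):
        p_star = treatment_threshold(base_endstates)
        below = treat_stage_value(p_star - 1e-6, base_endstates, base_params)[0]
        above = treat_stage_value(p_star + 1e-6, base_endstates, base_params)[0]
        assert (below, above) == ("no_treat", "treat")
        assert p_star == pytest.approx(0.186, abs=0.002)


class TestTestStage:
    def test_free_information_never_hurts(self, base_endstates):
        lik = _two_bin([0.2, 0.8], [0.8, 0.2], "trs")
        params = EconomicParameters(cost_trs=0.0)
        model = StrategyModel(base_endstates, lik, None, params)
        p = default_risk_grid()
        tested = model.test_value(p, "trs", model.treat_decision)
        direct = model.treat_decision(p)
        assert (tested.nmb >= direct.nmb - 1e-9).all()

    def test_uninformative_costly_test_loses_exactly_its_cost(self, base_endstates, base_params):
        lik = _two_bin([0.5, 0.5], [0.5, 0.5], "trs")
        model = StrategyModel(base_endstates, lik, None, base_params)
        p = default_risk_grid()
        tested = model.test_value(p, "trs", model.treat_decision)
        direct = model.treat_decision(p)
        np.testing.assert_allclose(tested.nmb, direct.nmb - base_params.cost_trs, atol=1e-9)
        np.testing.assert_allclose(tested.cost, direct.cost + base_params.cost_trs, atol=1e-9)

    def test_missing_likelihood_rejected(self, base_endstates, base_params):
        model = StrategyModel(base_endstates, None, None, base_params)
        with pytest.raises(ValueError):
            model.test_value(np.array([0.2]), "grs", model.treat_decision)


class TestSolveStrategy:
    def test_no_treatment_strategy_is_linear(self, base_endstates, base_params, model_inputs):
        lik_trs, lik_grs, _ = model_inputs
        policy = solve_strategy("i", base_endstates, lik_trs, lik_grs, base_params)
        p = policy.grid["prior"].to_numpy()
        expected = (
            p * base_endstates.chd_untreated.nmb + (1 - p) * base_endstates.no_chd_untreated.nmb
        )
        np.testing.assert_allclose(policy.grid["nmb"], expected, atol=1e-9)
        assert (policy.grid["action"] == "no_treat").all()

    def test_perfect_free_tests_attain_oracle_bound(self):
        endstates = _endstates_from_nmbs(100.0, 92.0, 20.0, 70.0)
        perfect = _two_bin([0.0, 1.0], [1.0, 0.0], "trs")
        grs = _two_bin([0.3, 0.7], [0.7, 0.3], "grs")
        params = EconomicParameters(wtp=1.0, cost_trs=0.0, cost_grs=0.0)
        policy = solve_strategy("v", endstates, perfect, grs, params)
        p = policy.grid["prior"].to_numpy()
        np.testing.assert_allclose(policy.grid["nmb"], p * 70.0 + (1 - p) * 100.0, atol=1e-9)

    def test_two_test_dp_equals_exhaustive_enumeration(self, toy_model):
        model, endstates, lik_a, lik_b = toy_model
        nmbs = (100.0, 92.0, 20.0, 70.0)
        for p in (0.02, 0.05, 0.12, 0.2, 0.35, 0.5, 0.8):
            oracle = _enumerate_two_test_value(p, nmbs, lik_a, lik_b, 1.0, 0.8)
            value, _ = model.value("v", np.array([p]))
            assert value.nmb[0] == pytest.approx(oracle, rel=1e-9)

    def test_forced_strategy_vii_matches_direct_expectation(self, toy_model):
        model, endstates, lik_a, _ = toy_model
        p = 0.15
        # fold the treat decision through the TRS result distribution by hand
        expected = -1.0
        for b in range(lik_a.n_bins):
            l1, l0 = lik_a.p_result_given_chd[b], lik_a.p_result_given_no_chd[b]
            marg = p * l1 + (1 - p) * l0
            post = p * l1 / marg
            treat = post * 70.0 + (1 - post) * 92.0
            no_treat = post * 20.0 + (1 - post) * 100.0
            expected += marg * max(treat, no_treat)
        value, _ = model.value("vii", np.array([p]))
        assert value.nmb[0] == pytest.approx(expected, rel=1e-12)

    def test_embedded_option_dominance_nesting(self, model_inputs):
        """Richer strategies are pointwise at least as valuable on random models."""
        lik_trs, lik_grs, _ = model_inputs
        rng = np.random.default_rng(5)
        for _ in range(4):
            n3, n4 = sorted(rng.uniform(0, 50, 2))
            n2, n1 = sorted(rng.uniform(50, 120, 2))
            endstates = _endstates_from_nmbs(n1, n2, n3, n4)
            params = EconomicParameters(
                wtp=1.0, cost_trs=rng.uniform(0, 2), cost_grs=rng.uniform(0, 2)
            )
            model = StrategyModel(endstates, lik_trs, lik_grs, params)
            p = default_risk_grid()
            nmb = {sid: model.value(sid, p)[0].nmb for sid in STRATEGIES}
            for hi, lo in [
                ("v", "iii"), ("iii", "ii"), ("ii", "i"),
                ("vi", "iv"), ("iv", "ii"),
                ("iii", "vii"), ("iv", "viii"),
            ]:
                assert (nmb[hi] >= nmb[lo] - 1e-9).all(), (hi, lo)

    def test_value_functions_convex_in_prior(
        self, base_endstates, base_params, model_inputs
    ):
        lik_trs, lik_grs, _ = model_inputs
        model = StrategyModel(base_endstates, lik_trs, lik_grs, base_params)
        p = default_risk_grid()
        # ix is excluded: its forced GRS-inside-a-fixed-risk-window rule is a
        # non-convex policy constraint, so its value need not be convex.
        for sid in set(STRATEGIES) - {"ix"}:
            v = model.value(sid, p)[0].nmb
            second_diff = v[2:] - 2 * v[1:-1] + v[:-2]
            assert (second_diff >= -1e-6).all(), sid

    def test_accounting_identity_on_grid(self, base_endstates, base_params, model_inputs):
        lik_trs, lik_grs, _ = model_inputs
        for sid in STRATEGIES:
            policy = solve_strategy(sid, base_endstates, lik_trs, lik_grs, base_params)
            g = policy.grid
            np.testing.assert_allclose(
                g["nmb"], g["qaly"] * base_params.wtp - g["cost"], atol=1.0
            )

    def test_treated_segment_matches_closed_form_threshold(
        self, base_endstates, base_params, model_inputs
    ):
        lik_trs, lik_grs, _ = model_inputs
        p_star = treatment_threshold(base_endstates)
        policy = solve_strategy("ii", base_endstates, lik_trs, lik_grs, base_params)
        treated = policy.grid.loc[policy.grid["action"] == "treat", "prior"]
        assert treated.min() == pytest.approx(np.ceil(p_star * 100) / 100, abs=1e-9)
        assert (policy.grid.loc[policy.grid["prior"] < p_star, "action"] == "no_treat").all()


class TestEvaluateAndRank:
    def test_point_mass_recovers_grid_value(self, base_endstates, base_params, model_inputs):
        lik_trs, lik_grs, _ = model_inputs
        policy = solve_strategy("v", base_endstates, lik_trs, lik_grs, base_params)
        weights = np.zeros(101)
        weights[20] = 1.0
        ev = evaluate_strategy(policy, RiskDistribution(default_risk_grid(), weights))
        row = policy.grid.iloc[20]
        assert ev.nmb == pytest.approx(row["nmb"])
        assert ev.cost == pytest.approx(row["cost"])
        assert ev.qaly == pytest.approx(row["qaly"])

    def test_two_point_mass_is_arithmetic_mean(self, base_endstates, base_params, model_inputs):
        lik_trs, lik_grs, _ = model_inputs
        policy = solve_strategy("iii", base_endstates, lik_trs, lik_grs, base_params)
        weights = np.zeros(101)
        weights[[10, 40]] = 0.5
        ev = evaluate_strategy(policy, RiskDistribution(default_risk_grid(), weights))
        rows = policy.grid.iloc[[10, 40]]
        assert ev.nmb == pytest.approx(rows["nmb"].mean())
        assert ev.share_treated == pytest.approx(rows["p_treat"].mean())

    def test_all_mass_at_zero_risk_treats_nobody(self, base_endstates, base_params, model_inputs):
        lik_trs, lik_grs, _ = model_inputs
        policy = solve_strategy("ii", base_endstates, lik_trs, lik_grs, base_params)
        weights = np.zeros(101)
        weights[0] = 1.0
        ev = evaluate_strategy(policy, RiskDistribution(default_risk_grid(), weights))
        assert ev.share_treated == 0.0

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            RiskDistribution(default_risk_grid(), np.full(101, 0.5))
        with pytest.raises(ValueError):
            RiskDistribution(default_risk_grid(), -np.ones(101) / 101)

    def test_ranking_sorted_and_complete(self, base_params, model_inputs):
        lik_trs, lik_grs, dist = model_inputs
        evals = evaluate_strategies(base_params, lik_trs, lik_grs, dist)
        ranking = rank_strategies(evals)
        assert list(ranking["nmb"]) == sorted(ranking["nmb"], reverse=True)
        assert set(ranking["strategy"]) == set(STRATEGIES)
        assert ((ranking["share_treated"] >= 0) & (ranking["share_treated"] <= 1)).all()

    def test_two_test_optimized_strategy_ranks_first(self, base_params, model_inputs):
        """Qualitative reproduction: the TRS-then-GRS optimized strategy leads."""
        lik_trs, lik_grs, dist = model_inputs
        ranking = rank_strategies(evaluate_strategies(base_params, lik_trs, lik_grs, dist))
        assert ranking.iloc[0]["strategy"] == "v"

    def test_segments_partition_the_grid(self, base_endstates, base_params, model_inputs):
        lik_trs, lik_grs, _ = model_inputs
        policy = solve_strategy("v", base_endstates, lik_trs, lik_grs, base_params)
        seg = policy.segments()
        assert seg["risk_lo"].iloc[0] == 0.0
        assert seg["risk_hi"].iloc[-1] == 1.0
        # contiguous, non-overlapping
        assert (seg["risk_lo"].iloc[1:].to_numpy() > seg["risk_hi"].iloc[:-1].to_numpy()).all()
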