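"""Decision-tree construction, path enumeration, costing and CEA measures."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

import steppedcare as sc
from steppedcare.parameters import ConfigError
from steppedcare.tree import (
    CohortResult,
    StateSchedule,
    compile_expression,
    expected_outcomes_arrays,
)

U_EPISODE = 0.688 * 0.58 + 0.312 * 0.78  # severity-mixed episode utility, 0.6424


@pytest.fixture(scope="module")
def trees(config):
    return {s: sc.build_strategy_tree(s, config) for s in config.strategy_names}


class TestExpressions:
    def test_arithmetic_and_names(self):
        e = compile_expression("1 - 2*x + y/4")
        assert e({"x": 0.25, "y": 2.0}) == pytest.approx(1.0)
        assert e.names == {"x", "y"}

    def test_rejects_non_arithmetic(self):
        with pytest.raises(ConfigError):
            compile_expression("__import__('os')")

    def test_unresolved_name_is_configuration_error(self):
        with pytest.raises(ConfigError, match="unresolved"):
            compile_expression("missing_param")({})


class TestTreeStructure:
    def test_unknown_strategy_rejected(self, config):
        with pytest.raises(ValueError, match="unknown strategy"):
            sc.build_strategy_tree("placebo", config)

    def test_mycompass_tree_references_published_nonadherence(self, config, trees):
        tree = trees["myCompass"]
        assert "nonadherence_acute_mycompass" in tree.parameter_names
        assert config.parameters["nonadherence_acute_mycompass"].point_estimate == 0.279

    def test_branch_probabilities_sum_to_one_at_point_estimates(self, trees, point_params):
        for tree in trees.values():
            paths = sc.enumerate_paths(tree, point_params)
            assert sum(p.probability for p in paths) == pytest.approx(1.0, abs=1e-12)

    @given(seed=st.integers(0, 2**20))
    def test_path_probabilities_sum_to_one_under_sampled_parameters(self, seed):
        config = sc.default_config()
        params = sc.sample_parameters(config, 1, seed=seed)[0]
        for s in config.strategy_names:
            paths = sc.enumerate_paths(sc.build_strategy_tree(s, config), params)
            assert sum(p.probability for p in paths) == pytest.approx(1.0, abs=1e-9)

    def test_two_leaf_toy_tree_enumeration(self, toy_config):
        tree = sc.build_strategy_tree("Gamble", toy_config)
        params = dict(sc.point_parameter_set(toy_config))
        params["p_success"] = 0.3
        paths = sorted(sc.enumerate_paths(tree, params), key=lambda p: p.probability)
        assert [p.probability for p in paths] == pytest.approx([0.3, 0.7])

    def test_switch_mass_matches_hand_arithmetic(self, trees, point_params):
        # mass reaching second-line antidepressants in the myCompass arm:
        # acute non-adherence + adherent non-response
        # = 0.279 + (1 - 0.279) * (1 - 0.449) = 0.676271
        paths = sc.enumerate_paths(trees["myCompass"], point_params)
        switch = sum(p.probability for p in paths if p.terminal_name.startswith("switch"))
        assert switch == pytest.approx(0.279 + 0.721 * 0.551, abs=1e-12)

    def test_zeroing_a_branch_removes_its_paths(self, config, point_params):
        params = dict(point_params)
        params["nonadherence_acute_mycompass"] = 0.0
        paths = sc.enumerate_paths(sc.build_strategy_tree("myCompass", config), params)
        mass = sum(p.probability for p in paths if "after_nonadherence" in p.terminal_name)
        assert mass == 0.0


class TestQALYsAndCosts:
    def test_full_horizon_episode_qaly(self, config, point_params):
        sched = StateSchedule(("episode",) * 4, 7)
        assert sc.path_qaly(sched, point_params, config) == pytest.approx(U_EPISODE * 28 / 52, abs=1e-9)
        assert sc.path_qaly(sched, point_params, config) == pytest.approx(0.3459, abs=5e-4)

    def test_episode_then_maintenance_qaly(self, config, point_params):
        sched = StateSchedule(("episode", "maintenance", "maintenance", "maintenance"), 7)
        expected = (U_EPISODE * 7 + 0.88 * 21) / 52
        assert sc.path_qaly(sched, point_params, config) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.4418, abs=5e-4)

    def test_zero_utilities_give_zero_qalys(self, config, point_params):
        params = dict(point_params)
        params.update(utility_mild=0.0, utility_moderate=0.0, utility_maintenance=0.0)
        sched = StateSchedule(("episode", "maintenance") * 2, 7)
        assert sc.path_qaly(sched, params, config) == 0.0

    def test_path_cost_inner_product(self, point_params):
        assert sc.path_cost({"gp_consultation": 2.48}, point_params) == pytest.approx(2.48 * 36.88)
        assert sc.path_cost({"cbt_course": 1.0}, point_params) == pytest.approx(737.72)
        assert sc.path_cost({}, point_params) == 0.0

    def test_missing_unit_cost_parameter_is_configuration_error(self):
        with pytest.raises(ConfigError, match="cost_cbt_course"):
            sc.path_cost({"cbt_course": 1.0}, {"cost_gp_plan": 71.70})


class TestExpectedOutcomes:
    def test_two_point_expectation(self, toy_config):
        # Gamble arm with p=0.5: leaf values (0 cost, 7/52 QALY) and (0, 0)
        params = dict(sc.point_parameter_set(toy_config))
        params["p_success"] = 0.5
        r = sc.expected_outcomes(sc.build_strategy_tree("Gamble", toy_config), params, toy_config)
        assert r.expected_cost == pytest.approx(0.0)
        assert r.expected_qaly == pytest.approx(0.5 * 7 / 52)

    def test_linear_in_unit_costs(self, config, trees, point_params):
        doubled = dict(point_params)
        for name, spec in config.parameters.items():
            if spec.role == "unit-cost":
                doubled[name] = 2.0 * doubled[name]
        for s, tree in trees.items():
            base = sc.expected_outcomes(tree, point_params, config)
            high = sc.expected_outcomes(tree, doubled, config)
            assert high.expected_cost == pytest.approx(2.0 * base.expected_cost, rel=1e-12)
            assert high.expected_qaly == pytest.approx(base.expected_qaly, rel=1e-12)

    def test_perfect_treatment_reaches_maximum_qaly_path(self, config, trees, point_params):
        # no non-adherence, certain response, certain sustained remission:
        # everyone follows the 7-week-episode + 21-week-maintenance path
        params = dict(point_params)
        for s in ("tau", "cbt", "mycompass"):
            params[f"nonadherence_acute_{s}"] = 0.0
            params[f"nonadherence_maintenance_{s}"] = 0.0
            params[f"eff_initial_{s}"] = 1.0
            params[f"eff_maintenance_{s}"] = 1.0
        expected = (U_EPISODE * 7 + 0.88 * 21) / 52
        for tree in trees.values():
            r = sc.expected_outcomes(tree, params, config)
            assert r.expected_qaly == pytest.approx(expected, abs=1e-12)

    def test_mycompass_cheapest_at_point_estimates(self, config, trees, point_params):
        costs = {s: sc.expected_outcomes(t, point_params, config).expected_cost for s, t in trees.items()}
        assert costs["myCompass"] < costs["TAU"] < costs["CBT"]

    def test_vectorised_evaluation_matches_scalar(self, config, trees):
        env = sc.sample_parameter_arrays(config, 5, seed=21)
        for s, tree in trees.items():
            cost, qaly = expected_outcomes_arrays(tree, env, config)
            for i in range(5):
                params = {k: float(v[i]) for k, v in env.items()}
                r = sc.expected_outcomes(tree, params, config)
                assert cost[i] == pytest.approx(r.expected_cost, rel=1e-12)
                assert qaly[i] == pytest.approx(r.expected_qaly, rel=1e-12)


class TestSummaryMeasures:
    def test_nmb_direct_formula(self):
        assert sc.nmb(0.5, 1000.0, 50_000.0) == 24_000.0
        assert sc.nmb(0.3, 750.0, 0.0) == -750.0

    def test_icer_values_and_undefined_flag(self):
        assert sc.icer(100.0, 0.01) == (10_000.0, "")
        assert sc.icer(0.0, 0.1)[0] == 0.0
        value, note = sc.icer(100.0, 0.0)
        assert value is None and "undefined" in note

    def test_average_cer(self):
        assert sc.average_cer(524.91, 0.24) == pytest.approx(2187.13, abs=0.05)
        assert sc.average_cer(0.0, 0.1) == 0.0
        with pytest.raises(ValueError):
            sc.average_cer(100.0, 0.0)

    def test_incremental_identity_and_sign_convention(self):
        ref = CohortResult("myCompass", 334.96, 0.26)
        comp = CohortResult("TAU", 524.91, 0.24)
        inc = sc.incremental_summary(ref, comp, 50_000.0)
        assert inc.delta_cost == pytest.approx(524.91 - 334.96)
        assert round(inc.delta_cost) == 190
        assert inc.incremental_nmb == pytest.approx(inc.delta_qaly * 50_000.0 - inc.delta_cost, abs=1e-9)

    @given(
        c1=st.floats(0, 5000), c2=st.floats(0, 5000),
        e1=st.floats(0, 0.5), e2=st.floats(0, 0.5),
        wtp=st.floats(0, 100_000),
    )
    def test_incremental_nmb_identity_property(self, c1, c2, e1, e2, wtp):
        inc = sc.incremental_summary(CohortResult("a", c1, e1), CohortResult("b", c2, e2), wtp)
        assert inc.incremental_nmb == pytest.approx(inc.delta_qaly * wtp - inc.delta_cost, abs=1e-9)

    def test_identical_strategies_have_null_increments(self):
        r = CohortResult("a", 100.0, 0.2)
        inc = sc.incremental_summary(r, CohortResult("b", 100.0, 0.2), 50_000.0)
        assert inc.delta_cost == 0 and inc.delta_qaly == 0
        assert inc.icer is None and inc.incremental_nmb == 0
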