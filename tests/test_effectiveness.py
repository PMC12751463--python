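"""Predictive values, outcome states, QALY identities, inflation scaling."""

import pytest

import diagcea as d
from diagcea.effectiveness import WEEKS_PER_YEAR
from diagcea.errors import HorizonError, ModelingError


def contingency_ppv_npv(se, sp, p, n=10**6):
    """Independent oracle: build the expected 2x2 table for an n-cohort."""
    diseased = n * p
    healthy = n - diseased
    tp, fn = diseased * se, diseased * (1 - se)
    tn, fp = healthy * sp, healthy * (1 - sp)
    return tp / (tp + fp), tn / (tn + fn)


class TestPredictiveValues:
    def test_perfect_specificity_gives_ppv_one(self):
        perf = d.TestPerformance(sensitivity=0.6, specificity=1.0)
        assert d.ppv(perf, 0.2) == pytest.approx(1.0)

    def test_zero_prevalence_gives_ppv_zero(self):
        perf = d.TestPerformance(sensitivity=0.9, specificity=0.8)
        assert d.ppv(perf, 0.0) == 0.0

    def test_cma_reference_value(self):
        perf = d.TestPerformance(0.9068, 0.9440)
        assert d.ppv(perf, 0.1665) == pytest.approx(0.7638, abs=5e-4)

    @pytest.mark.parametrize(
        "se,sp,p",
        [
            (0.9068, 0.9440, 0.1665),
            (0.8960, 0.9250, 0.1665),
            (0.9593, 0.9933, 0.1665),
            (0.726, 0.807, 0.41),
            (0.5, 0.5, 0.01),
        ],
    )
    def test_closed_form_matches_contingency_table(self, se, sp, p):
        perf = d.TestPerformance(se, sp)
        oracle_ppv, oracle_npv = contingency_ppv_npv(se, sp, p)
        assert d.ppv(perf, p) == pytest.approx(oracle_ppv, abs=1e-9)
        assert d.npv(perf, p) == pytest.approx(oracle_npv, abs=1e-9)

    def test_degenerate_denominator_raises(self):
        perf = d.TestPerformance(sensitivity=0.0, specificity=1.0)
        with pytest.raises(ModelingError):
            d.ppv(perf, 0.0)

    def test_direct_predictive_values_pass_through(self):
        pv = d.PredictiveValues(ppv=0.74, npv=0.71)
        assert d.ppv(pv, 0.999) == 0.74
        assert d.npv(pv, 0.999) == 0.71


def _state(outcome, tat_years, prob=1.0, perf=None, override=None):
    return d.OutcomeState(
        exit_node_id="x",
        outcome=outcome,
        tat_years=tat_years,
        path_probability=prob,
        terminal_action_id="t" if perf else None,
        performance=perf,
        utility_override=override,
    )


UTIL = d.UtilityWeights(u_tp=0.85, u_tn=0.95, u_fp=0.75, u_fn=-0.25, u_undiagnosed=0.8)
CFG = d.CeaConfig(utilities=UTIL, prevalence=0.1665, horizon_years=1.0)


class TestExpectedUtility:
    def test_certain_positive_gets_u_tp(self):
        state = _state(1, 0.0, perf=d.PredictiveValues(ppv=1.0))
        assert d.expected_utility(state, 0.2, UTIL) == UTIL.u_tp

    def test_negative_mixes_tn_and_fn_by_npv(self):
        state = _state(0, 0.0, perf=d.PredictiveValues(npv=0.5))
        # 0.5*0.95 + 0.5*(-0.25)
        assert d.expected_utility(state, 0.2, UTIL) == pytest.approx(0.35)

    def test_cma_positive_reference(self):
        state = _state(1, 0.0, perf=d.TestPerformance(0.9068, 0.9440))
        assert d.expected_utility(state, 0.1665, UTIL) == pytest.approx(0.8264, abs=5e-4)

    def test_override_wins(self):
        state = _state(None, 0.0, override=-0.25)
        assert d.expected_utility(state, 0.1665, UTIL) == -0.25


class TestQaly:
    def test_zero_tat_limit(self):
        state = _state(1, 0.0, perf=d.PredictiveValues(ppv=1.0))
        assert d.qaly(state, CFG) == CFG.horizon_years * UTIL.u_tp

    def test_full_horizon_tat_limit(self):
        state = _state(1, 1.0, perf=d.PredictiveValues(ppv=1.0))
        assert d.qaly(state, CFG) == CFG.horizon_years * UTIL.u_undiagnosed

    def test_interior_arithmetic(self):
        state = _state(1, 0.5, perf=d.PredictiveValues(ppv=1.0))
        cfg = d.CeaConfig(
            utilities=d.UtilityWeights(0.9, 0.95, 0.75, -0.25, 0.8),
            prevalence=0.2,
        )
        # 0.5*0.8 + 0.5*0.9
        assert d.qaly(state, cfg) == pytest.approx(0.85)

    def test_linear_in_horizon(self):
        perf = d.TestPerformance(0.9, 0.92)
        state = _state(0, 0.25, perf=perf)
        q1 = d.qaly(state, CFG)
        cfg2 = d.CeaConfig(utilities=UTIL, prevalence=0.1665, horizon_years=2.0)
        q2 = d.qaly(state, cfg2)
        eu = d.expected_utility(state, 0.1665, UTIL)
        assert q2 - q1 == pytest.approx(1.0 * eu, rel=1e-12)

    def test_tat_beyond_horizon_raises(self):
        state = _state(1, 1.5, perf=d.PredictiveValues(ppv=1.0))
        with pytest.raises(HorizonError):
            d.qaly(state, CFG)

    def test_raising_undiagnosed_utility_raises_qaly_when_tat_positive(self):
        perf = d.TestPerformance(0.9, 0.92)
        state = _state(0, 0.3, perf=perf)
        low = d.CeaConfig(
            utilities=d.UtilityWeights(0.85, 0.95, 0.75, -0.25, 0.5),
            prevalence=0.1665,
        )
        high = d.CeaConfig(
            utilities=d.UtilityWeights(0.85, 0.95, 0.75, -0.25, 0.9),
            prevalence=0.1665,
        )
        assert d.qaly(state, high) > d.qaly(state, low)


class TestExpectedQaly:
    def test_single_state_passthrough(self):
        state = _state(1, 0.0, 1.0, perf=d.PredictiveValues(ppv=1.0))
        assert d.expected_qaly([state], CFG) == d.qaly(state, CFG)

    def test_equiprobable_average(self):
        a = _state(1, 0.0, 0.5, perf=d.PredictiveValues(ppv=1.0))  # qaly 0.85
        b = _state(0, 0.0, 0.5, perf=d.PredictiveValues(npv=1.0))  # qaly 0.95
        assert d.expected_qaly([a, b], CFG) == pytest.approx(0.9)

    def test_invariant_under_state_splitting(self):
        perf = d.TestPerformance(0.9, 0.92)
        whole = [_state(0, 0.25, 1.0, perf=perf)]
        halves = [_state(0, 0.25, 0.5, perf=perf), _state(0, 0.25, 0.5, perf=perf)]
        assert d.expected_qaly(halves, CFG) == pytest.approx(
            d.expected_qaly(whole, CFG), rel=1e-12
        )

    def test_ratio(self):
        assert d.cost_per_qaly(5021.75, 0.85) == pytest.approx(5907.9, abs=0.1)
        with pytest.raises(ModelingError):
            d.cost_per_qaly(100.0, 0.0)


class TestOutcomeStates:
    def test_scenario4_states(self, table1_params):
        tree, registry, overrides = d.scenario_model("dd_mca_s4", table1_params)
        states = d.outcome_states(tree, registry, overrides=overrides)
        assert len(states) == 2
        by_outcome = {s.outcome: s for s in states}
        # consult 4 wk + exome 8 wk
        assert by_outcome[1].tat_years == pytest.approx(12 / WEEKS_PER_YEAR)
        assert by_outcome[1].path_probability == pytest.approx(27 / 73)
        assert sum(s.path_probability for s in states) == pytest.approx(1.0)

    def test_cma_positive_tat_is_six_weeks(self, table1_params):
        tree, registry, overrides = d.scenario_model("dd_mca_s1", table1_params)
        states = {s.exit_node_id: s for s in d.outcome_states(tree, registry, overrides=overrides)}
        assert states["5x"].tat_years == pytest.approx(6 / WEEKS_PER_YEAR)

    def test_scenario2_negative_terminal_is_the_exome_test(self, table1_params):
        tree, registry, overrides = d.scenario_model("dd_mca_s2", table1_params)
        states = {s.exit_node_id: s for s in d.outcome_states(tree, registry, overrides=overrides)}
        terminal = states["26x"]
        assert terminal.outcome == 0
        assert terminal.terminal_action_id == "24"
        assert terminal.performance == d.TestPerformance(0.9593, 0.9933)

    def test_exit_without_result_needs_override(self):
        nodes = [
            d.Node("r", "decision", base_cost=10.0),
            d.Node("a", "action", base_cost=5.0),
            d.Node("x", "exit"),
        ]
        edges = [d.Transition("r", "a", 1.0), d.Transition("a", "x", 1.0)]
        tree = d.DiagnosticTree.build(nodes, edges, "r")
        with pytest.raises(ModelingError, match="no result node"):
            d.outcome_states(tree, {})
        states = d.outcome_states(tree, {}, overrides={"x": 0.6})
        assert states[0].utility_override == 0.6

    def test_missing_registry_entry_names_the_action(self, table1_params):
        tree, _, overrides = d.scenario_model("dd_mca_s4", table1_params)
        with pytest.raises(ModelingError, match="'4'"):
            d.outcome_states(tree, {}, overrides=overrides)


class TestInflation:
    def test_identity_when_indices_equal(self):
        assert d.adjust_for_inflation(825.0, 100.0, 100.0) == 825.0

    @pytest.mark.parametrize("original,adjusted", [(825.0, 871.39), (165.0, 174.28)])
    def test_published_adjustments_at_their_ratio(self, original, adjusted):
        ratio = 871.39 / 825.0  # same price-index ratio for both rows
        assert d.adjust_for_inflation(original, ratio, 1.0) == pytest.approx(
            adjusted, abs=0.005
        )

    def test_nonpositive_base_index_raises(self):
        with pytest.raises(ValueError):
            d.adjust_for_inflation(100.0, 1.0, 0.0)


class TestUtilityWeightsValidation:
    def test_true_positive_must_beat_false_positive(self):
        with pytest.raises(ValueError, match="u_tp"):
            d.UtilityWeights(u_tp=0.7, u_tn=0.95, u_fp=0.75, u_fn=-0.2, u_undiagnosed=0.8)

    def test_false_negative_may_be_worse_than_death(self):
        w = d.UtilityWeights(u_tp=0.85, u_tn=0.95, u_fp=0.75, u_fn=-0.5, u_undiagnosed=0.8)
        assert w.u_fn == -0.5
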