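"""Fuzzy risk engine: membership, inference, defuzzification, alerts."""

import itertools

import numpy as np
import pytest

from sensrec.fuzzy import (
    AggregatedSet,
    Categorical,
    FuzzyRule,
    Gaussian,
    InferenceError,
    LinguisticVariable,
    Trapezoid,
    activate,
    aggregate,
    build_all_controllers,
    build_controller,
    compare_defuzzifiers,
    defuzzify,
    fuzzify,
    load_defuzz_suite,
    load_worked_examples,
    mu,
    track_duration,
    two_rule_demo_controller,
)
from sensrec.fuzzy.engine import build_alert

CATEGORY_RANK = {"Low": 0, "Medium": 1, "High": 2}


@pytest.fixture(scope="module")
def controllers():
    return build_all_controllers()


class TestMembership:
    def test_trapezoid_plateau(self):
        assert mu(Trapezoid(0, 1, 2, 3), 1.5) == 1.0

    def test_trapezoid_ramp_midpoint(self):
        assert mu(Trapezoid(0, 1, 2, 3), 0.5) == 0.5

    def test_gaussian_peak(self):
        assert mu(Gaussian(26.0, 3.0), 26.0) == 1.0

    def test_degrees_bounded(self):
        shapes = [Trapezoid(0, 1, 2, 3), Gaussian(5, 2)]
        for shape in shapes:
            for x in np.linspace(-10, 20, 121):
                assert 0.0 <= mu(shape, x) <= 1.0

    def test_invalid_parameters_fail_at_construction(self):
        with pytest.raises(ValueError):
            Trapezoid(3, 2, 1, 0)
        with pytest.raises(ValueError):
            Gaussian(0, -1)

    def test_categorical_indicator(self):
        assert mu(Categorical("low"), "low") == 1.0
        assert mu(Categorical("low"), "normal") == 0.0


class TestFuzzify:
    @pytest.mark.parametrize(
        "modality,value,expected_argmax",
        [("brightness", 750, "High"), ("temperature", 26, "Moderate"), ("noise", 80, "High"),
         ("brightness", 100, "Low"), ("temperature", 15, "Low"), ("noise", 60, "Moderate")],
    )
    def test_stimulus_exemplars_argmax_term(self, controllers, modality, value, expected_argmax):
        degrees = fuzzify(controllers[modality].stimulus, value)
        assert max(degrees, key=degrees.get) == expected_argmax

    def test_out_of_universe_values_are_clamped(self, controllers):
        degrees = fuzzify(controllers["noise"].stimulus, 500.0)
        assert degrees == fuzzify(controllers["noise"].stimulus, 90.0)

    def test_unknown_categorical_level_rejected(self, controllers):
        with pytest.raises(InferenceError):
            fuzzify(controllers["noise"].attention, "asleep")

    def test_coverage_invariant_on_all_numeric_variables(self, controllers):
        for controller in controllers.values():
            assert controller.stimulus.check_coverage() >= 0.5
            assert controller.duration.check_coverage() >= 0.5
            assert controller.output.check_coverage() >= 0.5


class TestRules:
    def test_activation_is_min_of_antecedents(self):
        rule = FuzzyRule({"stimulus": "High", "duration": "Long"}, "High Risk")
        inputs = {"stimulus": {"High": 0.7}, "duration": {"Long": 0.4}}
        assert activate(rule, inputs) == 0.4
        inputs["duration"]["Long"] = 0.0
        assert activate(rule, inputs) == 0.0
        assert activate(rule, {"stimulus": {"High": 1.0}, "duration": {"Long": 1.0}}) == 1.0

    def test_missing_variable_names_the_variable(self):
        rule = FuzzyRule({"stimulus": "High", "duration": "Long"}, "High Risk")
        with pytest.raises(InferenceError, match="duration"):
            activate(rule, {"stimulus": {"High": 1.0}})

    def test_sixty_three_rules_shipped(self, controllers):
        assert sum(len(c.rules) for c in controllers.values()) == 63
        assert all(len(c.rules) == 21 for c in controllers.values())

    def test_every_term_combination_reachable(self, controllers):
        for controller in controllers.values():
            for combo in itertools.product(
                controller.stimulus.order,
                controller.duration.order,
                controller.attention.order,
                controller.stress.order,
            ):
                named = dict(zip(("stimulus", "duration", "attention", "stress"), combo))
                assert any(rule.matches(named) for rule in controller.rules)


class TestAggregationAndDefuzz:
    def test_single_full_strength_rule_reproduces_consequent(self, controllers):
        output = controllers["noise"].output
        rule = FuzzyRule({"stimulus": "High"}, "Medium Risk")
        agg = aggregate([(rule, 1.0)], output)
        expected = output.terms["Medium Risk"].mu_array(agg.xs)
        assert np.allclose(agg.mus, expected)

    def test_zero_strength_rule_contributes_nothing(self, controllers):
        output = controllers["noise"].output
        low = FuzzyRule({"stimulus": "Low"}, "Low Risk")
        high = FuzzyRule({"stimulus": "High"}, "High Risk")
        only_low = aggregate([(low, 1.0)], output)
        both = aggregate([(low, 1.0), (high, 0.0)], output)
        assert np.allclose(both.mus, only_low.mus)

    def test_two_half_rules_on_disjoint_consequents_are_bimodal(self, controllers):
        output = controllers["noise"].output
        low = FuzzyRule({"stimulus": "Low"}, "Low Risk")
        high = FuzzyRule({"stimulus": "High"}, "High Risk")
        agg = aggregate([(low, 0.5), (high, 0.5)], output)
        assert agg.mus.max() == pytest.approx(0.5)
        mid = (agg.xs > 4.0) & (agg.xs < 6.0)
        assert agg.mus[mid].min() < 0.5  # dip between the two plateaus

    def test_symmetric_set_centroid_and_lom_agree(self):
        xs = np.linspace(0, 10, 1001)
        mus = np.clip(1 - np.abs(xs - 5) / 2, 0, None)
        agg = AggregatedSet(xs, mus)
        assert defuzzify(agg, "centroid") == pytest.approx(5.0)
        assert defuzzify(agg, "LOM") == pytest.approx(5.0)

    def test_lom_takes_largest_point_of_plateau(self):
        xs = np.linspace(0, 10, 1001)
        mus = np.where((xs >= 6) & (xs <= 8), 1.0, 0.0)
        assert defuzzify(AggregatedSet(xs, mus), "LOM") == pytest.approx(8.0)

    def test_empty_set_cannot_be_defuzzified(self):
        xs = np.linspace(0, 10, 11)
        with pytest.raises(InferenceError):
            defuzzify(AggregatedSet(xs, np.zeros_like(xs), empty=True))

    def test_lom_in_support_centroid_in_hull(self, controllers):
        rng = np.random.default_rng(0)
        controller = controllers["temperature"]
        for _ in range(50):
            fuzzified = controller.fuzzify_inputs(
                rng.uniform(-10, 45), rng.uniform(0, 120),
                rng.choice(["low", "normal"]), rng.choice(["low", "moderate", "high"]),
            )
            agg = controller.aggregate(fuzzified)
            support = agg.xs[agg.mus > 0]
            lom = defuzzify(agg, "LOM")
            centroid = defuzzify(agg, "centroid")
            assert support.min() <= lom <= support.max()
            assert agg.mus[np.argmin(np.abs(agg.xs - lom))] == pytest.approx(agg.mus.max())
            assert support.min() <= centroid <= support.max()


class TestInference:
    def test_worked_examples_reproduce_levels_and_categories(self, controllers):
        for case in load_worked_examples():
            result = controllers[case["modality"]].infer(
                case["stimulus"], case["duration"], case["attention"], case["stress"]
            )
            assert result.stimulus_level == case["level"], case
            assert result.category == case["category"], case

    def test_moderate_brightness_normal_low_is_no_impact(self, controllers):
        result = controllers["brightness"].infer(400, 40, "normal", "low")
        assert result.category == "Low"
        assert result.strategy == "Brightness level is moderate. No impact."

    def test_hot_room_distressed_child_gets_deep_pressure(self, controllers):
        result = controllers["temperature"].infer(32, 40, "low", "high")
        assert result.category == "High"
        assert "Reduce temperature" in result.strategy
        assert "deep pressure" in result.strategy

    def test_loud_room_gets_fidget_toy(self, controllers):
        result = controllers["noise"].infer(80, 40, "low", "moderate")
        assert result.category == "High"
        assert "fidget toy" in result.strategy

    def test_risk_monotone_in_duration_and_stress(self, controllers):
        stress_order = ["low", "moderate", "high"]
        durations = [5, 15, 25, 32, 38, 60, 200]
        for controller, stimuli in (
            (controllers["temperature"], [15, 25, 32]),
            (controllers["brightness"], [100, 400, 750]),
            (controllers["noise"], [40, 60, 80]),
        ):
            for stimulus in stimuli:
                for attention in ("normal", "low"):
                    for stress in stress_order:
                        ranks = [
                            CATEGORY_RANK[controller.infer(stimulus, d, attention, stress).category]
                            for d in durations
                        ]
                        assert ranks == sorted(ranks), (controller.modality, stimulus, stress)
                    for d in durations:
                        ranks = [
                            CATEGORY_RANK[controller.infer(stimulus, d, attention, s).category]
                            for s in stress_order
                        ]
                        assert ranks == sorted(ranks), (controller.modality, stimulus, d)

    def test_controllers_are_independent(self, controllers):
        base = controllers["brightness"].infer(400, 10, "normal", "low")
        for noise_level in (40, 60, 80):
            controllers["noise"].infer(noise_level, 50, "low", "high")
            again = controllers["brightness"].infer(400, 10, "normal", "low")
            assert again == base

    def test_inference_is_deterministic(self, controllers):
        a = controllers["noise"].infer(73.5, 27.2, "low", "moderate")
        b = controllers["noise"].infer(73.5, 27.2, "low", "moderate")
        assert a == b


class TestDefuzzifierComparison:
    def test_two_rule_scenario_diverges(self):
        demo = two_rule_demo_controller()
        lom = demo.infer(32, 27, "normal", "low", method="LOM")
        centroid = demo.infer(32, 27, "normal", "low", method="centroid")
        assert lom.category == "High"
        assert centroid.category == "Medium"

    def test_lom_matches_all_combinations_centroid_strictly_fewer(self):
        modality, suite = load_defuzz_suite()
        assert len(suite) == 21
        fractions = compare_defuzzifiers(build_controller(modality), suite)
        assert fractions["LOM"] == 1.0
        assert fractions["centroid"] < 1.0

    def test_empty_suite_is_an_error(self, controllers):
        with pytest.raises(ValueError):
            compare_defuzzifiers(controllers["noise"], [])


class TestDurationTracking:
    def test_counts_consecutive_atypical_seconds(self):
        stream = [("low", "high", "high")] * 25
        assert track_duration(stream) == list(range(1, 26))

    def test_reset_on_recovery(self):
        stream = [("low", "low", "high")] * 3 + [("normal", "low", "high")] + [("low", "low", "high")] * 2
        assert track_duration(stream) == [1, 2, 3, 0, 1, 2]

    def test_all_normal_stream_stays_zero(self):
        assert track_duration([("normal", "low", "moderate")] * 10) == [0] * 10

    def test_moderate_stimulus_does_not_accumulate(self):
        assert track_duration([("low", "high", "moderate")] * 5) == [0] * 5


class TestAlerts:
    def _assessment(self, category):
        from sensrec.fuzzy import RiskAssessment

        return RiskAssessment(9.0, category, "noise", "high", "strategy text")

    def test_high_risk_with_subscription_emits_payload(self):
        payload = build_alert(self._assessment("High"), "+86 138 0000 0000", timestamp=12)
        assert payload["recipient"] == "+86 138 0000 0000"
        assert payload["category"] == "High"
        assert payload["timestamp"] == 12

    def test_low_risk_with_subscription_is_silent(self):
        assert build_alert(self._assessment("Low"), "+8613800000000") is None

    def test_high_risk_without_subscription_is_silent(self):
        assert build_alert(self._assessment("High"), None) is None

    def test_malformed_phone_rejected(self):
        with pytest.raises(ValueError):
            build_alert(self._assessment("High"), "not-a-number")
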