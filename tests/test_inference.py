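import itertools

import pytest

from vitalfuzz import (
    CONDITION_CODES,
    VITAL_ORDER,
    VOCABULARY,
    ConditionActivation,
    ConditionLabel,
    FuzzyRule,
    RuleBase,
    RuleConflictError,
    VitalKind,
    aggregate,
    build_rulebase,
    defuzzify,
    evaluate_rule,
    fallback_condition,
    fuzzify_sample,
    infer_condition,
    infer_condition_detailed,
)
from vitalfuzz.inference import ANY, CALIBRATION_RULES, PRINTED_RULES, CrispCondition
from tests.conftest import sample_from_labels

C = ConditionLabel
ALL_NORMAL = ("Normal", "Normal", "Normal", "Normal", "Normal")


def mk_rule(temp, hr, spo2, bp, gl, consequent, provenance="test"):
    return FuzzyRule(
        antecedent=dict(zip(VITAL_ORDER, (temp, hr, spo2, bp, gl))),
        consequent=consequent,
        provenance=provenance,
    )


class TestConditionCodes:
    def test_bijection(self):
        assert CONDITION_CODES == {
            C.critical: 0,
            C.very_critical: 1,
            C.very_unhealthy: 2,
            C.unhealthy: 3,
            C.moderate_unhealthy: 4,
            C.healthy: 5,
        }
        assert sorted(CONDITION_CODES.values()) == list(range(6))

    def test_severity_order(self):
        order = [C.healthy, C.moderate_unhealthy, C.unhealthy,
                 C.very_unhealthy, C.critical, C.very_critical]
        assert [lab.severity for lab in order] == list(range(6))


class TestBuildRulebase:
    def test_contains_expert_rules(self, rulebase):
        keys = {r.antecedent_key(): r.consequent for r in rulebase}
        assert keys[("Normal", "Normal", "Critical", "Elevated", "Normal")] == C.critical
        assert keys[("Low", "Low", "Worrisome", "Low", "Normal")] == C.very_unhealthy
        assert keys[("Low", "Normal", "Worrisome", "Elevated", "Normal")] == C.critical

    def test_expert_rules_take_precedence_over_duplicate_calibration_rows(self, rulebase):
        # three calibration rows duplicate expert rules; they are merged
        provs = [r.provenance for r in rulebase]
        assert len(rulebase) == 11
        assert provs.count("table8_row_1") == 0  # same antecedent as rule 1
        assert all(f"printed_rule_{i}" in provs for i in range(1, 8))

    def test_conflicting_rules_rejected(self):
        a = mk_rule("Low", "Low", "Normal", "Normal", "Normal", C.healthy, "a")
        b = mk_rule("Low", "Low", "Normal", "Normal", "Normal", C.critical, "b")
        with pytest.raises(RuleConflictError, match="a"):
            RuleBase((a, b))

    def test_invalid_antecedent_label_rejected(self):
        with pytest.raises(ValueError):
            mk_rule("Elevated", "Normal", "Normal", "Normal", "Normal", C.healthy)


class TestEvaluateRule:
    def test_min_of_degrees(self, cfg_default):
        # construct a sample whose Low-BP degree is fractional (BP 91.5 is on
        # the rising shoulder between Low and Normal)
        from vitalfuzz import VitalSample

        s = VitalSample("p", 0, 30, 60, 91.5, 90.5, 85)
        fz = fuzzify_sample(s, cfg_default)
        rule = mk_rule("Low", "Low", "Worrisome", "Low", "Normal", C.very_unhealthy)
        strength = evaluate_rule(rule, fz)
        expected = min(
            fz.degree(VitalKind.temperature, "Low"),
            fz.degree(VitalKind.heart_rate, "Low"),
            fz.degree(VitalKind.oxygen_saturation, "Worrisome"),
            fz.degree(VitalKind.blood_pressure, "Low"),
            fz.degree(VitalKind.glucose, "Normal"),
        )
        assert 0 < strength < 1 and strength == expected

    def test_exact_match_fires_at_one(self, cfg_default):
        fz = fuzzify_sample(sample_from_labels("Low", "Low", "Worrisome", "Low", "Normal"), cfg_default)
        rule = mk_rule("Low", "Low", "Worrisome", "Low", "Normal", C.very_unhealthy)
        assert evaluate_rule(rule, fz) == 1.0

    def test_zero_degree_kills_rule(self, cfg_default):
        fz = fuzzify_sample(sample_from_labels(*ALL_NORMAL), cfg_default)
        rule = mk_rule("Low", "Normal", "Normal", "Normal", "Normal", C.unhealthy)
        assert evaluate_rule(rule, fz) == 0.0

    def test_any_contributes_one(self, cfg_default):
        fz = fuzzify_sample(sample_from_labels(*ALL_NORMAL), cfg_default)
        rule = mk_rule(ANY, ANY, ANY, ANY, ANY, C.healthy)
        assert evaluate_rule(rule, fz) == 1.0


class TestAggregate:
    def test_single_rule(self, cfg_default):
        fz = fuzzify_sample(sample_from_labels("High", "Normal", "Worrisome", "Normal", "Normal"), cfg_default)
        rb = RuleBase((mk_rule("High", "Normal", "Worrisome", "Normal", "Normal", C.moderate_unhealthy),))
        act = aggregate(rb, fz)
        assert act.strengths[C.moderate_unhealthy] == 1.0
        assert all(s == 0.0 for lab, s in act.strengths.items() if lab != C.moderate_unhealthy)

    def test_max_over_same_consequent(self, cfg_default):
        from vitalfuzz import VitalSample

        # BP 90.5 gives fractional Low and Normal degrees
        s = VitalSample("p", 0, 36.5, 130, 97, 90.5, 85)
        fz = fuzzify_sample(s, cfg_default)
        r1 = mk_rule("Normal", "Normal", "Normal", "Low", "Normal", C.critical, "r1")
        r2 = mk_rule("Normal", "Normal", "Normal", "Normal", "Normal", C.critical, "r2")
        act = aggregate(RuleBase((r1, r2)), fz)
        assert act.strengths[C.critical] == max(evaluate_rule(r1, fz), evaluate_rule(r2, fz))

    def test_no_rule_fires(self, cfg_default, rulebase):
        fz = fuzzify_sample(sample_from_labels(*ALL_NORMAL), cfg_default)
        act = aggregate(rulebase, fz)
        assert all(s == 0.0 for s in act.strengths.values())


class TestFallback:
    @pytest.mark.parametrize(
        "labels, expected",
        [
            (ALL_NORMAL, C.healthy),
            (("Low", "Normal", "Normal", "Normal", "Normal"), C.moderate_unhealthy),
            (("Low", "Low", "Normal", "Normal", "Normal"), C.unhealthy),
            (("Low", "Low", "Worrisome", "Normal", "Normal"), C.very_unhealthy),
            (("Low", "Low", "Worrisome", "Low", "Normal"), C.critical),
            (("Low", "Low", "Critical", "Low", "High"), C.very_critical),
        ],
    )
    def test_abnormal_count_grading(self, labels, expected):
        assert fallback_condition(labels) == expected

    def test_monotone_in_abnormality(self):
        # flipping any one vital from Normal to abnormal never lowers severity
        for i, kind in enumerate(VITAL_ORDER):
            for base in itertools.product(*(VOCABULARY[k] for k in VITAL_ORDER)):
                if base[i] != "Normal":
                    continue
                for abnormal in VOCABULARY[kind]:
                    if abnormal == "Normal":
                        continue
                    flipped = list(base)
                    flipped[i] = abnormal
                    assert (
                        fallback_condition(flipped).severity
                        >= fallback_condition(base).severity
                    )


class TestDefuzzify:
    def test_severity_tie_break(self):
        act = ConditionActivation({lab: 0.0 for lab in C} | {C.critical: 0.6, C.unhealthy: 0.6})
        assert defuzzify(act, ALL_NORMAL) == CrispCondition(C.critical)
        assert defuzzify(act, ALL_NORMAL).code == 0

    def test_fallback_on_zero_activation(self):
        act = ConditionActivation({lab: 0.0 for lab in C})
        assert defuzzify(act, ALL_NORMAL).code == 5

    def test_single_activation(self):
        act = ConditionActivation({lab: 0.0 for lab in C} | {C.unhealthy: 0.4})
        assert defuzzify(act, ALL_NORMAL).code == 3


class TestInferCondition:
    @pytest.mark.parametrize("rule", PRINTED_RULES + CALIBRATION_RULES,
                             ids=lambda r: r.provenance)
    def test_rule_fidelity(self, rule, cfg_default, rulebase):
        # feeding each rule's antecedent plateau values reproduces its consequent
        labels = rule.antecedent_key()
        crisp = infer_condition(sample_from_labels(*labels), cfg_default, rulebase)
        assert crisp.label == rule.consequent

    def test_table5_row1_critical(self, cfg_default, rulebase):
        s = sample_from_labels("Normal", "Normal", "Critical", "Elevated", "Normal")
        assert infer_condition(s, cfg_default, rulebase).code == 0

    def test_table5_row3_unhealthy(self, cfg_default, rulebase):
        s = sample_from_labels("Low", "Low", "Worrisome", "Normal", "Elevated")
        assert infer_condition(s, cfg_default, rulebase).code == 3

    def test_healthy_fallback(self, cfg_default, rulebase):
        res = infer_condition_detailed(sample_from_labels(*ALL_NORMAL), cfg_default, rulebase)
        assert res.condition.code == 5
        assert res.matched_rule == "fallback"

    def test_exhaustive_label_combinations(self, cfg_default, rulebase):
        # all 3*3*3*4*4 = 432 crisp combinations resolve without conflict
        combos = list(itertools.product(*(VOCABULARY[k] for k in VITAL_ORDER)))
        assert len(combos) == 432
        for combo in combos:
            crisp = infer_condition(sample_from_labels(*combo), cfg_default, rulebase)
            assert isinstance(crisp.label, ConditionLabel)
            assert 0 <= crisp.code <= 5

    def test_deterministic(self, cfg_default, rulebase):
        s = sample_from_labels("Low", "Normal", "Worrisome", "Elevated", "Normal")
        codes = {infer_condition(s, cfg_default, rulebase).code for _ in range(5)}
        assert len(codes) == 1
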