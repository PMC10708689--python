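"""Fuzzy rule base, Mamdani inference and defuzzification to crisp condition codes.

The health condition of a patient is one of six ordered states, from least to
most severe: Healthy, Moderate Unhealthy, Unhealthy, Very Unhealthy,
Critical, Very Critical.  Each state carries a fixed integer code used on
the wire (Critical = 0, Very Critical = 1, Very Unhealthy = 2,
Unhealthy = 3, Moderate Unhealthy = 4, Healthy = 5).

Inference follows the Mamdani convention: a rule's firing strength is the
minimum of its antecedent membership degrees (AND = min), per-condition
activations are the maximum over rules sharing a consequent
(aggregation = max), and defuzzification picks the condition with the
highest activation, breaking ties toward the more severe state.  When no
rule fires at all, a fallback grades the condition by the number of vitals
whose crisp label is abnormal (0 abnormal -> Healthy ... 5 -> Very Critical).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .core import (
    VITAL_ORDER,
    VOCABULARY,
    RangeTable,
    VitalKind,
    VitalSample,
    classify_sample,
    default_range_table,
)
from .membership import FuzzifiedSample, FuzzySystemConfig, builtin_paramset

#: Antecedent wildcard: the rule does not constrain this vital.
ANY = "ANY"


class ConditionLabel(str, Enum):
    """Six health states with a total severity order (Healthy least severe)."""

    healthy = "Healthy"
    moderate_unhealthy = "Moderate Unhealthy"
    unhealthy = "Unhealthy"
    very_unhealthy = "Very Unhealthy"
    critical = "Critical"
    very_critical = "Very Critical"

    @property
    def severity(self) -> int:
        return _SEVERITY[self]

    @property
    def code(self) -> int:
        return CONDITION_CODES[self]


_SEVERITY = {label: i for i, label in enumerate(ConditionLabel)}

#: Crisp integer code per condition.
CONDITION_CODES: dict[ConditionLabel, int] = {
    ConditionLabel.critical: 0,
    ConditionLabel.very_critical: 1,
    ConditionLabel.very_unhealthy: 2,
    ConditionLabel.unhealthy: 3,
    ConditionLabel.moderate_unhealthy: 4,
    ConditionLabel.healthy: 5,
}

CODE_TO_CONDITION: dict[int, ConditionLabel] = {v: k for k, v in CONDITION_CODES.items()}


@dataclass(frozen=True)
class CrispCondition:
    """The defuzzified outcome: a condition label and its integer code."""

    label: ConditionLabel

    @property
    def code(self) -> int:
        return self.label.code


@dataclass(frozen=True)
class FuzzyRule:
    """IF <per-vital labels, ANY allowed> THEN <condition>."""

    antecedent: Mapping[VitalKind, str]
    consequent: ConditionLabel
    provenance: str = "custom"

    def __post_init__(self) -> None:
        for kind, label in self.antecedent.items():
            if label != ANY and label not in VOCABULARY[kind]:
                raise ValueError(f"{label!r} is not a valid {kind.value} label")

    def antecedent_key(self) -> tuple[str, ...]:
        return tuple(self.antecedent.get(kind, ANY) for kind in VITAL_ORDER)


class RuleConflictError(ValueError):
    """Two rules share an antecedent but demand different consequents."""


@dataclass(frozen=True)
class RuleBase:
    """An ordered, conflict-free collection of fuzzy rules."""

    rules: tuple[FuzzyRule, ...]

    def __post_init__(self) -> None:
        seen: dict[tuple[str, ...], FuzzyRule] = {}
        for rule in self.rules:
            key = rule.antecedent_key()
            prev = seen.get(key)
            if prev is not None and prev.consequent != rule.consequent:
                raise RuleConflictError(
                    f"rules {prev.provenance} and {rule.provenance} share antecedent "
                    f"{key} but conclude {prev.consequent.value} vs {rule.consequent.value}"
                )
            seen.setdefault(key, rule)

    def __iter__(self):
        return iter(self.rules)

    def __len__(self) -> int:
        return len(self.rules)


def _rule(temp, hr, spo2, bp, gl, consequent, provenance) -> FuzzyRule:
    return FuzzyRule(
        antecedent={
            VitalKind.temperature: temp,
            VitalKind.heart_rate: hr,
            VitalKind.oxygen_saturation: spo2,
            VitalKind.blood_pressure: bp,
            VitalKind.glucose: gl,
        },
        consequent=consequent,
        provenance=provenance,
    )


C = ConditionLabel

# The seven expert rules of the decision-support system.
PRINTED_RULES: tuple[FuzzyRule, ...] = (
    _rule("Normal", "Normal", "Critical", "Elevated", "Normal", C.critical, "printed_rule_1"),
    _rule("Low", "Low", "Worrisome", "Normal", "Elevated", C.unhealthy, "printed_rule_2"),
    _rule("Normal", "Low", "Normal", "Low", "Low", C.very_critical, "printed_rule_3"),
    _rule("Low", "Low", "Normal", "Low", "High", C.very_critical, "printed_rule_4"),
    _rule("Low", "Low", "Worrisome", "Low", "Normal", C.very_unhealthy, "printed_rule_5"),
    _rule("High", "Normal", "Worrisome", "Normal", "Normal", C.moderate_unhealthy, "printed_rule_6"),
    _rule("Low", "Normal", "Normal", "Normal", "Normal", C.unhealthy, "printed_rule_7"),
)

# Calibration rows: additional crisp-antecedent rules from the published
# sensor-calibration table (order: temp, HR, SpO2, BP, glucose).
CALIBRATION_RULES: tuple[FuzzyRule, ...] = (
    _rule("Normal", "Normal", "Critical", "Elevated", "Normal", C.critical, "table8_row_1"),
    _rule("Low", "Normal", "Worrisome", "Elevated", "Normal", C.critical, "table8_row_2"),
    _rule("Low", "Low", "Worrisome", "Normal", "Normal", C.unhealthy, "table8_row_3"),
    _rule("Normal", "Low", "Normal", "Low", "High", C.very_critical, "table8_row_4"),
    _rule("Low", "Low", "Critical", "Normal", "Low", C.very_critical, "table8_row_5"),
    _rule("Low", "Low", "Worrisome", "Low", "Normal", C.very_unhealthy, "table8_row_6"),
    _rule("High", "Normal", "Worrisome", "Normal", "Normal", C.moderate_unhealthy, "table8_row_7"),
)


def build_rulebase() -> RuleBase:
    """Union of the seven expert rules and the seven calibration rows.

    Expert rules take precedence on identical antecedents (duplicate
    calibration rows are dropped); any remaining antecedent collision with a
    different consequent raises :class:`RuleConflictError`.
    """
    rules: list[FuzzyRule] = list(PRINTED_RULES)
    keys = {r.antecedent_key(): r for r in rules}
    for rule in CALIBRATION_RULES:
        prev = keys.get(rule.antecedent_key())
        if prev is None:
            rules.append(rule)
            keys[rule.antecedent_key()] = rule
        elif prev.consequent != rule.consequent:
            raise RuleConflictError(
                f"{prev.provenance} and {rule.provenance} conflict on antecedent "
                f"{rule.antecedent_key()}"
            )
    return RuleBase(tuple(rules))


def evaluate_rule(rule: FuzzyRule, fz: FuzzifiedSample) -> float:
    """Firing strength: min over antecedent degrees (ANY contributes 1)."""
    strength = 1.0
    for kind in VITAL_ORDER:
        label = rule.antecedent.get(kind, ANY)
        if label == ANY:
            continue
        strength = min(strength, fz.degree(kind, label))
        if strength == 0.0:
            break
    return strength


@dataclass(frozen=True)
class ConditionActivation:
    """Aggregated firing strength per condition."""

    strengths: Mapping[ConditionLabel, float]

    def max_strength(self) -> float:
        return max(self.strengths.values())


def aggregate(rulebase: RuleBase, fz: FuzzifiedSample) -> ConditionActivation:
    """Per condition, the max firing strength over rules with that consequent."""
    strengths = {label: 0.0 for label in ConditionLabel}
    for rule in rulebase:
        s = evaluate_rule(rule, fz)
        if s > strengths[rule.consequent]:
            strengths[rule.consequent] = s
    return ConditionActivation(strengths)


def fallback_condition(labels: Sequence[str]) -> ConditionLabel:
    """Grade by abnormal-vital count when no explicit rule fires.

    ``labels`` are crisp labels in canonical vital order.  Any label other
    than "Normal" counts as abnormal (both Worrisome and Critical SpO2 are
    abnormal); the count maps 0 -> Healthy, 1 -> Moderate Unhealthy,
    2 -> Unhealthy, 3 -> Very Unhealthy, 4 -> Critical, 5 -> Very Critical.
    """
    n_abnormal = sum(1 for lab in labels if lab != "Normal")
    order = (
        ConditionLabel.healthy,
        ConditionLabel.moderate_unhealthy,
        ConditionLabel.unhealthy,
        ConditionLabel.very_unhealthy,
        ConditionLabel.critical,
        ConditionLabel.very_critical,
    )
    return order[n_abnormal]


def defuzzify(act: ConditionActivation, labels: Sequence[str]) -> CrispCondition:
    """Argmax condition with severity tie-break; fallback when nothing fires."""
    best = act.max_strength()
    if best > 0.0:
        winners = [lab for lab, s in act.strengths.items() if s == best]
        winner = max(winners, key=lambda lab: lab.severity)
        return CrispCondition(winner)
    return CrispCondition(fallback_condition(labels))


@dataclass(frozen=True)
class InferenceResult:
    """Full provenance of one inference: condition, strength, matched rule."""

    condition: CrispCondition
    firing_strength: float
    matched_rule: str  # provenance of the strongest rule, or "fallback"


def infer_condition(
    sample: VitalSample,
    cfg: FuzzySystemConfig | None = None,
    rulebase: RuleBase | None = None,
    table: RangeTable | None = None,
) -> CrispCondition:
    """Fuzzify a sample, run the rule base and defuzzify to a crisp condition."""
    return infer_condition_detailed(sample, cfg, rulebase, table).condition


def infer_condition_detailed(
    sample: VitalSample,
    cfg: FuzzySystemConfig | None = None,
    rulebase: RuleBase | None = None,
    table: RangeTable | None = None,
) -> InferenceResult:
    from .membership import fuzzify_sample

    if cfg is None:
        cfg = builtin_paramset()
    if rulebase is None:
        rulebase = build_rulebase()
    if table is None:
        table = default_range_table()
    fz = fuzzify_sample(sample, cfg)
    act = aggregate(rulebase, fz)
    labels = classify_sample(sample, table)
    crisp = defuzzify(act, labels)
    best = act.max_strength()
    if best > 0.0:
        matched = next(
            r.provenance
            for r in rulebase
            if r.consequent == crisp.label and evaluate_rule(r, fz) == best
        )
        return InferenceResult(crisp, best, matched)
    return InferenceResult(crisp, 0.0, "fallback")
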