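"""Mamdani severity engine: grading, rules, aggregation, banding, fusion."""

import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pneumofuzz.confidence import ConfigError, ProbabilityVector, ValidationError, calibrate
from pneumofuzz.fuzzy import (
    SEVERITY_CLASSES,
    FuzzyRule,
    MembershipFunctionSet,
    RuleBase,
    activate,
    aggregate,
    assess,
    band,
    crisp_category,
    defuzzify,
    fuse,
    grade,
)
from pneumofuzz.synth import CaseSpec, gen_case

ALL_SYMPTOMS = ("breathlessness", "sputum_production", "hemoptysis", "fatigue",
                "appetite_loss", "chest_pain", "cough_severity", "confusion",
                "fever_value", "oxygen_level", "fever_duration")


class TestGrading:
    def test_crisp_categories(self):
        assert crisp_category(0.2) == "Poor"
        assert crisp_category(0.3) == "Average"
        assert crisp_category(0.7) == "Average"
        assert crisp_category(0.71) == "Good"

    def test_crossover_grades_are_half(self):
        g03 = grade(0.3)
        assert g03["Poor"] == pytest.approx(0.5)
        assert g03["Average"] == pytest.approx(0.5)
        g07 = grade(0.7)
        assert g07["Average"] == pytest.approx(0.5)
        assert g07["Good"] == pytest.approx(0.5)

    def test_plateau_midpoint(self):
        g = grade(0.5)
        assert (g["Poor"], g["Average"], g["Good"]) == (0.0, 1.0, 0.0)

    def test_out_of_range_clipped(self, caplog):
        with caplog.at_level("WARNING"):
            g = grade(1.4)
        assert g["Good"] == 1.0

    @given(st.floats(0, 1))
    def test_shape_constraints(self, x):
        mfs = MembershipFunctionSet()
        g = mfs.grades(x)
        assert all(0.0 <= v <= 1.0 for v in g.values())
        # Poor nonincreasing / Good nondecreasing
        g2 = mfs.grades(min(1.0, x + 0.05))
        assert g2["Poor"] <= g["Poor"] + 1e-12
        assert g2["Good"] >= g["Good"] - 1e-12


def _rule(logic, antecedents, consequent="Severe", weight=None, name="r"):
    return FuzzyRule(name=name, logic=logic, antecedents=tuple(antecedents),
                     consequent=consequent, weight=weight)


class TestActivation:
    def test_and_is_min_or_is_max(self):
        grades = {"a": {"Good": 0.6}, "b": {"Good": 0.9}}
        r_and = _rule("AND", [("a", "Good"), ("b", "Good")])
        r_or = _rule("OR", [("a", "Good"), ("b", "Good")])
        assert activate(r_and, grades) == pytest.approx(0.6)
        assert activate(r_or, grades) == pytest.approx(0.9)

    def test_and_annihilator_and_unit(self):
        grades = {"a": {"Good": 1.0}, "b": {"Good": 1.0}, "c": {"Good": 0.0}}
        assert activate(_rule("AND", [("a", "Good"), ("b", "Good")]), grades) == 1.0
        assert activate(_rule("AND", [("a", "Good"), ("c", "Good")]), grades) == 0.0

    def test_unknown_symptom_rejected(self):
        with pytest.raises(ValidationError):
            activate(_rule("AND", [("missing", "Good")]), {"a": {"Good": 1.0}})

    def test_rule_schema_validation(self):
        with pytest.raises(ConfigError):
            _rule("NAND", [("a", "Good")])
        with pytest.raises(ConfigError):
            _rule("AND", [])
        with pytest.raises(ConfigError):
            _rule("AND", [("a", "Great")])


class TestAggregation:
    def test_default_rule_weights(self):
        rb_and = RuleBase([_rule("AND", [("a", "Good")])])
        assert aggregate(rb_and, [1.0])[1] == pytest.approx(10.0)
        rb_or = RuleBase([_rule("OR", [("a", "Good")])])
        assert aggregate(rb_or, [1.0])[1] == pytest.approx(5.0)

    def test_weighted_sum_example(self):
        rb = RuleBase([_rule("AND", [("a", "Good")]), _rule("OR", [("b", "Good")])])
        _, total = aggregate(rb, [0.6, 0.8])
        assert total == pytest.approx(10 * 0.6 + 5 * 0.8)

    def test_no_active_rules(self):
        rb = RuleBase([_rule("AND", [("a", "Good")])])
        raw, total = aggregate(rb, [0.0])
        assert total == 0.0 and all(v == 0.0 for v in raw.values())

    def test_empty_rulebase_warns(self, caplog):
        with caplog.at_level("WARNING"):
            raw, total = aggregate(RuleBase([]), [])
        assert total == 0.0 and "empty" in caplog.text

    def test_max_mode(self):
        rb = RuleBase([_rule("AND", [("a", "Good")]), _rule("OR", [("b", "Good")])])
        _, total = aggregate(rb, [0.5, 1.0], mode="max")
        assert total == pytest.approx(5.0)

    def test_matches_bruteforce_evaluator_on_grid(self):
        # exhaustive oracle over a 0.1 grid for a compact rule base
        rb = RuleBase([
            _rule("AND", [("a", "Good"), ("b", "Average")], "Severe"),
            _rule("OR", [("a", "Average"), ("b", "Good")], "Moderate"),
            _rule("AND", [("b", "Poor")], "Mild", weight=7),
            _rule("OR", [("a", "Poor"), ("b", "Poor")], "Negligible"),
        ])
        mfs = MembershipFunctionSet()
        for ta in np.arange(0, 1.01, 0.1):
            for tb in np.arange(0, 1.01, 0.1):
                grades = {"a": mfs.grades(ta), "b": mfs.grades(tb)}
                acts = [activate(r, grades) for r in rb]
                raw, total = aggregate(rb, acts)
                # oracle: direct arithmetic, one term per rule
                ga, gb = grades["a"], grades["b"]
                expected = {
                    "Severe": 10 * min(ga["Good"], gb["Average"]),
                    "Moderate": 5 * max(ga["Average"], gb["Good"]),
                    "Mild": 7 * gb["Poor"],
                    "Negligible": 5 * max(ga["Poor"], gb["Poor"]),
                }
                for cls in SEVERITY_CLASSES:
                    assert raw[cls] == pytest.approx(expected[cls], abs=1e-12)
                assert total == pytest.approx(sum(expected.values()), abs=1e-12)


class TestDefuzzify:
    def test_ratio_and_bounds(self):
        assert defuzzify(10.0, 40.0) == pytest.approx(0.25)
        assert defuzzify(0.0, 40.0) == 0.0
        assert defuzzify(40.0, 40.0) == 1.0

    def test_zero_weight_rejected(self):
        with pytest.raises(ConfigError):
            defuzzify(1.0, 0.0)


class TestBanding:
    @pytest.mark.parametrize("score,expected", [
        (0, "Negligible"), (9.99, "Negligible"), (10, "Mild"), (24.99, "Mild"),
        (25, "Moderate"), (39.99, "Moderate"), (40, "Severe"), (120, "Severe"),
    ])
    def test_table_boundaries(self, score, expected):
        assert band(score) == expected

    def test_negative_score_rejected(self):
        with pytest.raises(ValidationError):
            band(-1.0)


class TestFusion:
    def test_zero_confidence_is_identity(self):
        raw = {"Negligible": 0.0, "Mild": 12.0, "Moderate": 3.0, "Severe": 0.0}
        a = fuse(raw, 0.2, None)
        assert a.confidence == 0.0
        assert a.adjusted_scores == raw
        assert a.label == "Mild"
        assert a.s_final == pytest.approx(0.2)

    def test_confidence_breaks_a_tie(self):
        raw = {"Negligible": 0.0, "Mild": 0.0, "Moderate": 20.0, "Severe": 20.0}
        b = calibrate(ProbabilityVector((0.0, 0.0, 1.0)))  # Pneumonia -> Severe
        scaled = type(b)(**{**b.__dict__, "confidence": 3.0})
        a = fuse(raw, 0.5, scaled)
        assert a.label == "Severe"
        assert a.margin == pytest.approx(3.0)
        assert not a.borderline

    def test_tie_breaks_toward_more_severe(self):
        raw = {"Negligible": 0.0, "Mild": 8.0, "Moderate": 8.0, "Severe": 0.0}
        assert fuse(raw, 0.1, None).label == "Moderate"

    def test_all_zero_scores_label_negligible(self):
        raw = {c: 0.0 for c in SEVERITY_CLASSES}
        a = fuse(raw, 0.0, None)
        assert a.label == "Negligible"
        assert not a.borderline

    def test_literal_mode_adds_to_scalar(self):
        raw = {"Negligible": 0.0, "Mild": 5.0, "Moderate": 0.0, "Severe": 0.0}
        b = calibrate(ProbabilityVector((0.0, 0.0, 1.0)))
        a = fuse(raw, 0.4, b, mode="literal")
        assert a.s_final == pytest.approx(0.4 + b.confidence)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigError):
            fuse({c: 0.0 for c in SEVERITY_CLASSES}, 0.0, None, mode="average")

    @pytest.mark.parametrize("margin", np.arange(0.0, 5.01, 0.5).tolist())
    def test_borderline_flag_threshold(self, margin):
        raw = {"Negligible": 0.0, "Mild": 20.0 - margin, "Moderate": 20.0, "Severe": 0.0}
        a = fuse(raw, 0.5, None)
        assert a.margin == pytest.approx(margin)
        assert a.borderline == (margin <= 2.0)


class TestAssess:
    def _minimum_record(self, ranges):
        # clinical minimum severity: oxygen sits at its benign (high) end
        rec = {s: spec.delta_min for s, spec in ranges.items()}
        rec["oxygen_level"] = 100.0
        return rec

    def test_all_minimum_no_dl_scores_zero(self, ranges):
        a = assess(self._minimum_record(ranges), None)
        assert a.mu_severity == 0.0
        assert a.band == "Negligible"
        assert a.label == "Negligible"

    def test_all_maximum_severity_bands_severe(self, ranges):
        rec = {s: spec.delta_max for s, spec in ranges.items()}
        rec["oxygen_level"] = 80.0
        a = assess(rec, None)
        assert a.band == "Severe"
        assert a.label == "Severe"
        assert a.s_fuzzy <= 1.0

    def test_missing_symptom_named_in_error(self, ranges):
        rec = self._minimum_record(ranges)
        del rec["fever_value"]
        with pytest.raises(ValidationError, match="fever_value"):
            assess(rec, None)

    def test_synthetic_extremes_band_as_generated(self):
        rec, p = gen_case(CaseSpec("Negligible", seed=4))
        assert assess(rec, None).band == "Negligible"
        rec, p = gen_case(CaseSpec("Severe", seed=4))
        assert assess(rec, p).band == "Severe"

    def test_dl_input_can_flip_a_tied_label(self, ranges, rulebase):
        # same record with and without a Pneumonia-leaning classifier:
        # labels may differ only through the confidence pathway
        rec, p = gen_case(CaseSpec("Moderate", seed=11))
        a_with = assess(rec, p, rulebase=rulebase)
        a_without = assess(rec, None, rulebase=rulebase)
        diff = {c: a_with.adjusted_scores[c] - a_without.adjusted_scores[c]
                for c in SEVERITY_CLASSES}
        nonzero = [c for c, v in diff.items() if abs(v) > 1e-12]
        assert len(nonzero) <= 1   # confidence lands on exactly one class

    def test_s_fuzzy_always_in_unit_interval(self, ranges, rulebase):
        rng = np.random.default_rng(0)
        for _ in range(25):
            rec = {}
            for s, spec in ranges.items():
                rec[s] = float(rng.uniform(spec.delta_min, spec.delta_max))
            a = assess(rec, None, rulebase=rulebase)
            assert 0.0 <= a.s_fuzzy <= 1.0
            assert all(v >= 0 for v in a.raw_scores.values())

    def test_monotone_in_any_single_symptom(self, ranges, rulebase):
        # raising any symptom on the severity-aligned axis never lowers the
        # total severity membership under the default rule base
        rng = np.random.default_rng(1)
        from pneumofuzz.fuzzy import MembershipFunctionSet, activate, aggregate, grade
        mfs = MembershipFunctionSet()

        def total(theta):
            g = {s: grade(t, mfs) for s, t in theta.items()}
            return aggregate(rulebase, [activate(r, g) for r in rulebase])[1]

        for trial in range(200):
            theta = {s: rng.random() for s in ALL_SYMPTOMS}
            sym = ALL_SYMPTOMS[trial % len(ALL_SYMPTOMS)]
            before = total(theta)
            theta[sym] = min(1.0, theta[sym] + rng.uniform(0.0, 0.4))
            assert total(theta) >= before - 1e-9


class TestRuleBaseIO:
    def test_default_rulebase_contains_printed_examples(self, rulebase):
        by_name = {r.name: r for r in rulebase}
        triad = by_name["severe-triad"]
        assert triad.logic == "AND" and triad.consequent == "Severe"
        assert set(triad.antecedents) == {
            ("breathlessness", "Good"), ("fever_value", "Average"),
            ("sputum_production", "Poor")}
        pair = by_name["moderate-appetite-or-fever"]
        assert pair.logic == "OR" and pair.consequent == "Moderate"

    def test_json_roundtrip(self, tmp_path, rulebase):
        payload = [
            {"name": r.name, "logic": r.logic,
             "antecedents": [{"symptom": s, "category": c} for s, c in r.antecedents],
             "consequent": r.consequent,
             **({"weight": r.weight} if r.weight is not None else {})}
            for r in rulebase
        ]
        path = tmp_path / "rules.json"
        path.write_text(json.dumps(payload))
        again = RuleBase.from_file(path)
        assert len(again) == len(rulebase)
        assert again.total_weight == rulebase.total_weight
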