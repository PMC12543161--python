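"""Mamdani-style fuzzy inference for pneumonia severity.

Pipeline for one patient visit: normalize the 11 clinical inputs onto the
severity-aligned unit axis, grade each against piecewise-linear Poor /
Average / Good membership functions, activate the expert rule base
(AND = min, OR = max), aggregate rule activations into per-severity-class
raw scores and a total weighted-sum membership, defuzzify by weighted
average, fuse with the calibrated DL confidence, and band the result.

Severity classes, ordered: Negligible < Mild < Moderate < Severe, with the
rule-based score bands

=========  ==================
Negligible score < 10
Mild       10 <= score < 25
Moderate   25 <= score < 40
Severe     score >= 40
=========  ==================

Design notes
------------
* The logical connectives are the standard Mamdani t-norms: AND -> min,
  OR -> max.  Rule weights default to +10 for AND rules and +5 for OR
  rules and may be overridden per rule.
* Aggregation is a weighted SUM of activations by default (the only reading
  consistent with the 0-40+ band scale); a max-of-activations mode is
  available as an option.
* Confidence fusion has two modes.  ``argmax`` (default) keeps per-class raw
  scores and adds the confidence contribution to the severity class mapped
  from the predicted image class (Normal->Negligible, Abnormal->Moderate,
  Pneumonia->Severe); the label is the argmax, ties broken toward the more
  severe class, and an all-zero score vector labels Negligible.  ``literal``
  adds the confidence directly to the defuzzified scalar score.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .confidence import (
    CalibrationBreakdown,
    ConfigError,
    NormalizationSpec,
    ProbabilityVector,
    ValidationError,
    calibrate,
    load_symptom_ranges,
    severity_axis,
)

log = logging.getLogger(__name__)

SEVERITY_CLASSES = ("Negligible", "Mild", "Moderate", "Severe")
CATEGORIES = ("Poor", "Average", "Good")

#: image class -> severity class receiving the DL confidence contribution
DEFAULT_AFFINITY = {"Normal": "Negligible", "Abnormal": "Moderate", "Pneumonia": "Severe"}

AND_WEIGHT = 10.0
OR_WEIGHT = 5.0
BORDERLINE_MARGIN = 2.0


# --------------------------------------------------------------------------
# membership functions
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MembershipFunctionSet:
    """Piecewise-linear Poor/Average/Good membership functions on [0, 1].

    The default breakpoints place the Poor/Average crossover at 0.3 and the
    Average/Good crossover at 0.7, both with grade 0.5, matching the crisp
    category table (Poor x < 0.3; Average 0.3 <= x <= 0.7; Good x > 0.7).
    """

    poor: tuple[tuple[float, float], ...] = ((0.0, 1.0), (0.2, 1.0), (0.4, 0.0), (1.0, 0.0))
    average: tuple[tuple[float, float], ...] = (
        (0.0, 0.0), (0.2, 0.0), (0.4, 1.0), (0.6, 1.0), (0.8, 0.0), (1.0, 0.0))
    good: tuple[tuple[float, float], ...] = ((0.0, 0.0), (0.6, 0.0), (0.8, 1.0), (1.0, 1.0))

    def _eval(self, pts: tuple[tuple[float, float], ...], x: float) -> float:
        xs, ys = zip(*pts)
        return float(np.interp(x, xs, ys))

    def grades(self, x: float) -> dict[str, float]:
        return {
            "Poor": self._eval(self.poor, x),
            "Average": self._eval(self.average, x),
            "Good": self._eval(self.good, x),
        }


def crisp_category(x: float) -> str:
    """Crisp Poor/Average/Good category of a normalized value."""
    if x < 0.3:
        return "Poor"
    if x <= 0.7:
        return "Average"
    return "Good"


def grade(theta: float, mfs: MembershipFunctionSet | None = None) -> dict:
    """Fuzzy-grade a normalized value; returns grades plus the crisp label.

    Values outside [0, 1] are clipped with a warning.
    """
    if mfs is None:
        mfs = MembershipFunctionSet()
    if theta < 0.0 or theta > 1.0:
        log.warning("normalized value %.4g outside [0,1]; clipping", theta)
        theta = min(max(theta, 0.0), 1.0)
    out = mfs.grades(theta)
    out["crisp"] = crisp_category(theta)
    return out


# --------------------------------------------------------------------------
# rules
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FuzzyRule:
    name: str
    logic: str                                   # "AND" | "OR"
    antecedents: tuple[tuple[str, str], ...]     # (symptom, category)
    consequent: str                              # severity class
    weight: float | None = None                  # None -> default by logic

    def __post_init__(self) -> None:
        if self.logic not in ("AND", "OR"):
            raise ConfigError(f"rule {self.name!r}: logic must be AND or OR")
        if not self.antecedents:
            raise ConfigError(f"rule {self.name!r}: needs at least one antecedent")
        if self.consequent not in SEVERITY_CLASSES:
            raise ConfigError(f"rule {self.name!r}: unknown consequent {self.consequent!r}")
        for _, cat in self.antecedents:
            if cat not in CATEGORIES:
                raise ConfigError(f"rule {self.name!r}: unknown category {cat!r}")

    @property
    def effective_weight(self) -> float:
        if self.weight is not None:
            return float(self.weight)
        return AND_WEIGHT if self.logic == "AND" else OR_WEIGHT


class RuleBase:
    """An ordered collection of fuzzy rules loaded from a JSON schema.

    Schema per rule: ``{name, logic: "AND"|"OR", antecedents:
    [{symptom, category}], consequent, weight?}``.
    """

    def __init__(self, rules: Sequence[FuzzyRule]):
        self.rules = tuple(rules)

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    @property
    def total_weight(self) -> float:
        return sum(r.effective_weight for r in self.rules)

    @classmethod
    def from_json(cls, text: str) -> "RuleBase":
        raw = json.loads(text)
        rules = [
            FuzzyRule(
                name=r.get("name", f"rule-{i}"),
                logic=r["logic"],
                antecedents=tuple((a["symptom"], a["category"]) for a in r["antecedents"]),
                consequent=r["consequent"],
                weight=r.get("weight"),
            )
            for i, r in enumerate(raw)
        ]
        return cls(rules)

    @classmethod
    def from_file(cls, path) -> "RuleBase":
        with open(path) as fh:
            return cls.from_json(fh.read())

    @classmethod
    def default(cls) -> "RuleBase":
        """The shipped illustrative rule base (editable config, not a claim
        of clinical fidelity)."""
        text = resources.files("pneumofuzz.data").joinpath("default_rules.json").read_text()
        return cls.from_json(text)


def activate(rule: FuzzyRule, grades_by_symptom: Mapping[str, Mapping[str, float]]) -> float:
    """Activation mu_k of one rule given per-symptom membership grades.

    AND takes the min of antecedent grades, OR the max.
    """
    vals = []
    for symptom, category in rule.antecedents:
        if symptom not in grades_by_symptom:
            raise ValidationError(
                f"rule {rule.name!r} references unknown symptom {symptom!r}")
        vals.append(grades_by_symptom[symptom][category])
    return float(min(vals) if rule.logic == "AND" else max(vals))


def aggregate(
    rulebase: RuleBase,
    activations: Sequence[float],
    mode: str = "sum",
) -> tuple[dict[str, float], float]:
    """Aggregate rule activations into per-class scores and a total.

    mu_Severity = sum_k w_k * mu_k (default); per-class raw score R_c sums
    over the rules with consequent c.  ``mode="max"`` instead takes the max
    weighted activation (per class and overall).
    """
    if mode not in ("sum", "max"):
        raise ConfigError(f"unknown aggregation mode {mode!r}")
    if len(rulebase) == 0:
        log.warning("empty rule base: all severity scores are zero")
        return {c: 0.0 for c in SEVERITY_CLASSES}, 0.0
    if len(activations) != len(rulebase):
        raise ValidationError("one activation per rule required")

    raw = {c: 0.0 for c in SEVERITY_CLASSES}
    weighted = [r.effective_weight * mu for r, mu in zip(rulebase, activations)]
    if mode == "sum":
        for r, wmu in zip(rulebase, weighted):
            raw[r.consequent] += wmu
        total = float(sum(weighted))
    else:
        for r, wmu in zip(rulebase, weighted):
            raw[r.consequent] = max(raw[r.consequent], wmu)
        total = float(max(weighted))
    return raw, total


def defuzzify(mu_severity: float, total_weight: float) -> float:
    """Weighted-average defuzzification: S_fuzzy = mu_Severity / sum_k w_k."""
    if total_weight <= 0:
        raise ConfigError("total rule weight must be positive for defuzzification")
    return mu_severity / total_weight


def band(score: float) -> str:
    """Severity band of a rule-based score (monotone step function)."""
    if score < 0:
        raise ValidationError(f"severity score must be >= 0, got {score}")
    if score < 10:
        return "Negligible"
    if score < 25:
        return "Mild"
    if score < 40:
        return "Moderate"
    return "Severe"


# --------------------------------------------------------------------------
# fusion and the full assessment
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SeverityAssessment:
    """Full, explainable outcome of one severity inference."""

    raw_scores: dict[str, float]          # R_c per severity class
    mu_severity: float                    # weighted-sum aggregate
    s_fuzzy: float                        # defuzzified score in [0, 1]
    confidence: float                     # DL contribution used (0 if absent)
    adjusted_scores: dict[str, float]     # A_c after confidence fusion
    s_final: float                        # literal fusion: S_fuzzy + Confidence
    label: str                            # winning severity class
    bands: dict[str, str]                 # bands of mu_severity / top R_c / S_final
    margin: float                         # top-1 minus top-2 adjusted score
    borderline: bool                      # margin <= 2.0 with actual competition
    breakdown: CalibrationBreakdown | None = None
    grades: dict | None = None

    @property
    def band(self) -> str:
        """Headline band: the Table-scale weighted-sum aggregate."""
        return self.bands["mu_severity"]

    def as_dict(self) -> dict:
        d = {
            "raw_scores": self.raw_scores,
            "mu_severity": self.mu_severity,
            "s_fuzzy": self.s_fuzzy,
            "confidence": self.confidence,
            "adjusted_scores": self.adjusted_scores,
            "s_final": self.s_final,
            "label": self.label,
            "bands": self.bands,
            "margin": self.margin,
            "borderline": self.borderline,
        }
        if self.breakdown is not None:
            d["calibration"] = self.breakdown.as_dict()
        if self.grades is not None:
            d["grades"] = self.grades
        return d


def _label_from_scores(scores: Mapping[str, float]) -> str:
    """Argmax label with ties broken toward the more severe class.

    An all-zero vector means no rule fired and no confidence arrived: that
    is the absence of findings, labelled Negligible.
    """
    if all(v == 0.0 for v in scores.values()):
        return "Negligible"
    best = max(scores.values())
    for c in reversed(SEVERITY_CLASSES):
        if scores[c] == best:
            return c
    raise AssertionError("unreachable")


def fuse(
    raw_scores: Mapping[str, float],
    s_fuzzy: float,
    breakdown: CalibrationBreakdown | None,
    mode: str = "argmax",
    affinity: Mapping[str, str] = DEFAULT_AFFINITY,
    borderline_margin: float = BORDERLINE_MARGIN,
    grades: dict | None = None,
) -> SeverityAssessment:
    """Fuse the fuzzy scores with the calibrated DL confidence.

    With no DL input the confidence contribution is zero and the assessment
    is identical to a fuzzy-only run.  A case is flagged borderline when the
    top-two adjusted scores differ by at most ``borderline_margin`` *and*
    both of those scores are positive: "nearly identical top-two severity
    scores" means a genuine contest between two activated severity levels,
    not an inactive score vector (plainly negligible) or a single weak
    activation standing alone.
    """
    if mode not in ("argmax", "literal"):
        raise ConfigError(f"unknown fusion mode {mode!r}")

    conf = 0.0 if breakdown is None else breakdown.confidence
    adjusted = {c: float(raw_scores[c]) for c in SEVERITY_CLASSES}
    if breakdown is not None and mode == "argmax":
        target = affinity[breakdown.predicted_label]
        adjusted[target] += conf

    s_final = s_fuzzy + conf
    mu_severity = float(sum(raw_scores.values()))

    if mode == "literal":
        label = band(s_final)
        ranked = sorted(adjusted.values(), reverse=True)
    else:
        label = _label_from_scores(adjusted)
        ranked = sorted(adjusted.values(), reverse=True)
    margin = float(ranked[0] - ranked[1])
    borderline = bool(ranked[1] > 0.0 and margin <= borderline_margin)

    top_raw = max(raw_scores.values())
    bands = {
        "mu_severity": band(mu_severity),
        "top_rule_score": band(top_raw),
        "s_final": band(s_final),
    }
    return SeverityAssessment(
        raw_scores=dict(raw_scores), mu_severity=mu_severity, s_fuzzy=s_fuzzy,
        confidence=conf, adjusted_scores=adjusted, s_final=s_final,
        label=label, bands=bands, margin=margin, borderline=borderline,
        breakdown=breakdown, grades=grades,
    )


def assess(
    record: Mapping[str, float],
    p: ProbabilityVector | None = None,
    rulebase: RuleBase | None = None,
    ranges: Mapping[str, NormalizationSpec] | None = None,
    mfs: MembershipFunctionSet | None = None,
    mode: str = "argmax",
    affinity: Mapping[str, str] = DEFAULT_AFFINITY,
) -> SeverityAssessment:
    """Run the full severity pipeline on one symptom record.

    ``record`` maps each of the 11 symptom names to its raw clinical value.
    ``p`` is the optional image-classifier probability vector; without it
    the run is the non-DL-assisted pathway.
    """
    if rulebase is None:
        rulebase = RuleBase.default()
    if ranges is None:
        ranges = load_symptom_ranges()
    if mfs is None:
        mfs = MembershipFunctionSet()

    missing = [s for s in ranges if s not in record]
    if missing:
        raise ValidationError(f"missing symptom value(s): {', '.join(sorted(missing))}")

    grades_by_symptom = {}
    for symptom, spec in ranges.items():
        theta = severity_axis(record[symptom], spec)
        grades_by_symptom[symptom] = grade(theta, mfs)

    activations = [activate(r, grades_by_symptom) for r in rulebase]
    raw, mu_total = aggregate(rulebase, activations)
    s_fuzzy = defuzzify(mu_total, rulebase.total_weight)
    breakdown = calibrate(p) if p is not None else None
    return fuse(raw, s_fuzzy, breakdown, mode=mode, affinity=affinity,
                grades=grades_by_symptom)
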