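"""Calibrated DL confidence scoring and clinical input normalization.

Raw softmax outputs of an image classifier are notoriously overconfident.
Before a class probability vector is allowed to influence the fuzzy severity
engine, it is converted into a calibrated confidence score that combines

* the top-1 probability (prediction dominance),
* the margin between the two most likely classes (opposing-class strength),
* the normalized Shannon entropy of the vector (uncertainty), and
* a fixed per-class clinical relevance weight (clinically weighted softmax
  scaling, CWSS).

The same module holds the min-max normalization that maps raw clinical
measurements (fever in degC, SpO2 in %, ...) onto the unit interval the
fuzzy membership functions operate on.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

log = logging.getLogger(__name__)

#: canonical image-class order used throughout the package
CLASS_LABELS = ("Normal", "Abnormal", "Pneumonia")

#: clinical relevance scores, one per class, in CLASS_LABELS order.
#: Monotone in clinical urgency: a pneumonia prediction carries more weight
#: than a normal one.
DEFAULT_RELEVANCE = (0.25, 0.50, 0.75)

PROB_ATOL = 1e-9


class ValidationError(ValueError):
    """Raised when an input fails a contract check."""


class ConfigError(ValueError):
    """Raised when a configuration value is inconsistent."""


# --------------------------------------------------------------------------
# clinical input normalization
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalizationSpec:
    """Clinical bounds for one symptom/condition.

    ``severity_inverted`` marks measurements whose *low* end is the severe
    direction (oxygen saturation): the severity-aligned value used for fuzzy
    grading is then ``1 - theta``.
    """

    delta_min: float
    delta_max: float
    unit: str = ""
    severity_inverted: bool = False

    def __post_init__(self) -> None:
        if not self.delta_min < self.delta_max:
            raise ConfigError(
                f"delta_min ({self.delta_min}) must be < delta_max ({self.delta_max})"
            )


def load_symptom_ranges() -> dict[str, NormalizationSpec]:
    """Load the default clinical ranges for the 11 symptoms/conditions.

    Eight symptoms live on a 0-1 severity scale; fever value (35-42 degC),
    oxygen level (80-100 %) and fever duration (0-30 days) carry physical
    units.
    """
    text = resources.files("pneumofuzz.data").joinpath("symptom_ranges.json").read_text()
    raw = json.loads(text)
    return {
        name: NormalizationSpec(
            delta_min=spec["min"],
            delta_max=spec["max"],
            unit=spec.get("unit", ""),
            severity_inverted=spec.get("severity_inverted", False),
        )
        for name, spec in raw.items()
    }


SYMPTOM_NAMES = tuple(json.loads(
    resources.files("pneumofuzz.data").joinpath("symptom_ranges.json").read_text()
).keys())


def normalize_symptom(value: float, spec: NormalizationSpec) -> float:
    """Min-max normalize a raw clinical value onto [0, 1].

    theta = (delta - delta_min) / (delta_max - delta_min).  Values outside
    the clinical bounds are clipped with a logged warning rather than
    rejected: follow-up symptom streams may briefly exceed them.
    """
    if value < spec.delta_min or value > spec.delta_max:
        log.warning(
            "value %.4g outside clinical bounds [%.4g, %.4g]; clipping",
            value, spec.delta_min, spec.delta_max,
        )
        value = min(max(value, spec.delta_min), spec.delta_max)
    return (value - spec.delta_min) / (spec.delta_max - spec.delta_min)


def severity_axis(value: float, spec: NormalizationSpec) -> float:
    """Normalized value mapped onto the severity-aligned axis.

    Identical to :func:`normalize_symptom` except for severity-inverted
    measurements (oxygen level), where the severe direction is low raw
    values: there the result is ``1 - theta``.
    """
    theta = normalize_symptom(value, spec)
    return 1.0 - theta if spec.severity_inverted else theta


# --------------------------------------------------------------------------
# calibrated confidence (CWSS)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbabilityVector:
    """A softmax output over the three image classes."""

    probs: tuple[float, ...]
    class_labels: tuple[str, ...] = CLASS_LABELS

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if len(self.probs) != len(self.class_labels):
            raise ValidationError("probs and class_labels length mismatch")
        if np.any(p < -PROB_ATOL) or np.any(p > 1 + PROB_ATOL):
            raise ValidationError(f"probabilities outside [0,1]: {self.probs}")
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValidationError(f"probabilities sum to {p.sum():.9f}, not 1")

    @property
    def predicted_index(self) -> int:
        return int(np.argmax(self.probs))

    @property
    def predicted_label(self) -> str:
        return self.class_labels[self.predicted_index]


@dataclass(frozen=True)
class CalibrationBreakdown:
    """Every intermediate of the calibration, retained for explainability."""

    p_top1: float
    p_top2: float
    margin: float               # M = p_top1 - p_top2
    entropy: float              # H, nats
    entropy_norm: float         # H / ln(k)
    calibrated: float           # C = p_top1 * M * exp(-H_norm)
    relevance: tuple[float, ...]
    predicted_index: int
    predicted_label: str
    weight: float               # lambda = softmax(relevance)[predicted]
    confidence: float           # 100 * lambda * C

    def as_dict(self) -> dict:
        return {
            "p_top1": self.p_top1, "p_top2": self.p_top2,
            "margin": self.margin, "entropy": self.entropy,
            "entropy_norm": self.entropy_norm, "calibrated": self.calibrated,
            "predicted_label": self.predicted_label, "weight": self.weight,
            "confidence": self.confidence,
        }


def calibrate(
    p: ProbabilityVector,
    relevance: tuple[float, ...] = DEFAULT_RELEVANCE,
    eps: float = 1e-12,
) -> CalibrationBreakdown:
    """Compute the calibrated confidence score of a probability vector.

    The chain is: margin ``M = p_top1 - p_top2``; Shannon entropy
    ``H = -sum p_i ln(p_i + eps)`` (natural log; the base cancels in the
    normalization); ``H_norm = H / ln(k)``; calibrated score
    ``C = p_top1 * M * exp(-H_norm)``; per-class weight
    ``lambda = softmax(relevance)[argmax]``; and finally
    ``Confidence = 100 * lambda * C`` on a 0-100*lambda scale.
    """
    probs = np.asarray(p.probs, dtype=float)
    k = probs.size
    if len(relevance) != k:
        raise ConfigError("relevance vector length must match class count")

    order = np.sort(probs)[::-1]
    p_top1, p_top2 = float(order[0]), float(order[1])
    margin = p_top1 - p_top2
    entropy = float(-np.sum(probs * np.log(probs + eps)))
    entropy = max(entropy, 0.0)  # eps can push a one-hot vector fractionally below 0
    entropy_norm = entropy / math.log(k)
    calibrated = p_top1 * margin * math.exp(-entropy_norm)

    a = p.predicted_index
    r = np.asarray(relevance, dtype=float)
    weight = float(np.exp(r[a]) / np.exp(r).sum())
    conf = 100.0 * weight * calibrated

    return CalibrationBreakdown(
        p_top1=p_top1, p_top2=p_top2, margin=margin,
        entropy=entropy, entropy_norm=entropy_norm, calibrated=calibrated,
        relevance=tuple(relevance), predicted_index=a,
        predicted_label=p.class_labels[a], weight=weight, confidence=conf,
    )
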