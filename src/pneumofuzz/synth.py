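"""Seeded synthetic-data generators: softmax vectors, symptom cases,
drifting symptom streams, and phantom radiograph-like images.

These stand in for clinical data so every pipeline stage is testable
offline.  All generators are deterministic under a fixed seed and respect
the clinical bounds of the symptom-range config.  The class-conditional
sampling intervals are declared defaults, not a claim of clinical fidelity:

=========== =================== =============== ============ =============
category    unit symptoms       fever (degC)    SpO2 (%)     duration (d)
=========== =================== =============== ============ =============
Negligible  U(0.00, 0.20)       U(36.0, 37.2)   U(95, 100)   U(0.0, 2.0)
Mild        interpolated 1/3 of the way from Negligible to Severe
Moderate    interpolated 2/3 of the way
Severe      U(0.75, 1.00)       U(39.0, 41.5)   U(80, 88)    U(7.0, 21.0)
=========== =================== =============== ============ =============

The DL-class bias couples category to the image classifier: Negligible
cases look radiographically Normal (bias strength 0.9), Severe cases look
like Pneumonia (0.9), and the Mild/Moderate middle is ambiguous Abnormal
(0.65).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .confidence import CLASS_LABELS, NormalizationSpec, ProbabilityVector, load_symptom_ranges
from .dynamics import SymptomHistory
from .imaging import GrayImage

SEVERITY_CLASSES = ("Negligible", "Mild", "Moderate", "Severe")

_UNIT_SYMPTOMS = ("breathlessness", "sputum_production", "hemoptysis", "fatigue",
                  "appetite_loss", "chest_pain", "cough_severity", "confusion")

#: endpoints of the class-conditional sampling intervals (Negligible, Severe);
#: Mild and Moderate interpolate linearly at t = 1/3 and 2/3
_ANCHORS = {
    "unit": ((0.0, 0.2), (0.75, 1.0)),
    "fever_value": ((36.0, 37.2), (39.0, 41.5)),
    "oxygen_level": ((95.0, 100.0), (80.0, 88.0)),
    "fever_duration": ((0.0, 2.0), (7.0, 21.0)),
}

_DL_BIAS = {
    "Negligible": ("Normal", 0.9),
    "Mild": ("Abnormal", 0.65),
    "Moderate": ("Abnormal", 0.65),
    "Severe": ("Pneumonia", 0.9),
}


def _interval(kind: str, severity: str) -> tuple[float, float]:
    (lo0, hi0), (lo1, hi1) = _ANCHORS[kind]
    t = SEVERITY_CLASSES.index(severity) / 3.0
    return lo0 + t * (lo1 - lo0), hi0 + t * (hi1 - hi0)


def class_intervals(severity: str) -> dict[str, tuple[float, float]]:
    """Per-symptom sampling interval for one severity category."""
    out = {s: _interval("unit", severity) for s in _UNIT_SYMPTOMS}
    for s in ("fever_value", "oxygen_level", "fever_duration"):
        out[s] = _interval(s, severity)
    return out


@dataclass(frozen=True)
class CaseSpec:
    """Recipe for one synthetic patient case."""

    severity: str
    seed: int = 0
    intervals: dict[str, tuple[float, float]] | None = None
    dl_dominant: str | None = None     # None -> category default
    dl_strength: float | None = None

    def __post_init__(self) -> None:
        if self.severity not in SEVERITY_CLASSES:
            raise ValueError(f"unknown severity category {self.severity!r}")


def gen_softmax(dominant: str, strength: float, seed: int) -> ProbabilityVector:
    """A 3-class probability vector biased toward ``dominant``.

    A concentrated Dirichlet draw around uniform is mixed with the one-hot
    vector of the dominant class: strength 0 gives a near-uniform vector
    (margin ~ 0), strength 1 a one-hot.
    """
    if dominant not in CLASS_LABELS:
        raise ValueError(f"unknown class {dominant!r}")
    if not 0 <= strength <= 1:
        raise ValueError("strength must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    base = rng.dirichlet([40.0, 40.0, 40.0])
    onehot = np.zeros(3)
    onehot[CLASS_LABELS.index(dominant)] = 1.0
    p = (1.0 - strength) * base + strength * onehot
    p = p / p.sum()
    return ProbabilityVector(probs=tuple(p))


def gen_case(spec: CaseSpec) -> tuple[dict[str, float], ProbabilityVector]:
    """One symptom record plus a class-biased classifier output."""
    rng = np.random.default_rng(spec.seed)
    intervals = spec.intervals or class_intervals(spec.severity)
    ranges = load_symptom_ranges()
    record = {}
    for symptom, (lo, hi) in intervals.items():
        spec_r = ranges[symptom]
        if not (spec_r.delta_min <= lo <= hi <= spec_r.delta_max):
            raise ValueError(
                f"interval ({lo}, {hi}) for {symptom!r} outside clinical bounds")
        record[symptom] = float(rng.uniform(lo, hi))
    dominant, strength = _DL_BIAS[spec.severity]
    if spec.dl_dominant is not None:
        dominant = spec.dl_dominant
    if spec.dl_strength is not None:
        strength = spec.dl_strength
    p = gen_softmax(dominant, strength, seed=int(rng.integers(2 ** 31)))
    return record, p


def gen_stream(
    symptom: str,
    trend: str = "stable",
    n: int = 100,
    noise_sd: float = 0.1,
    outlier_rate: float = 0.0,
    seed: int = 0,
    return_outlier_indices: bool = False,
):
    """A symptom time series with linear trend, noise, and rare outliers.

    The trend runs on the severity-aligned normalized axis (``worsening``
    drifts from 0.3 to 0.8 severity, ``improving`` the reverse, ``stable``
    stays at 0.5); ``noise_sd`` is Gaussian noise on that axis.  Values are
    clipped to [0, 1] and mapped back to the raw clinical scale.  With
    probability ``outlier_rate`` a point is replaced by the severity
    extreme (an in-bounds but grossly deviant value).
    """
    ends = {"stable": (0.5, 0.5), "worsening": (0.3, 0.8), "improving": (0.8, 0.3)}
    if trend not in ends:
        raise ValueError(f"unknown trend {trend!r}")
    ranges = load_symptom_ranges()
    spec = ranges[symptom]
    rng = np.random.default_rng(seed)

    s0, s1 = ends[trend]
    sev = np.linspace(s0, s1, n) + rng.normal(0.0, noise_sd, size=n)
    outliers = rng.random(n) < outlier_rate
    sev[outliers] = 1.0
    sev = np.clip(sev, 0.0, 1.0)

    span = spec.delta_max - spec.delta_min
    raw = spec.delta_max - sev * span if spec.severity_inverted else spec.delta_min + sev * span
    hist = SymptomHistory(symptom, tuple(float(t) for t in range(n)), tuple(raw))
    if return_outlier_indices:
        return hist, np.flatnonzero(outliers)
    return hist


def gen_all_streams(
    trend: str = "stable",
    n: int = 100,
    noise_sd: float = 0.25,
    outlier_rate: float = 0.05,
    seed: int = 0,
) -> dict[str, SymptomHistory]:
    """One stream per clinical symptom, with per-symptom derived seeds."""
    rng = np.random.default_rng(seed)
    return {
        symptom: gen_stream(symptom, trend, n, noise_sd, outlier_rate,
                            seed=int(rng.integers(2 ** 31)))
        for symptom in load_symptom_ranges()
    }


@dataclass(frozen=True)
class Phantom:
    """A synthetic radiograph-like image with ground-truth geometry."""

    image: GrayImage
    label: str
    blobs: tuple[tuple[int, int, float], ...] = ()   # (row, col, sigma) per opacity


def gen_phantom(cls: str, size: int = 32, seed: int = 0) -> Phantom:
    """A class-separable grayscale phantom.

    Normal: smooth vertical gradient with two dark elliptical lung fields.
    Pneumonia: the same plus bright Gaussian blobs (consolidation proxy),
    with blob centroids recorded for localization checks.  Abnormal: ring
    and line artifacts.
    """
    if cls not in CLASS_LABELS:
        raise ValueError(f"unknown class {cls!r}")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)

    base = 90.0 + 40.0 * yy / size + rng.normal(0.0, 4.0, size=(size, size))
    for cx in (size * 0.3, size * 0.7):
        lung = np.exp(-(((xx - cx) / (size * 0.16)) ** 2
                        + ((yy - size * 0.5) / (size * 0.3)) ** 2))
        base -= 45.0 * lung

    blobs: list[tuple[int, int, float]] = []
    if cls == "Pneumonia":
        for _ in range(int(rng.integers(1, 3))):
            r = int(rng.integers(int(size * 0.3), int(size * 0.75)))
            c = int(rng.integers(int(size * 0.2), int(size * 0.8)))
            sigma = float(rng.uniform(size * 0.06, size * 0.12))
            blob = np.exp(-(((xx - c) ** 2 + (yy - r) ** 2) / (2 * sigma ** 2)))
            base += 120.0 * blob
            blobs.append((r, c, sigma))
    elif cls == "Abnormal":
        r0 = size * rng.uniform(0.35, 0.65)
        c0 = size * rng.uniform(0.35, 0.65)
        radius = size * rng.uniform(0.18, 0.28)
        dist = np.sqrt((xx - c0) ** 2 + (yy - r0) ** 2)
        base += 90.0 * np.exp(-((dist - radius) ** 2) / (2 * (size * 0.02) ** 2))
        row = int(rng.integers(int(size * 0.2), int(size * 0.8)))
        base[row, :] += 70.0

    return Phantom(image=GrayImage.from_array(base, clip=True), label=cls,
                   blobs=tuple(blobs))


def gen_phantom_dataset(
    n_per_class: int = 10, size: int = 32, seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[Phantom]]:
    """A balanced phantom set as (images [0,1], integer labels, phantoms)."""
    rng = np.random.default_rng(seed)
    images, labels, phantoms = [], [], []
    for ci, cls in enumerate(CLASS_LABELS):
        for _ in range(n_per_class):
            ph = gen_phantom(cls, size=size, seed=int(rng.integers(2 ** 31)))
            images.append(ph.image.pixels.astype(float) / 255.0)
            labels.append(ci)
            phantoms.append(ph)
    return np.asarray(images), np.asarray(labels), phantoms
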