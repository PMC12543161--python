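"""Evaluation metrics and the two headline in-silico experiments.

* :func:`borderline_experiment` — run the fuzzy severity system on
  synthetic cases with and without the DL confidence and study where the
  confidence changes the per-class scores, flagging borderline cases
  (top-two margin <= 2.0 in either setup).
* :func:`stabilization_experiment` — feed noisy symptom streams for all 11
  symptoms through the dynamic membership adjustment and summarise bound
  fluctuations at checkpoints 10/20/30/50/100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .confidence import ProbabilityVector, calibrate
from .dynamics import DEFAULT_CHECKPOINTS, StabilizationReport, run_stabilization
from .fuzzy import BORDERLINE_MARGIN, SEVERITY_CLASSES, RuleBase, assess
from .synth import CaseSpec, gen_all_streams, gen_case

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# confusion-matrix metrics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def support(self) -> int:
        return self.tp + self.fn


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Precision, recall, F1 and specificity; None when undefined (zero
    denominator), never silently 0."""
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    specificity = _ratio(c.tn, c.tn + c.fp)
    return {"precision": precision, "recall": recall, "f1": f1,
            "specificity": specificity}


def confusion_from_labels(y_true, y_pred, classes) -> dict[str, ConfusionCounts]:
    """Per-class one-vs-rest confusion counts."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    out = {}
    for cls in classes:
        tp = sum(t == cls and p == cls for t, p in zip(y_true, y_pred))
        fp = sum(t != cls and p == cls for t, p in zip(y_true, y_pred))
        fn = sum(t == cls and p != cls for t, p in zip(y_true, y_pred))
        tn = len(y_true) - tp - fp - fn
        out[cls] = ConfusionCounts(tp, fp, fn, tn)
    return out


def aggregate_metrics(per_class: dict[str, ConfusionCounts],
                      average: str = "macro") -> dict[str, float | None]:
    """micro / macro / weighted aggregation across classes.

    Weighted aggregation uses support (class counts) as weights.
    """
    if average == "micro":
        total = ConfusionCounts(
            sum(c.tp for c in per_class.values()),
            sum(c.fp for c in per_class.values()),
            sum(c.fn for c in per_class.values()),
            sum(c.tn for c in per_class.values()),
        )
        return metrics(total)
    per = {cls: metrics(c) for cls, c in per_class.items()}
    if average == "macro":
        weights = {cls: 1.0 for cls in per_class}
    elif average == "weighted":
        weights = {cls: float(c.support) for cls, c in per_class.items()}
    else:
        raise ValueError(f"unknown average {average!r}")
    out = {}
    for key in ("precision", "recall", "f1", "specificity"):
        vals = [(per[cls][key], weights[cls]) for cls in per_class
                if per[cls][key] is not None and weights[cls] > 0]
        wsum = sum(w for _, w in vals)
        out[key] = None if not vals or wsum == 0 else \
            sum(v * w for v, w in vals) / wsum
    return out


# --------------------------------------------------------------------------
# borderline experiment
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BorderlineResult:
    case_id: int
    category: str
    with_dl: dict[str, float]       # adjusted per-class scores, DL-assisted
    without_dl: dict[str, float]
    difference: dict[str, float]    # with - without, exactly
    margin_with: float
    margin_without: float
    borderline_with: bool
    borderline_without: bool

    @property
    def borderline(self) -> bool:
        return self.borderline_with or self.borderline_without


def borderline_experiment(
    n_cases: int = 300,
    seed: int = 0,
    rulebase: RuleBase | None = None,
) -> tuple[list[BorderlineResult], pd.DataFrame]:
    """Assess synthetic cases with and without the DL confidence.

    ``n_cases`` cases are generated evenly across the four severity
    categories (75 each at the default 300).  Each case is assessed twice —
    once with its classifier probability vector, once without (the
    non-DL-assisted pathway never sees the vector) — and flagged borderline
    if either setup's top-two score margin is <= 2.0.  Returns the
    per-case results plus a tidy frame of per-class score differences for
    the borderline cases.
    """
    if rulebase is None:
        rulebase = RuleBase.default()
    rng = np.random.default_rng(seed)
    per_cat = n_cases // len(SEVERITY_CLASSES)
    counts = {c: per_cat for c in SEVERITY_CLASSES}
    for c in SEVERITY_CLASSES[:n_cases - per_cat * len(SEVERITY_CLASSES)]:
        counts[c] += 1

    results: list[BorderlineResult] = []
    case_id = 0
    for category in SEVERITY_CLASSES:
        for _ in range(counts[category]):
            spec = CaseSpec(severity=category, seed=int(rng.integers(2 ** 31)))
            record, p = gen_case(spec)
            a_with = assess(record, p, rulebase=rulebase)
            a_without = assess(record, None, rulebase=rulebase)
            diff = {c: a_with.adjusted_scores[c] - a_without.adjusted_scores[c]
                    for c in SEVERITY_CLASSES}
            results.append(BorderlineResult(
                case_id=case_id, category=category,
                with_dl=a_with.adjusted_scores,
                without_dl=a_without.adjusted_scores,
                difference=diff,
                margin_with=a_with.margin, margin_without=a_without.margin,
                borderline_with=a_with.borderline,
                borderline_without=a_without.borderline,
            ))
            case_id += 1

    rows = [
        {"case_id": r.case_id, "category": r.category, "severity_class": c,
         "difference": r.difference[c]}
        for r in results if r.borderline for c in SEVERITY_CLASSES
    ]
    diff_frame = pd.DataFrame(rows, columns=["case_id", "category",
                                             "severity_class", "difference"])
    return results, diff_frame


def borderline_summary(diff_frame: pd.DataFrame) -> pd.DataFrame:
    """Mean |score difference| per severity class among borderline cases."""
    if diff_frame.empty:
        return pd.DataFrame({"severity_class": list(SEVERITY_CLASSES),
                             "mean_abs_difference": [0.0] * 4})
    g = (diff_frame.assign(abs_diff=diff_frame["difference"].abs())
         .groupby("severity_class")["abs_diff"].mean())
    return pd.DataFrame({
        "severity_class": list(SEVERITY_CLASSES),
        "mean_abs_difference": [float(g.get(c, 0.0)) for c in SEVERITY_CLASSES],
    })


def plot_borderline(diff_frame: pd.DataFrame, path) -> None:
    """Per-severity-class line plots of the borderline score differences."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(4, 1, figsize=(8, 10), sharex=True)
    for ax, cls in zip(axes, SEVERITY_CLASSES):
        sub = diff_frame[diff_frame["severity_class"] == cls]
        ax.plot(sub["case_id"].to_numpy(), sub["difference"].to_numpy(),
                marker=".", lw=0.8)
        ax.set_ylabel(cls)
        ax.axhline(0, color="gray", lw=0.5)
    axes[-1].set_xlabel("borderline case id")
    fig.suptitle("Score difference (DL-assisted minus fuzzy-only)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


# --------------------------------------------------------------------------
# stabilization experiment
# --------------------------------------------------------------------------

def stabilization_experiment(
    seed: int = 0,
    checkpoints=DEFAULT_CHECKPOINTS,
    noise_sd: float = 0.25,
    outlier_rate: float = 0.05,
    out_dir: str | Path | None = None,
) -> StabilizationReport:
    """Run the dynamic adjustment on streams for all 11 symptoms.

    Streams are stable-trend with Gaussian noise and occasional outliers.
    If ``out_dir`` is given, writes the bounds and std-dev tables as CSV
    and a fluctuation plot as PNG.
    """
    horizon = max(checkpoints)
    streams = gen_all_streams(trend="stable", n=horizon, noise_sd=noise_sd,
                              outlier_rate=outlier_rate, seed=seed)
    report = run_stabilization(streams, checkpoints=checkpoints)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.bounds_frame().to_csv(out_dir / "stabilization_bounds.csv")
        report.std_frame().to_csv(out_dir / "stabilization_stddev.csv")
        _plot_fluctuations(report, out_dir / "stabilization_fluctuations.png")
    return report


def _plot_fluctuations(report: StabilizationReport, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(8, 7), sharex=True)
    cps = list(report.checkpoints)
    for sym, per_cp in report.fluctuation.items():
        ax1.plot(cps, [per_cp[c][0] for c in cps], marker="o", label=sym)
        ax2.plot(cps, [per_cp[c][1] for c in cps], marker="o", label=sym)
    ax1.set_ylabel("min-bound fluctuation (%)")
    ax2.set_ylabel("max-bound fluctuation (%)")
    ax2.set_xlabel("iteration checkpoint")
    ax1.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
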