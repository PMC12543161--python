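"""Dynamic fuzzy-membership adjustment and stabilization diagnostics.

A patient's symptom values recorded over follow-up visits drive a per-symptom
adjustment of the fuzzy membership bounds, in seven steps:

1. Z-score outlier filtering (drop points beyond 3 population standard
   deviations of the full series).
2. Recent mean and population variance over the last 10 points (all points
   if fewer are available).
3. Smoothing factor ``S = min(1, B + sigma^2 / 100)`` with base ``B = 0.3``.
4. Exponential smoothing ``S_x1 = x1; S_xi = S*x_i + (1-S)*x_{i-1}`` — note
   the recursion deliberately references the previous *raw* value; the
   classic EMA (previous smoothed value) is available as an option.
5. Percentile thresholds from the recent mean on the normalized scale:
   mu <= 0.5 -> (10, 90); mu > 0.5 -> (15, 85).
6. Adjusted min/max = those percentiles of the smoothed series
   (linear-interpolation percentiles), gridded at 0.1 steps.
7. Clipping to the clinical bounds.

The stabilization diagnostics track how much the adjusted bounds fluctuate
as the stream grows, summarised at checkpoints (10, 20, 30, 50, 100
iterations by default): per-iteration percent changes of each bound are
averaged per checkpoint window, combined into initial/final averages, a
stabilization factor ``SF = max(0.4, 1 - Final/Initial)`` and a fluctuation
reduction ``F = (Initial - Final)/Initial * 100``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .confidence import NormalizationSpec, ValidationError, load_symptom_ranges, normalize_symptom

log = logging.getLogger(__name__)

DEFAULT_CHECKPOINTS = (10, 20, 30, 50, 100)
SF_FLOOR = 0.4


@dataclass(frozen=True)
class SymptomHistory:
    """A dated series of raw clinical values for one symptom."""

    symptom: str
    timestamps: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.timestamps) != len(self.values):
            raise ValidationError("timestamps and values must align")
        t = np.asarray(self.timestamps, dtype=float)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValidationError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(np.asarray(self.values, dtype=float))):
            raise ValidationError("values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, symptom: str) -> "SymptomHistory":
        """Build from a CSV-style frame with columns timestamp, symptom, value."""
        sub = df[df["symptom"] == symptom].sort_values("timestamp")
        return cls(symptom, tuple(sub["timestamp"]), tuple(sub["value"]))


@dataclass(frozen=True)
class AdjustmentConfig:
    z_cutoff: float = 3.0
    window: int = 10
    base_smoothing: float = 0.3
    variance_divisor: float = 100.0
    grid_step: float = 0.1
    classic_ema: bool = False   # Step-4 variant: smooth against previous smoothed value

    def __post_init__(self) -> None:
        if not 0 < self.base_smoothing <= 1:
            raise ValidationError("base_smoothing must be in (0, 1]")
        if self.window < 1:
            raise ValidationError("window must be >= 1")


@dataclass(frozen=True)
class AdjustedRange:
    """Evolving membership bounds for one symptom, in clinical units."""

    symptom: str
    a_min: float
    a_max: float
    grid: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.a_min > self.a_max + 1e-12:
            raise ValidationError("a_min must be <= a_max")


# --------------------------------------------------------------------------
# the seven steps
# --------------------------------------------------------------------------

def zscore_filter(series: Sequence[float], cutoff: float = 3.0) -> np.ndarray:
    """Drop values deviating more than ``cutoff`` population SDs from the mean.

    Uses the full series' mean and population standard deviation.  Series
    with fewer than two points, or zero spread, pass through unchanged.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        return x.copy()
    sd = x.std()  # population
    if sd == 0:
        return x.copy()
    z = np.abs(x - x.mean()) / sd
    return x[z <= cutoff]


def recent_stats(series: Sequence[float], n: int = 10) -> tuple[float, float]:
    """Mean and population variance of the last ``min(n, len)`` points."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot compute statistics of an empty series")
    tail = x[-n:]
    return float(tail.mean()), float(tail.var())


def smoothing_factor(variance: float, base: float = 0.3, divisor: float = 100.0) -> float:
    """S = min(1, B + sigma^2 / 100).

    On raw clinical scales the variance term can exceed 1 (fever-duration
    variance runs to hundreds); the cap keeps the smoothing recursion convex.
    """
    return min(1.0, base + variance / divisor)


def exp_smooth(series: Sequence[float], s: float, classic_ema: bool = False) -> np.ndarray:
    """Exponential smoothing of a series with factor ``s``.

    Default recursion uses the previous *raw* observation:
    out[0] = x[0]; out[i] = s*x[i] + (1-s)*x[i-1].  With ``classic_ema``
    the previous *smoothed* value is used instead.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        return x.copy()
    out = np.empty_like(x)
    out[0] = x[0]
    if classic_ema:
        for i in range(1, x.size):
            out[i] = s * x[i] + (1 - s) * out[i - 1]
    else:
        out[1:] = s * x[1:] + (1 - s) * x[:-1]
    return out


def percentile_bounds(mu_normalized: float) -> tuple[float, float]:
    """Percentile thresholds from the recent mean on the normalized scale.

    mu <= 0.5 -> (10, 90); mu > 0.5 -> (15, 85).  The boundary value 0.5
    takes the (10, 90) branch.
    """
    return (10.0, 90.0) if mu_normalized <= 0.5 else (15.0, 85.0)


def adjusted_range(
    smoothed: Sequence[float],
    percentiles: tuple[float, float],
    bounds: NormalizationSpec,
    symptom: str = "",
    step: float = 0.1,
) -> AdjustedRange:
    """Percentile bounds of the smoothed series, gridded and clipped.

    Percentiles use linear interpolation between order statistics; the grid
    runs from the adjusted minimum to the adjusted maximum in ``step``
    increments on the raw clinical scale; both ends are clipped to the
    clinical bounds.
    """
    x = np.asarray(smoothed, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot derive a range from an empty series")
    lo, hi = np.percentile(x, percentiles)  # linear interpolation
    lo = float(np.clip(lo, bounds.delta_min, bounds.delta_max))
    hi = float(np.clip(hi, bounds.delta_min, bounds.delta_max))
    if lo > hi:
        lo, hi = hi, lo
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    grid = tuple(min(lo + i * step, hi) for i in range(n))
    if grid[-1] < hi - 1e-9:
        grid = grid + (hi,)
    return AdjustedRange(symptom=symptom, a_min=lo, a_max=hi, grid=grid)


def update_membership(
    history: SymptomHistory,
    config: AdjustmentConfig = AdjustmentConfig(),
    bounds: NormalizationSpec | None = None,
) -> AdjustedRange:
    """Run the full seven-step adjustment on one symptom history."""
    if len(history) == 0:
        raise ValidationError(f"empty history for symptom {history.symptom!r}")
    if bounds is None:
        bounds = load_symptom_ranges()[history.symptom]

    retained = zscore_filter(history.values, config.z_cutoff)           # step 1
    if retained.size == 0:                                              # cannot happen with cutoff>0; guard anyway
        retained = np.asarray(history.values, dtype=float)
    mu, var = recent_stats(retained, config.window)                     # step 2
    s = smoothing_factor(var, config.base_smoothing, config.variance_divisor)  # step 3
    smoothed = exp_smooth(retained, s, config.classic_ema)              # step 4
    mu_norm = normalize_symptom(mu, bounds)                             # step 5 pivot on the normalized scale
    pcts = percentile_bounds(mu_norm)
    return adjusted_range(smoothed, pcts, bounds, history.symptom, config.grid_step)  # steps 6-7


# --------------------------------------------------------------------------
# stabilization diagnostics
# --------------------------------------------------------------------------

@dataclass
class StabilizationReport:
    """Fluctuation diagnostics of the adjusted bounds across checkpoints."""

    checkpoints: tuple[int, ...]
    #: symptom -> checkpoint -> (a_min, a_max)
    bounds: dict[str, dict[int, tuple[float, float]]]
    #: symptom -> checkpoint -> mean |pct change| of (min, max) bound in window
    fluctuation: dict[str, dict[int, tuple[float, float]]]
    #: symptom -> checkpoint -> std of pct changes of (min, max) bound
    fluctuation_std: dict[str, dict[int, tuple[float, float]]]
    initial_average: float
    final_average: float
    stabilization_factor: float | None
    fluctuation_reduction: float | None
    over_one_percent: tuple[str, ...]   # symptoms fluctuating > 1% at the last checkpoint
    error: str | None = None

    def bounds_frame(self) -> pd.DataFrame:
        """Min/Max bounds per symptom per checkpoint (wide layout)."""
        rows = {}
        for sym, per_cp in self.bounds.items():
            rows[sym] = {
                f"Min/Max @{cp}": f"{per_cp[cp][0]:.3g}/{per_cp[cp][1]:.3g}"
                for cp in self.checkpoints
            }
        return pd.DataFrame.from_dict(rows, orient="index")

    def std_frame(self) -> pd.DataFrame:
        rows = {}
        for sym, per_cp in self.fluctuation_std.items():
            rows[sym] = {
                f"StdDev@{cp} (min/max)": f"{per_cp[cp][0]:.2f}/{per_cp[cp][1]:.2f}"
                for cp in self.checkpoints
            }
        return pd.DataFrame.from_dict(rows, orient="index")


def _pct_changes(traj: Sequence[tuple[float, float]]) -> tuple[list[float], list[float]]:
    """Per-iteration percent changes of the (min, max) bound trajectory.

    A step whose previous bound is ~0 is skipped (percent change undefined).
    """
    mins, maxs = [], []
    for (pm, px), (cm, cx) in zip(traj[:-1], traj[1:]):
        if abs(pm) > 1e-12:
            mins.append(abs(cm - pm) / abs(pm) * 100.0)
        if abs(px) > 1e-12:
            maxs.append(abs(cx - px) / abs(px) * 100.0)
    return mins, maxs


def stabilization_metrics(
    trajectories: Mapping[str, Sequence[tuple[float, float]]],
    checkpoints: Sequence[int] = DEFAULT_CHECKPOINTS,
    over_threshold: float = 1.0,
) -> StabilizationReport:
    """Summarise bound-fluctuation behaviour from per-iteration trajectories.

    ``trajectories`` maps each symptom to its (a_min, a_max) at every
    iteration 1..T.  For each checkpoint the per-iteration percent changes
    within the window since the previous checkpoint are averaged (and their
    population std taken) per symptom.  InitialAverage combines the mean
    min- and max-bound fluctuations at the first checkpoint, FinalAverage
    those at the last; SF = max(0.4, 1 - Final/Initial) and
    F = (Initial - Final)/Initial * 100.  Symptoms whose mean fluctuation
    (either bound) exceeds ``over_threshold`` percent at the last checkpoint
    are flagged for additional stabilization.
    """
    cps = tuple(int(c) for c in checkpoints)
    fluct: dict[str, dict[int, tuple[float, float]]] = {}
    fstd: dict[str, dict[int, tuple[float, float]]] = {}
    bounds_at: dict[str, dict[int, tuple[float, float]]] = {}

    for sym, traj in trajectories.items():
        traj = list(traj)
        fluct[sym], fstd[sym], bounds_at[sym] = {}, {}, {}
        prev_cp = 1
        for cp in cps:
            hi = min(cp, len(traj))
            window = traj[prev_cp - 1: hi]        # iterations prev_cp..cp
            mins, maxs = _pct_changes(window)
            fluct[sym][cp] = (
                float(np.mean(mins)) if mins else 0.0,
                float(np.mean(maxs)) if maxs else 0.0,
            )
            fstd[sym][cp] = (
                float(np.std(mins)) if mins else 0.0,
                float(np.std(maxs)) if maxs else 0.0,
            )
            bounds_at[sym][cp] = traj[hi - 1]
            prev_cp = cp

    first, last = cps[0], cps[-1]
    mean_init_min = float(np.mean([fluct[s][first][0] for s in fluct]))
    mean_init_max = float(np.mean([fluct[s][first][1] for s in fluct]))
    mean_fin_min = float(np.mean([fluct[s][last][0] for s in fluct]))
    mean_fin_max = float(np.mean([fluct[s][last][1] for s in fluct]))
    initial_avg = (mean_init_min + mean_init_max) / 2.0
    final_avg = (mean_fin_min + mean_fin_max) / 2.0

    error = None
    if initial_avg == 0.0:
        sf, reduction = None, None
        error = "initial fluctuation average is zero; SF and F undefined"
        log.warning(error)
    else:
        sf = max(SF_FLOOR, 1.0 - final_avg / initial_avg)
        reduction = (initial_avg - final_avg) / initial_avg * 100.0

    flagged = tuple(
        s for s in fluct
        if fluct[s][last][0] > over_threshold or fluct[s][last][1] > over_threshold
    )
    if flagged:
        log.info("symptoms fluctuating > %.1f%% at checkpoint %d: %s",
                 over_threshold, last, ", ".join(flagged))

    return StabilizationReport(
        checkpoints=cps, bounds=bounds_at, fluctuation=fluct,
        fluctuation_std=fstd, initial_average=initial_avg,
        final_average=final_avg, stabilization_factor=sf,
        fluctuation_reduction=reduction, over_one_percent=flagged, error=error,
    )


def run_stabilization(
    streams: Mapping[str, SymptomHistory],
    checkpoints: Sequence[int] = DEFAULT_CHECKPOINTS,
    config: AdjustmentConfig = AdjustmentConfig(),
    ranges: Mapping[str, NormalizationSpec] | None = None,
) -> StabilizationReport:
    """Feed each stream point-by-point through the adjustment algorithm.

    At iteration t the bounds are recomputed from the stream observed so
    far, so the bounds used at each iteration reflect the updates from the
    previous ones; the full per-iteration bound trajectories then feed the
    stabilization metrics.  Deterministic for deterministic streams.
    """
    if ranges is None:
        ranges = load_symptom_ranges()
    horizon = max(int(c) for c in checkpoints)
    trajectories: dict[str, list[tuple[float, float]]] = {}
    for sym, hist in streams.items():
        if len(hist) < horizon:
            raise ValidationError(
                f"stream for {hist.symptom!r} has {len(hist)} points; "
                f"needs at least {horizon}")
        traj = []
        for t in range(1, horizon + 1):
            sub = SymptomHistory(hist.symptom, hist.timestamps[:t], hist.values[:t])
            rng = update_membership(sub, config, ranges[hist.symptom])
            traj.append((rng.a_min, rng.a_max))
        trajectories[sym] = traj
    return stabilization_metrics(trajectories, checkpoints)
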