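"""Dynamic insulin-secretion analysis for islet perifusion experiments.

A perifusion run flows buffer over islets at a constant rate while the
outflow is collected in timed fractions and assayed for insulin.  The
standard protocol analysed here holds islets at basal (2.8 mmol/L) glucose
for 52 min, applies a secretagogue (16.7 mmol/L glucose, 10 umol/L
glibenclamide, or 30 mmol/L KCl) for 16 min, then returns to basal buffer.
Fractions are collected every minute between 49 and 58 min, when first-phase
secretion changes fastest, and every 2 min for the rest of the run.

The quantities computed here are the field's standard dynamic-secretion
summaries:

* basal secretion — mean insulin over the pre-stimulus fractions;
* stimulation index (SI) — window-averaged secretion divided by basal.
  First-phase SI averages fractions collected 53-56 min, second-phase SI
  averages 57-70 min (window endpoints inclusive);
* first/second-phase ratio — SI1/SI2, an index of how prominent the sharp
  transient first phase is relative to the sustained plateau;
* AUC — trapezoidal area under the normalized trace across the stimulus
  window, without baseline subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Literal, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "SamplingGrid",
    "RampSchedule",
    "PerifusionTrace",
    "SecretionMetrics",
    "FIRST_PHASE_WINDOW",
    "SECOND_PHASE_WINDOW",
    "build_sampling_grid",
    "normalize_trace",
    "basal_mean",
    "stimulation_index",
    "phase_ratio",
    "auc_ramp",
    "secretion_metrics",
    "compare_groups_ratio",
]

#: Fraction-collection window (minutes, inclusive) averaged for first-phase SI.
FIRST_PHASE_WINDOW: Tuple[float, float] = (53.0, 56.0)
#: Window averaged for second-phase SI.  Extends 2 min past the canonical
#: stimulus end (68 min); kept as the protocol defines it.
SECOND_PHASE_WINDOW: Tuple[float, float] = (57.0, 70.0)

#: Start/end (minutes) of the dense per-minute fraction collection.
DENSE_START_MIN = 49.0
DENSE_END_MIN = 58.0


@dataclass(frozen=True)
class SamplingGrid:
    """Ordered fraction-collection times with the pump flow rate.

    Timestamps denote collection-end times.  The canonical grid samples
    every 2 min, densifying to every minute between 49 and 58 min.
    """

    collection_times_min: np.ndarray
    flow_rate_ul_min: float = 120.0

    def __post_init__(self) -> None:
        t = np.asarray(self.collection_times_min, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("grid needs at least two collection times")
        if not np.all(np.diff(t) > 0):
            raise ValueError("collection times must be strictly increasing")
        if self.flow_rate_ul_min <= 0:
            raise ValueError("flow rate must be positive")
        object.__setattr__(self, "collection_times_min", t)

    @property
    def run_length_min(self) -> float:
        return float(self.collection_times_min[-1])

    def __len__(self) -> int:
        return int(self.collection_times_min.size)


@dataclass(frozen=True)
class RampSchedule:
    """Secretagogue schedule: basal glucose, stimulus identity and window."""

    basal_glucose_mM: float = 2.8
    stimulus_label: str = "glucose 16.7 mM"
    stimulus_start_min: float = 52.0
    stimulus_duration_min: float = 16.0

    def __post_init__(self) -> None:
        if self.stimulus_start_min <= 0 or self.stimulus_duration_min <= 0:
            raise ValueError("stimulus window must have positive start and duration")

    @property
    def stimulus_end_min(self) -> float:
        return self.stimulus_start_min + self.stimulus_duration_min


@dataclass(frozen=True)
class PerifusionTrace:
    """One perifusion run: a grid, one insulin value per fraction, a schedule.

    ``total_content`` is the islets' total insulin content (same units as
    the per-fraction amounts), required for percent-of-total normalization.
    ``normalized`` records which normalization, if any, has been applied.
    """

    grid: SamplingGrid
    insulin: np.ndarray
    schedule: RampSchedule = field(default_factory=RampSchedule)
    total_content: float | None = None
    normalized: Literal["raw", "fold_over_basal", "percent_total"] = "raw"

    def __post_init__(self) -> None:
        ins = np.asarray(self.insulin, dtype=float)
        if ins.shape != self.grid.collection_times_min.shape:
            raise ValueError("need exactly one insulin value per collection time")
        if np.any(ins < 0) or not np.all(np.isfinite(ins)):
            raise ValueError("insulin values must be finite and non-negative")
        if self.schedule.stimulus_end_min > self.grid.run_length_min:
            raise ValueError("stimulus window extends past the end of the grid")
        object.__setattr__(self, "insulin", ins)

    @property
    def times(self) -> np.ndarray:
        return self.grid.collection_times_min


@dataclass(frozen=True)
class SecretionMetrics:
    """Summary metrics for one trace (all on the fold-over-basal scale)."""

    basal_mean: float
    si_first: float
    si_second: float
    first_second_ratio: float
    auc_ramp: float


def build_sampling_grid(
    run_length_min: float, flow_rate_ul_min: float = 120.0
) -> SamplingGrid:
    """Build the canonical fraction grid for a run of the given length.

    Fractions fall every 2 min (2, 4, ..., 48), every minute from 49 to
    58, then every 2 min (60, 62, ...) up to ``run_length_min``.
    """
    if run_length_min < DENSE_END_MIN:
        raise ValueError(
            f"run must reach at least {DENSE_END_MIN:g} min to cover the "
            "per-minute collection window"
        )
    times = np.concatenate(
        [
            np.arange(2.0, DENSE_START_MIN, 2.0),
            np.arange(DENSE_START_MIN, DENSE_END_MIN + 0.5, 1.0),
            np.arange(DENSE_END_MIN + 2.0, run_length_min + 0.5, 2.0),
        ]
    )
    return SamplingGrid(times, flow_rate_ul_min=flow_rate_ul_min)


def _basal_mask(trace: PerifusionTrace) -> np.ndarray:
    # Basal = all pre-stimulus fractions (collection time <= stimulus start);
    # the post-stimulus return to 2.8 mM is not part of basal.
    return trace.times <= trace.schedule.stimulus_start_min


def basal_mean(trace: PerifusionTrace) -> float:
    """Mean insulin over the pre-stimulus (basal glucose) fractions."""
    mask = _basal_mask(trace)
    if not mask.any():
        raise ValueError("no fractions precede the stimulus")
    return float(trace.insulin[mask].mean())


def normalize_trace(
    trace: PerifusionTrace,
    mode: Literal["fold_over_basal", "percent_total"] = "fold_over_basal",
) -> PerifusionTrace:
    """Normalize a trace for cross-donor comparison.

    ``fold_over_basal`` divides every fraction by the mean pre-stimulus
    (basal) secretion, so basal averages 1 — the convention used when
    combining donors.  ``percent_total`` expresses each fraction as a
    percentage of the islets' total insulin content.  Re-normalizing an
    already fold-over-basal trace is a no-op.
    """
    if mode == "fold_over_basal":
        if trace.normalized == "fold_over_basal":
            return trace
        if trace.normalized == "percent_total":
            raise ValueError("trace already normalized to percent of total content")
        basal = basal_mean(trace)
        if basal <= 0:
            raise ValueError("basal mean must be positive for fold normalization")
        return replace(trace, insulin=trace.insulin / basal, normalized=mode)
    if mode == "percent_total":
        if trace.normalized != "raw":
            raise ValueError("can only percent-normalize a raw trace")
        if trace.total_content is None or trace.total_content <= 0:
            raise ValueError("percent_total requires a positive total insulin content")
        return replace(
            trace, insulin=100.0 * trace.insulin / trace.total_content, normalized=mode
        )
    raise ValueError(f"unknown normalization mode {mode!r}")


def _window_mask(trace: PerifusionTrace, window: Tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (trace.times >= lo) & (trace.times <= hi)


def stimulation_index(
    trace: PerifusionTrace, phase: Literal["first", "second"]
) -> float:
    """Window-averaged secretion divided by average basal secretion.

    First phase averages fractions collected at 53-56 min; second phase
    averages 57-70 min (both inclusive).  Works on raw or fold-normalized
    traces — basal division makes the result scale-free either way.
    """
    window = FIRST_PHASE_WINDOW if phase == "first" else SECOND_PHASE_WINDOW
    if phase not in ("first", "second"):
        raise ValueError(f"phase must be 'first' or 'second', got {phase!r}")
    mask = _window_mask(trace, window)
    if not mask.any():
        raise ValueError(f"no fractions collected within {window} min")
    basal = basal_mean(trace)
    if basal <= 0:
        raise ValueError("basal mean must be positive")
    return float(trace.insulin[mask].mean() / basal)


def phase_ratio(metrics: SecretionMetrics) -> float:
    """SI1/SI2: the prominence of first-phase over second-phase secretion."""
    if metrics.si_second <= 0:
        raise ValueError("second-phase SI must be positive to form the ratio")
    return metrics.si_first / metrics.si_second


def auc_ramp(
    trace: PerifusionTrace, window: Tuple[float, float] | None = None
) -> float:
    """Trapezoidal area under the normalized trace across the stimulus window.

    No baseline subtraction is applied; report alongside basal so either
    convention can be reconstructed.  The trace is treated as piecewise
    linear between fractions, so the integral is invariant to inserting an
    interior grid point on a linear segment and additive over adjacent
    windows.
    """
    if trace.normalized == "raw":
        raise ValueError("normalize the trace before computing AUC")
    if window is None:
        window = (trace.schedule.stimulus_start_min, trace.schedule.stimulus_end_min)
    lo, hi = window
    t = trace.times
    if lo < t[0] or hi > t[-1] or lo >= hi:
        raise ValueError(f"window {window} outside the sampled grid")
    inner = (t > lo) & (t < hi)
    xs = np.concatenate([[lo], t[inner], [hi]])
    ys = np.interp(xs, t, trace.insulin)
    return float(np.trapezoid(ys, xs))


def secretion_metrics(trace: PerifusionTrace) -> SecretionMetrics:
    """Compute basal, SI1, SI2, their ratio, and stimulus-window AUC."""
    basal = basal_mean(trace)
    si1 = stimulation_index(trace, "first")
    si2 = stimulation_index(trace, "second")
    fold = normalize_trace(trace, "fold_over_basal")
    metrics = SecretionMetrics(
        basal_mean=basal,
        si_first=si1,
        si_second=si2,
        first_second_ratio=si1 / si2 if si2 > 0 else float("nan"),
        auc_ramp=auc_ramp(fold),
    )
    return metrics


def compare_groups_ratio(
    ratios_by_group: Mapping[str, Sequence[float]], reference_group: str
) -> Dict[str, float]:
    """Express each group's mean first/second ratio as a percent of a reference.

    Ratios are computed per donor and averaged within group; the return maps
    each group to 100 * (group mean / reference mean), so the reference group
    maps to 100.
    """
    if reference_group not in ratios_by_group:
        raise KeyError(f"reference group {reference_group!r} not present")
    ref = np.asarray(ratios_by_group[reference_group], dtype=float)
    if ref.size == 0 or ref.mean() == 0:
        raise ValueError("reference group must be nonempty with nonzero mean")
    ref_mean = ref.mean()
    return {
        group: float(100.0 * np.asarray(vals, dtype=float).mean() / ref_mean)
        for group, vals in ratios_by_group.items()
    }
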