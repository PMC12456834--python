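"""Bud-length trace metrics: activity, lag, maximum growth rate, RGI, outcomes.

Works on either experimental-format traces (daily lengths in mm) or
simulated trajectories re-expressed as length traces (model units per time
step). The same extractor serves both: the length series is smoothed with a
centered moving average and differentiated with centered differences, and
all downstream metrics (activity, lag, maximum growth rate) are read off
the smoothed rate series.

A bud is *active* if its smoothed growth rate ever exceeds the activity
threshold (strictly): 2.5 mm/day for experimental traces, 0.02 length units
per time step for simulated ones. The *lag* is the time from the start of
the trace to the first rate sample exceeding the threshold. The *relative
growth index* (RGI) of an active explant is the longest bud's final length
divided by the summed final length of both buds: 0.5 means equal growth,
1 complete dominance.

Growth outcomes per explant are "both", "one", or "none". Experimental mode
counts active buds. Simulated mode follows the dominance convention used for
model runs: "one" when the longer bud's final length is more than three
times the shorter's; "both" when the ratio is at most three and both buds
passed an activation length (default 11x their initial length, i.e. initial
plus ten times initial); "none" otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BudTrace",
    "BudMetrics",
    "TraceMetrics",
    "OutcomeFractions",
    "InsufficientDataError",
    "UndefinedMetricError",
    "EXPERIMENTAL_ACTIVITY_THRESHOLD",
    "SIMULATED_ACTIVITY_THRESHOLD",
    "DEFAULT_SMOOTHING_WINDOW",
    "growth_rate_series",
    "is_active",
    "lag_time",
    "max_growth_rate",
    "relative_growth_index",
    "growth_outcome",
    "compute_metrics",
    "outcome_summary",
    "mitchison_series",
    "trajectory_to_trace",
]

EXPERIMENTAL_ACTIVITY_THRESHOLD = 2.5  # mm/day
SIMULATED_ACTIVITY_THRESHOLD = 0.02  # length units per time step
DEFAULT_SMOOTHING_WINDOW = 3  # samples


class InsufficientDataError(ValueError):
    pass


class UndefinedMetricError(ValueError):
    pass


@dataclass(frozen=True)
class BudTrace:
    """One explant's paired bud-length series.

    ``times`` are days for experimental traces and time steps for simulated
    ones; lengths are mm and model length units respectively.
    """

    explant_id: str
    label: str
    times: np.ndarray
    top: np.ndarray
    bottom: np.ndarray
    source: str = "experimental"  # "experimental" | "simulated"
    excluded: bool = False

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        top = np.asarray(self.top, dtype=float)
        bottom = np.asarray(self.bottom, dtype=float)
        if not (len(times) == len(top) == len(bottom)):
            raise ValueError("times, top, bottom must have equal length")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(top < 0) or np.any(bottom < 0):
            raise ValueError("lengths must be nonnegative")
        if self.source not in ("experimental", "simulated"):
            raise ValueError(f"unknown source {self.source!r}")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "top", top)
        object.__setattr__(self, "bottom", bottom)

    def default_threshold(self) -> float:
        return (
            EXPERIMENTAL_ACTIVITY_THRESHOLD
            if self.source == "experimental"
            else SIMULATED_ACTIVITY_THRESHOLD
        )


@dataclass(frozen=True)
class BudMetrics:
    active: bool
    lag: float | None  # time units from trace start; None if inactive
    max_rate: float
    final_length: float


@dataclass(frozen=True)
class TraceMetrics:
    explant_id: str
    label: str
    top: BudMetrics
    bottom: BudMetrics
    outcome: str  # "both" | "one" | "none"
    rgi: float | None  # None unless the explant is active

    @property
    def active(self) -> bool:
        return self.top.active or self.bottom.active


@dataclass(frozen=True)
class OutcomeFractions:
    p_both: float
    p_one: float
    p_none: float

    def __post_init__(self):
        total = self.p_both + self.p_one + self.p_none
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"outcome fractions must sum to 1, got {total}")
        for v in (self.p_both, self.p_one, self.p_none):
            if not 0 <= v <= 1:
                raise ValueError("fractions must lie in [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_both, self.p_one, self.p_none])


def growth_rate_series(
    lengths: np.ndarray,
    times: np.ndarray,
    smoothing_window: int = DEFAULT_SMOOTHING_WINDOW,
) -> np.ndarray:
    """Smoothed first-derivative series aligned to the time points.

    The length series is smoothed with a centered moving average of
    ``smoothing_window`` samples (shrinking at the edges) and differentiated
    with centered differences (one-sided at the ends).
    """
    lengths = np.asarray(lengths, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(lengths) < 3:
        raise InsufficientDataError("need at least 3 time points")
    if smoothing_window >= 1:
        smoothed = (
            pd.Series(lengths)
            .rolling(smoothing_window, center=True, min_periods=1)
            .mean()
            .to_numpy()
        )
    else:
        smoothed = lengths
    return np.gradient(smoothed, times)


def is_active(rates: np.ndarray, threshold: float) -> bool:
    """True iff any smoothed rate strictly exceeds the threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return bool(np.any(np.asarray(rates) > threshold))


def lag_time(rates: np.ndarray, times: np.ndarray, threshold: float) -> float:
    """Time from trace start to the first rate sample above threshold."""
    rates = np.asarray(rates)
    times = np.asarray(times, dtype=float)
    above = np.flatnonzero(rates > threshold)
    if above.size == 0:
        raise UndefinedMetricError("lag undefined for an inactive bud")
    return float(times[above[0]] - times[0])


def max_growth_rate(rates: np.ndarray) -> float:
    """Maximum of the smoothed rate series."""
    rates = np.asarray(rates)
    if rates.size == 0:
        raise UndefinedMetricError("empty rate series")
    return float(np.max(rates))


def relative_growth_index(top_final: float, bottom_final: float) -> float:
    """Longest final bud length over the summed final length; in [0.5, 1]."""
    total = top_final + bottom_final
    if total <= 0:
        raise UndefinedMetricError("RGI undefined when both lengths are 0")
    return max(top_final, bottom_final) / total


def _bud_metrics(lengths, times, threshold, window) -> BudMetrics:
    rates = growth_rate_series(lengths, times, window)
    active = is_active(rates, threshold)
    return BudMetrics(
        active=active,
        lag=lag_time(rates, times, threshold) if active else None,
        max_rate=max_growth_rate(rates),
        final_length=float(lengths[-1]),
    )


def growth_outcome(
    trace: BudTrace,
    mode: str | None = None,
    threshold: float | None = None,
    smoothing_window: int = DEFAULT_SMOOTHING_WINDOW,
    activation_factor: float = 10.0,
) -> str:
    """Growth outcome of one explant: "both", "one", or "none".

    ``mode`` defaults to the trace's source. Experimental mode counts active
    buds (2 -> both, 1 -> one, 0 -> none). Simulated mode applies the 3x
    final-length dominance rule; "both" additionally requires both final
    lengths above ``initial + activation_factor * initial``, since a pair of
    equally dormant buds also has a length ratio of 1.
    """
    mode = mode or trace.source
    if mode == "experimental":
        threshold = threshold if threshold is not None else trace.default_threshold()
        n_active = sum(
            _bud_metrics(lengths, trace.times, threshold, smoothing_window).active
            for lengths in (trace.top, trace.bottom)
        )
        return {2: "both", 1: "one", 0: "none"}[n_active]
    if mode != "simulated":
        raise ValueError(f"unknown mode {mode!r}")
    top_f, bot_f = float(trace.top[-1]), float(trace.bottom[-1])
    hi, lo = max(top_f, bot_f), min(top_f, bot_f)
    if hi > 3.0 * lo:
        return "one"
    act_top = trace.top[0] * (1.0 + activation_factor)
    act_bot = trace.bottom[0] * (1.0 + activation_factor)
    if top_f > act_top and bot_f > act_bot:
        return "both"
    return "none"


def compute_metrics(
    trace: BudTrace,
    mode: str | None = None,
    threshold: float | None = None,
    smoothing_window: int = DEFAULT_SMOOTHING_WINDOW,
    activation_factor: float = 10.0,
) -> TraceMetrics:
    """Per-bud and per-explant metrics for one trace."""
    mode = mode or trace.source
    threshold = threshold if threshold is not None else trace.default_threshold()
    top = _bud_metrics(trace.top, trace.times, threshold, smoothing_window)
    bottom = _bud_metrics(trace.bottom, trace.times, threshold, smoothing_window)
    outcome = growth_outcome(
        trace, mode, threshold=threshold, smoothing_window=smoothing_window,
        activation_factor=activation_factor,
    )
    active = top.active or bottom.active
    rgi = None
    if active and (top.final_length + bottom.final_length) > 0:
        rgi = relative_growth_index(top.final_length, bottom.final_length)
    return TraceMetrics(
        explant_id=trace.explant_id,
        label=trace.label,
        top=top,
        bottom=bottom,
        outcome=outcome,
        rgi=rgi,
    )


def outcome_summary(
    traces: list[BudTrace] | list[TraceMetrics], **metric_kwargs
) -> tuple[OutcomeFractions, float]:
    """Outcome fractions over explants plus the percentage of active explants.

    Accepts raw traces (metrics computed on the fly) or precomputed metrics.
    Excluded traces (wilted explants) are dropped before counting.
    """
    if len(traces) == 0:
        raise ValueError("need at least one trace")
    metrics = [
        t if isinstance(t, TraceMetrics) else compute_metrics(t, **metric_kwargs)
        for t in traces
        if not (isinstance(t, BudTrace) and t.excluded)
    ]
    if len(metrics) == 0:
        raise ValueError("all traces were excluded")
    n = len(metrics)
    counts = {"both": 0, "one": 0, "none": 0}
    for m in metrics:
        counts[m.outcome] += 1
    fractions = OutcomeFractions(
        p_both=counts["both"] / n, p_one=counts["one"] / n, p_none=counts["none"] / n
    )
    percent_active = 100.0 * (counts["both"] + counts["one"]) / n
    return fractions, percent_active


def mitchison_series(traces: list[BudTrace], **metric_kwargs) -> pd.DataFrame:
    """Long-format (top length, bottom length) pairs over time per explant.

    Rows carry the explant id, label, time, both lengths, and the explant's
    growth outcome for coloring, ordered by explant then time.
    """
    frames = []
    for trace in traces:
        outcome = growth_outcome(trace, **metric_kwargs)
        frames.append(
            pd.DataFrame(
                {
                    "explant_id": trace.explant_id,
                    "label": trace.label,
                    "t": trace.times,
                    "top": trace.top,
                    "bottom": trace.bottom,
                    "outcome": outcome,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def trajectory_to_trace(traj, explant_id: str, label: str = "") -> BudTrace:
    """Re-express a simulated trajectory as a simulated-source BudTrace."""
    return BudTrace(
        explant_id=explant_id,
        label=label,
        times=traj.times,
        top=traj.N,
        bottom=traj.M,
        source="simulated",
    )
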