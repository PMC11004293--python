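"""Time-resolved firing/event rates via a uniform-kernel (boxcar) KDE.

The rate at time t is the number of events within the centered window
``[t - w/2, t + w/2]`` divided by w (default w = 0.5 s, the full support of
the uniform kernel), evaluated on a uniform grid.  Windows truncated at the
series boundaries use the truncated width as denominator, which keeps the
estimator unbiased at the edges.

Two normalization rules are provided: ``single_shot`` divides by the mean
rate over the 5 s preceding stimulus onset; ``repetitive`` divides by the
mean rate over the 5 min preceding the first train.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    DegenerateBaselineError,
    EventList,
    InvalidParameterError,
    RangeError,
)

__all__ = ["RateSeries", "IntervalSummary", "kde_rate", "kde_integral",
           "normalize_rate", "interval_mean_frequency",
           "BASELINE_S", "NORMALIZATION_BASELINES"]

#: baseline-window length (s) preceding stimulus onset, per normalization mode
NORMALIZATION_BASELINES = {"single_shot": 5.0, "repetitive": 300.0}
BASELINE_S = NORMALIZATION_BASELINES  # alias


@dataclass
class RateSeries:
    """Uniformly gridded event rate (Hz, or dimensionless once normalized)."""

    times: np.ndarray
    values: np.ndarray
    kernel_width: float
    normalized: bool = False
    baseline_window: Optional[Tuple[float, float]] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times.size != self.values.size or self.times.size == 0:
            raise InvalidParameterError("times and values must be equal-length and non-empty")
        if self.times.size > 2:
            steps = np.diff(self.times)
            if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
                raise InvalidParameterError("grid must be uniform")
        if not self.normalized and self.values.size and self.values.min() < 0:
            raise InvalidParameterError("unnormalized rates must be >= 0")

    @property
    def grid_step(self) -> float:
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 0.0

    def mean_in(self, start: float, end: float) -> float:
        mask = (self.times >= start) & (self.times < end)
        if not mask.any():
            raise RangeError(f"window [{start}, {end}] s contains no grid points")
        return float(self.values[mask].mean())


@dataclass(frozen=True)
class IntervalSummary:
    """Mean event frequency over a labelled analysis window."""

    label: str
    window: Tuple[float, float]
    mean_frequency: float

    def __post_init__(self):
        if self.window[1] <= self.window[0]:
            raise InvalidParameterError("window start must precede end")


# ---------------------------------------------------------------------------

def kde_rate(
    events: EventList,
    *,
    grid_step: float = 0.01,
    kernel_width: float = 0.5,
    t_start: float = 0.0,
    t_stop: Optional[float] = None,
) -> RateSeries:
    """Boxcar-KDE event rate on a uniform grid.

    ``t_stop`` defaults to the last event time plus half a kernel width; it
    must be supplied for an empty event list.
    """
    if kernel_width <= 0 or grid_step <= 0:
        raise InvalidParameterError("kernel_width and grid_step must be > 0")
    if t_stop is None:
        if len(events) == 0:
            raise InvalidParameterError("t_stop required for an empty event list (grid would be empty)")
        t_stop = float(events.times[-1]) + kernel_width / 2.0
    if t_stop <= t_start:
        raise InvalidParameterError("empty grid: t_stop must exceed t_start")

    grid = t_start + np.arange(int(np.floor((t_stop - t_start) / grid_step)) + 1) * grid_step
    w2 = kernel_width / 2.0
    lo = np.maximum(grid - w2, t_start)
    hi = np.minimum(grid + w2, t_stop)
    counts = (np.searchsorted(events.times, hi, side="right")
              - np.searchsorted(events.times, lo, side="left"))
    widths = hi - lo
    values = counts / widths
    return RateSeries(grid, values, kernel_width)


def kde_integral(events: EventList, start: float, end: float, kernel_width: float = 0.5) -> float:
    """Exact integral of the (untruncated) boxcar KDE over ``[start, end]``.

    Each event contributes the overlap of its kernel support
    ``[t_i - w/2, t_i + w/2]`` with the interval, divided by w; over an
    interval containing every kernel support entirely this equals the event
    count (mass conservation).
    """
    if kernel_width <= 0:
        raise InvalidParameterError("kernel_width must be > 0")
    if end <= start:
        raise InvalidParameterError("end must exceed start")
    w2 = kernel_width / 2.0
    lo = np.maximum(events.times - w2, start)
    hi = np.minimum(events.times + w2, end)
    overlap = np.clip(hi - lo, 0.0, None)
    return float(overlap.sum() / kernel_width)


def normalize_rate(series: RateSeries, mode: str, stim_onset: float) -> RateSeries:
    """Divide a rate series by its pre-stimulus baseline mean.

    ``mode='single_shot'`` uses the 5 s before ``stim_onset``;
    ``mode='repetitive'`` uses the 5 min (300 s) before ``stim_onset``.
    The baseline mean of the output equals 1 by construction.
    """
    if mode not in NORMALIZATION_BASELINES:
        raise InvalidParameterError(f"mode must be one of {sorted(NORMALIZATION_BASELINES)}")
    span = NORMALIZATION_BASELINES[mode]
    b0, b1 = stim_onset - span, stim_onset
    eps = series.grid_step / 2 + 1e-12
    if b0 < series.times[0] - eps or b1 > series.times[-1] + eps:
        raise RangeError(f"baseline window [{b0}, {b1}] s not contained in the series")
    baseline_mean = series.mean_in(b0, b1)
    if baseline_mean == 0.0:
        raise DegenerateBaselineError("baseline mean rate is zero; normalization undefined")
    return RateSeries(series.times.copy(), series.values / baseline_mean,
                      series.kernel_width, normalized=True, baseline_window=(b0, b1))


def interval_mean_frequency(
    events: EventList,
    windows: Sequence[Tuple[str, float, float]],
) -> List[IntervalSummary]:
    """Mean event frequency (count / length) per labelled window."""
    out = []
    for label, start, end in windows:
        if end <= start:
            raise InvalidParameterError(f"zero-length or inverted window {label!r}")
        out.append(IntervalSummary(label, (start, end),
                                   events.count_in(start, end) / (end - start)))
    return out
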