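"""Event detection and recording quality control.

Miniature postsynaptic currents are found as threshold crossings of a
baseline-subtracted voltage-clamp trace: the baseline is a running median
(window 200 ms, slow drift only), the noise scale is a median-absolute-
deviation estimate on the first-difference residual (insensitive to event
contamination), and peaks beyond ``psc_threshold_sd`` times that scale in the
configured polarity are reported with peak-to-local-baseline amplitudes.

Action potentials in current clamp are one event per upward crossing of
``spike_threshold`` with refractory enforcement; the reported time is the
peak of the suprathreshold excursion.

QC implements three recording-rejection rules: resting potential more
positive than −60 mV, a steep sustained stimulation-epoch depolarization
beyond −50 mV, and series resistance outside 8–25 MOhm.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import (
    BiexpKernel,
    ClampMode,
    ConfigurationError,
    EventKind,
    EventList,
    EventSource,
    InvalidParameterError,
    Trace,
    WrongClampModeError,
)

__all__ = ["DetectorConfig", "QCReason", "QCResult", "QCLimits",
           "detect_psc_events", "detect_spikes", "qc_trace",
           "running_median", "robust_noise_sd"]


@dataclass(frozen=True)
class DetectorConfig:
    """Parameters for PSC and spike detection."""

    psc_threshold_sd: float = 5.0
    min_event_separation_ms: float = 5.0
    baseline_window_ms: float = 200.0
    smooth_ms: float = 1.0               # boxcar pre-smoothing; <0.4% peak loss for ~1 ms rise
    polarity: str = "negative"           # inward PSCs at -70 mV holding
    template: Optional[BiexpKernel] = None
    spike_threshold_mv: float = 0.0
    spike_refractory_ms: float = 2.0

    def __post_init__(self):
        if self.psc_threshold_sd <= 0 or self.min_event_separation_ms <= 0:
            raise InvalidParameterError("thresholds and separations must be > 0")
        if self.spike_refractory_ms <= 0:
            raise InvalidParameterError("refractory must be > 0")
        if self.polarity not in ("negative", "positive"):
            raise InvalidParameterError("polarity must be 'negative' or 'positive'")


class QCReason(str, enum.Enum):
    OK = "ok"
    DEPOLARIZED_BASELINE = "depolarized_baseline"
    STIM_DEPOLARIZATION = "stim_depolarization"
    SERIES_RESISTANCE_OUT_OF_RANGE = "series_resistance_out_of_range"


@dataclass(frozen=True)
class QCResult:
    accepted: bool
    reason: QCReason

    def __post_init__(self):
        if self.accepted != (self.reason == QCReason.OK):
            raise InvalidParameterError("reason must be 'ok' iff accepted")


@dataclass(frozen=True)
class QCLimits:
    """Recording acceptance limits.

    ``steepness_mv_per_s``/``sustain_s`` operationalize a "steep change":
    rejection requires the smoothed potential to exceed ``stim_max_mv`` for
    longer than ``sustain_s`` during the stimulation epoch after rising
    faster than ``steepness_mv_per_s``.
    """

    baseline_max_mv: float = -60.0
    stim_max_mv: float = -50.0
    rs_range_mohm: Tuple[float, float] = (8.0, 25.0)
    steepness_mv_per_s: float = 2.0
    sustain_s: float = 1.0
    smooth_s: float = 1.0


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def running_median(x: np.ndarray, window_samples: int, *, decimate_above: int = 50_000) -> np.ndarray:
    """Centered running median; computed on a decimated grid for long traces."""
    window_samples = max(int(window_samples) | 1, 1)
    if x.size > decimate_above and window_samples >= 20:
        step = max(window_samples // 20, 1)
        coarse = pd.Series(x[::step]).rolling(
            max(window_samples // step, 1) | 1, center=True, min_periods=1).median().to_numpy()
        idx = np.arange(x.size) / step
        return np.interp(idx, np.arange(coarse.size), coarse)
    return pd.Series(x).rolling(window_samples, center=True, min_periods=1).median().to_numpy()


def robust_noise_sd(x: np.ndarray) -> float:
    """Noise SD from the MAD of the first difference (event-insensitive).

    For white Gaussian noise, ``diff(x)`` has SD ``sqrt(2)`` times the noise
    SD and the MAD-to-SD factor is 1/0.6745.
    """
    d = np.diff(x)
    if d.size == 0:
        return 0.0
    return float(np.median(np.abs(d - np.median(d))) / (0.6745 * math.sqrt(2.0)))


# ---------------------------------------------------------------------------
# PSC detection
# ---------------------------------------------------------------------------

def detect_psc_events(trace: Trace, config: DetectorConfig = DetectorConfig(),
                      kind: EventKind = EventKind.MIPSC) -> EventList:
    """Detect miniature postsynaptic currents in a voltage-clamp trace."""
    if trace.clamp_mode is not ClampMode.VOLTAGE_CLAMP:
        raise WrongClampModeError("PSC detection requires a voltage-clamp trace")
    fs = trace.sampling_rate
    baseline = running_median(trace.samples, int(round(config.baseline_window_ms * 1e-3 * fs)))
    residual = trace.samples - baseline
    sd = robust_noise_sd(residual)
    y = -residual if config.polarity == "negative" else residual
    w = max(int(round(config.smooth_ms * 1e-3 * fs)), 1)
    if w > 1:
        y = np.convolve(y, np.ones(w) / w, mode="same")
    if sd == 0.0:
        # noise-free trace: any finite deflection is an event
        height = 0.5 * y.max() if y.max() > 0 else np.inf
    else:
        height = config.psc_threshold_sd * sd
    distance = max(int(round(config.min_event_separation_ms * 1e-3 * fs)), 1)
    # prominence filters secondary wiggles riding on an event's decay
    peaks, _ = find_peaks(y, height=height, distance=distance, prominence=height)
    amps = y[peaks]

    if config.template is not None:
        # localize on the steep rising edge (half-maximum crossing), which is
        # far less noise-sensitive than the flat peak, then shift by the
        # template's onset-to-half-rise latency to report event onsets
        times = np.empty(peaks.size)
        for i, (p, a) in enumerate(zip(peaks, amps)):
            half = a / 2.0
            q = p
            while q > 0 and y[q - 1] >= half:
                q -= 1
            if q > 0 and y[q] > y[q - 1]:
                frac = (y[q] - half) / (y[q] - y[q - 1])
            else:
                frac = 0.0
            times[i] = (q - frac) / fs - config.template.half_rise_time
        times += trace.start_time
    else:
        times = trace.start_time + peaks / fs

    order = np.argsort(times)
    times, amps = times[order], amps[order]
    if times.size:
        keep = np.concatenate([[True], np.diff(times) > 0])
        times, amps = times[keep], amps[keep]
    return EventList(kind, times, amps, EventSource.DETECTED)


# ---------------------------------------------------------------------------
# Spike detection
# ---------------------------------------------------------------------------

def detect_spikes(trace: Trace, config: DetectorConfig = DetectorConfig()) -> EventList:
    """Detect action potentials as threshold upcrossings with refractoriness."""
    if trace.clamp_mode is not ClampMode.CURRENT_CLAMP:
        raise WrongClampModeError("spike detection requires a current-clamp trace")
    v = trace.samples
    fs = trace.sampling_rate
    th = config.spike_threshold_mv
    above = v >= th
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if crossings.size == 0:
        return EventList(EventKind.SPIKE, np.empty(0), None, EventSource.DETECTED)

    refr = config.spike_refractory_ms * 1e-3 * fs
    peak_times = []
    last = -np.inf
    # ends of suprathreshold runs, for peak localization
    run_ends = np.flatnonzero(above[:-1] & ~above[1:]) + 1
    for c in crossings:
        if c - last < refr:
            continue
        last = c
        e_idx = run_ends.searchsorted(c)
        end = run_ends[e_idx] if e_idx < run_ends.size else v.size
        peak = c + int(np.argmax(v[c:end]))
        peak_times.append(trace.start_time + peak / fs)
    times = np.unique(np.asarray(peak_times))
    return EventList(EventKind.SPIKE, times, None, EventSource.DETECTED)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_trace(
    trace: Trace,
    stim_epoch: Optional[Tuple[float, float]] = None,
    limits: QCLimits = QCLimits(),
    *,
    require_stim_rule: bool = False,
) -> QCResult:
    """Apply the recording-rejection rules.

    Membrane-potential rules apply to current-clamp traces; the series-
    resistance rule applies whenever ``series_resistance_mohm`` is present in
    ``channel_meta``.  With ``require_stim_rule`` set, a missing
    ``stim_epoch`` is a configuration error rather than a silent skip.
    """
    if require_stim_rule and stim_epoch is None:
        raise ConfigurationError("stimulation-epoch rule requested but no stim_epoch given")

    if trace.clamp_mode is ClampMode.CURRENT_CLAMP:
        fs = trace.sampling_rate
        smooth = running_median(trace.samples, int(round(limits.smooth_s * fs)))
        t = trace.times
        out_of_epoch = np.ones(t.size, dtype=bool)
        if stim_epoch is not None:
            out_of_epoch = (t < stim_epoch[0]) | (t >= stim_epoch[1])
        baseline_v = float(np.median(smooth[out_of_epoch])) if out_of_epoch.any() else float(np.median(smooth))
        if baseline_v > limits.baseline_max_mv:
            return QCResult(False, QCReason.DEPOLARIZED_BASELINE)

        if stim_epoch is not None:
            in_epoch = ~out_of_epoch
            if in_epoch.any():
                ve = smooth[in_epoch]
                above = ve > limits.stim_max_mv
                # longest sustained run above the stim limit
                run = best = 0
                for a in above:
                    run = run + 1 if a else 0
                    best = max(best, run)
                sustained = best / fs > limits.sustain_s
                # depolarization rate on a 1-s scale
                k = max(int(round(1.0 * fs)), 1)
                if ve.size > k:
                    slope = np.max(ve[k:] - ve[:-k])  # mV per 1 s
                else:
                    slope = ve.max() - ve.min()
                if sustained and slope > limits.steepness_mv_per_s:
                    return QCResult(False, QCReason.STIM_DEPOLARIZATION)

    rs = trace.channel_meta.get("series_resistance_mohm")
    if rs is not None and not (limits.rs_range_mohm[0] <= float(rs) <= limits.rs_range_mohm[1]):
        return QCResult(False, QCReason.SERIES_RESISTANCE_OUT_OF_RANGE)

    return QCResult(True, QCReason.OK)
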