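"""Core domain types shared across the pipeline.

Sign conventions
----------------
Voltage-clamp traces are membrane currents in pA recorded at a fixed holding
potential (−70 mV in the experiments this package models).  Inward synaptic
currents (mEPSCs, mIPSCs with a high-chloride pipette) appear as *negative*
deflections; event amplitudes are stored as positive magnitudes with the
polarity carried by the event kind and detector configuration.  Current-clamp
traces are membrane potentials in mV.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np


# ---------------------------------------------------------------------------
# Exceptions
# ---------------------------------------------------------------------------

class SonophysError(Exception):
    """Base class for package errors."""


class InvalidParameterError(SonophysError, ValueError):
    """A parameter violates a documented precondition."""


class WrongClampModeError(SonophysError, ValueError):
    """An operation received a trace recorded in the wrong clamp mode."""


class ConfigurationError(SonophysError, ValueError):
    """Inconsistent or incomplete analysis configuration."""


class RangeError(SonophysError, ValueError):
    """A requested window or coordinate lies outside the data."""


class DegenerateBaselineError(SonophysError, ValueError):
    """Normalization baseline has zero mean; a ratio would be undefined."""


class EstimationError(SonophysError, RuntimeError):
    """A fit failed to converge or its preconditions were not met.

    Carries a ``diagnostics`` dict describing the failure context.
    """

    def __init__(self, message: str, diagnostics: Optional[dict] = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class UnsupportedSizeError(SonophysError, ValueError):
    """Sample size outside the supported range of a statistical routine."""


class UnitMismatchError(SonophysError, ValueError):
    """File units are inconsistent with the declared clamp mode."""


class AliasingError(SonophysError, ValueError):
    """Sampling rate too low for the requested carrier frequency."""


class OverlappingBurstError(SonophysError, ValueError):
    """Tone-burst duration times PRF exceeds one (bursts would overlap)."""


class EmptyPulseError(SonophysError, ValueError):
    """No pulse could be located in a pressure waveform."""


class OutOfExtentError(SonophysError, ValueError):
    """Half-maximum crossing not bracketed within the scanned grid."""


# ---------------------------------------------------------------------------
# Enums
# ---------------------------------------------------------------------------

class ClampMode(str, enum.Enum):
    VOLTAGE_CLAMP = "voltage_clamp"
    CURRENT_CLAMP = "current_clamp"


class EventKind(str, enum.Enum):
    MEPSC = "mEPSC"
    MIPSC = "mIPSC"
    SPIKE = "spike"


class EventSource(str, enum.Enum):
    GROUND_TRUTH = "ground_truth"
    DETECTED = "detected"


#: canonical units per clamp mode
UNITS = {ClampMode.VOLTAGE_CLAMP: "pA", ClampMode.CURRENT_CLAMP: "mV"}


# ---------------------------------------------------------------------------
# Trace
# ---------------------------------------------------------------------------

@dataclass
class Trace:
    """A uniformly sampled clamp signal.

    Parameters
    ----------
    samples : ndarray
        Signal values — pA under voltage clamp, mV under current clamp.
    sampling_rate : float
        Samples per second (Hz), strictly positive.
    clamp_mode : ClampMode
    start_time : float
        Time of the first sample, seconds.
    channel_meta : dict
        Free-form recording metadata (e.g. ``holding_potential_mv``,
        ``series_resistance_mohm``, ``temperature_c``).
    """

    samples: np.ndarray
    sampling_rate: float
    clamp_mode: ClampMode
    start_time: float = 0.0
    channel_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.clamp_mode = ClampMode(self.clamp_mode)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise InvalidParameterError("trace samples must be a non-empty 1-D array")
        if not (self.sampling_rate > 0):
            raise InvalidParameterError("sampling_rate must be > 0")

    @property
    def units(self) -> str:
        return UNITS[self.clamp_mode]

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate

    def index_at(self, t: float) -> int:
        """Nearest sample index at time ``t`` (clipped to the trace)."""
        i = int(round((t - self.start_time) * self.sampling_rate))
        return min(max(i, 0), self.n_samples - 1)

    def slice_window(self, start: float, end: float) -> np.ndarray:
        """Samples with times in ``[start, end)``; errors if outside the trace."""
        if end <= start:
            raise InvalidParameterError("window end must exceed start")
        if start < self.start_time - 0.5 / self.sampling_rate or end > self.end_time + 0.5 / self.sampling_rate:
            raise RangeError(
                f"window [{start}, {end}] s outside trace "
                f"[{self.start_time}, {self.end_time}] s"
            )
        i0 = int(np.ceil((start - self.start_time) * self.sampling_rate - 1e-9))
        i1 = int(np.ceil((end - self.start_time) * self.sampling_rate - 1e-9))
        return self.samples[max(i0, 0):min(i1, self.n_samples)]


# ---------------------------------------------------------------------------
# EventList
# ---------------------------------------------------------------------------

@dataclass
class EventList:
    """Detected or ground-truth event times with optional amplitudes."""

    kind: EventKind
    times: np.ndarray
    amplitudes: Optional[np.ndarray] = None
    source: EventSource = EventSource.GROUND_TRUTH

    def __post_init__(self):
        self.kind = EventKind(self.kind)
        self.source = EventSource(self.source)
        self.times = np.asarray(self.times, dtype=np.float64).ravel()
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise InvalidParameterError("event times must be strictly increasing")
        if self.amplitudes is not None:
            self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64).ravel()
            if self.amplitudes.size != self.times.size:
                raise InvalidParameterError("amplitudes must match times in length")
            if self.amplitudes.size and not np.all(self.amplitudes > 0):
                raise InvalidParameterError("amplitudes must be positive magnitudes")

    def __len__(self) -> int:
        return int(self.times.size)

    def shifted(self, dt: float) -> "EventList":
        return EventList(self.kind, self.times + dt, None if self.amplitudes is None else self.amplitudes.copy(), self.source)

    def count_in(self, start: float, end: float) -> int:
        return int(np.searchsorted(self.times, end, side="right")
                   - np.searchsorted(self.times, start, side="left"))


@dataclass
class GroundTruth:
    """Simulator truth record accompanying a synthetic trace."""

    events: EventList
    tonic_step_pa: float = 0.0
    tonic_step_time: Optional[float] = None
    suppression_ratio: float = 1.0
    suppression_onset: Optional[float] = None

    def __post_init__(self):
        if not (0 < self.suppression_ratio <= 1):
            raise InvalidParameterError("suppression_ratio must be in (0, 1]")


# ---------------------------------------------------------------------------
# Biexponential kernel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiexpKernel:
    """Difference-of-exponentials synaptic kernel, peak-normalized to 1.

    ``k(t) = (exp(-t/tau_decay) - exp(-t/tau_rise)) / k_max`` for t >= 0, so a
    transient of drawn amplitude A peaks at exactly A.  The peak occurs at
    ``t* = tau_rise*tau_decay/(tau_decay-tau_rise) * ln(tau_decay/tau_rise)``.
    """

    tau_rise: float = 0.001
    tau_decay: float = 0.015

    def __post_init__(self):
        if not (0 < self.tau_rise < self.tau_decay):
            raise InvalidParameterError("require 0 < tau_rise < tau_decay")

    @property
    def peak_time(self) -> float:
        tr, td = self.tau_rise, self.tau_decay
        return tr * td / (td - tr) * math.log(td / tr)

    def _raw(self, t: np.ndarray) -> np.ndarray:
        out = np.exp(-t / self.tau_decay) - np.exp(-t / self.tau_rise)
        out[t < 0] = 0.0
        return out

    @property
    def half_rise_time(self) -> float:
        """Time from onset to half of the peak on the rising edge."""
        t = np.linspace(0.0, self.peak_time, 2049)
        k = self._raw(t)
        k /= k[-1]
        return float(np.interp(0.5, k, t))

    def sample(self, sampling_rate: float, n_decay: float = 8.0) -> np.ndarray:
        """Kernel sampled on the trace grid, truncated at ``n_decay`` decay times."""
        n = max(int(round(n_decay * self.tau_decay * sampling_rate)), 2)
        t = np.arange(n) / sampling_rate
        peak = self._raw(np.array([self.peak_time]))[0]
        return self._raw(t) / peak
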