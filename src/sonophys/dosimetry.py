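"""Ultrasound stimulation protocols and acoustic exposure metrics.

Implements the standard free-field dosimetry quantities for gated-sinusoid
(tone-burst) stimulation:

* duty cycle ``DC = TBD x PRF`` (pulsed wave) or 1 (continuous wave),
* pulse intensity integral ``PII = \\int p^2/(rho c) dt`` over one pulse,
* spatial-peak pulse-average intensity ``I_SPPA = PII / TBD``,
* spatial-peak temporal-average intensity ``I_SPTA = PII x PRF``,
* full width at half maximum of a hydrophone beam-profile scan.

For a rectangular-gated sinusoid of peak pressure p0 the closed form is
``PII = p0^2 TBD / (2 rho c)``, so ``I_SPTA = I_SPPA x DC`` holds exactly.

Unit conventions: pressures in Pa (maps in kPa), PII reported in mJ/cm^2,
I_SPPA in W/cm^2, I_SPTA in mW/cm^2 — the units the field prints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .core import (
    AliasingError,
    ClampMode,
    EmptyPulseError,
    InvalidParameterError,
    OutOfExtentError,
    OverlappingBurstError,
    Trace,
)

__all__ = [
    "Medium",
    "WATER",
    "StimProtocol",
    "IntensityMetrics",
    "PressureMap",
    "protocol_metrics",
    "synthesize_pressure_waveform",
    "intensity_metrics",
    "metrics_from_pii",
    "fwhm_from_map",
]

W_PER_M2_TO_W_PER_CM2 = 1e-4
J_PER_M2_TO_MJ_PER_CM2 = 1e-4 * 1e3


@dataclass(frozen=True)
class Medium:
    """Acoustic propagation medium."""

    density: float = 998.0        # kg/m^3
    sound_speed: float = 1482.0   # m/s

    def __post_init__(self):
        if self.density <= 0 or self.sound_speed <= 0:
            raise InvalidParameterError("medium parameters must be > 0")

    @property
    def impedance(self) -> float:
        return self.density * self.sound_speed


#: degassed water at 25 degC
WATER = Medium()


@dataclass(frozen=True)
class StimProtocol:
    """PW/CW ultrasound stimulation protocol.

    The default is the pulsed-wave protocol used throughout the modeled
    experiments: 5 MHz carrier, 0.5 ms tone bursts at 100 Hz PRF (5% duty
    cycle), 2-s trains, 100 kPa peak pressure.
    """

    carrier_frequency: float = 5e6
    mode: str = "PW"
    tone_burst_duration: Optional[float] = 0.5e-3
    prf: Optional[float] = 100.0
    train_duration: float = 2.0
    n_trains: int = 1
    inter_train_onset_interval: float = 0.0
    peak_pressure: float = 100e3

    def __post_init__(self):
        if self.mode not in ("PW", "CW"):
            raise InvalidParameterError("mode must be 'PW' or 'CW'")
        if self.carrier_frequency <= 0 or self.train_duration <= 0:
            raise InvalidParameterError("carrier frequency and train duration must be > 0")
        if self.n_trains < 1:
            raise InvalidParameterError("n_trains must be >= 1")
        if self.n_trains > 1 and self.inter_train_onset_interval < self.train_duration:
            raise InvalidParameterError("inter-train onset interval must cover one train")
        if self.mode == "PW":
            if not self.tone_burst_duration or not self.prf:
                raise InvalidParameterError("PW mode requires tone_burst_duration and prf")
            if self.tone_burst_duration * self.prf > 1.0 + 1e-12:
                raise OverlappingBurstError(
                    f"TBD x PRF = {self.tone_burst_duration * self.prf:.3g} > 1: bursts overlap"
                )

    @property
    def duty_cycle(self) -> float:
        if self.mode == "CW":
            return 1.0
        return self.tone_burst_duration * self.prf

    @property
    def pulse_duration(self) -> float:
        return self.train_duration if self.mode == "CW" else self.tone_burst_duration

    @property
    def pulses_per_train(self) -> int:
        if self.mode == "CW":
            return 1
        return int(round(self.train_duration * self.prf))

    @property
    def total_protocol_duration(self) -> float:
        return (self.n_trains - 1) * self.inter_train_onset_interval + self.train_duration


@dataclass
class IntensityMetrics:
    """Timing and exposure metrics for one protocol.

    Intensity fields are ``None`` when only timing was requested.
    """

    duty_cycle: float
    pulse_count: int
    total_protocol_duration: float
    pii_mj_cm2: Optional[float] = None
    i_sppa_w_cm2: Optional[float] = None
    i_spta_mw_cm2: Optional[float] = None
    medium: Medium = field(default_factory=lambda: WATER)

    def as_dict(self) -> dict:
        d = {
            "duty_cycle_pct": 100.0 * self.duty_cycle,
            "pulses_per_train": self.pulse_count,
            "total_protocol_duration_s": self.total_protocol_duration,
        }
        if self.pii_mj_cm2 is not None:
            d.update({
                "pii_mj_cm2": self.pii_mj_cm2,
                "i_sppa_w_cm2": self.i_sppa_w_cm2,
                "i_spta_mw_cm2": self.i_spta_mw_cm2,
            })
        return d


@dataclass
class PressureMap:
    """Rectangular 2-D grid of peak pressures from a raster scan."""

    axis1_mm: np.ndarray
    axis2_mm: np.ndarray
    values_kpa: np.ndarray
    plane: str = "XY"

    def __post_init__(self):
        self.axis1_mm = np.asarray(self.axis1_mm, dtype=np.float64)
        self.axis2_mm = np.asarray(self.axis2_mm, dtype=np.float64)
        self.values_kpa = np.asarray(self.values_kpa, dtype=np.float64)
        if self.values_kpa.shape != (self.axis1_mm.size, self.axis2_mm.size):
            raise InvalidParameterError("values shape must match axis lengths")
        if self.values_kpa.size and self.values_kpa.min() < 0:
            raise InvalidParameterError("pressure magnitudes must be >= 0")
        if self.plane not in ("XY", "XZ"):
            raise InvalidParameterError("plane must be 'XY' or 'XZ'")

    @property
    def peak_kpa(self) -> float:
        return float(self.values_kpa.max())


# ---------------------------------------------------------------------------

def protocol_metrics(protocol: StimProtocol) -> IntensityMetrics:
    """Timing-only metrics: duty cycle, pulses per train, total duration."""
    return IntensityMetrics(
        duty_cycle=protocol.duty_cycle,
        pulse_count=protocol.pulses_per_train,
        total_protocol_duration=protocol.total_protocol_duration,
    )


def synthesize_pressure_waveform(protocol: StimProtocol, sampling_rate: float) -> Trace:
    """Rectangular-gated sinusoid realizing the burst/train schedule.

    Returned as a voltage-clamp-mode :class:`Trace` whose samples are pressure
    in Pa (``channel_meta['units'] = 'Pa'``).
    """
    if sampling_rate < 10 * protocol.carrier_frequency:
        raise AliasingError(
            f"sampling rate {sampling_rate:g} Hz < 10 x carrier {protocol.carrier_frequency:g} Hz"
        )
    n = int(round(protocol.total_protocol_duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    carrier = protocol.peak_pressure * np.sin(2 * np.pi * protocol.carrier_frequency * t)

    gate = np.zeros(n, dtype=bool)
    for k in range(protocol.n_trains):
        t0 = k * protocol.inter_train_onset_interval
        if protocol.mode == "CW":
            gate |= (t >= t0) & (t < t0 + protocol.train_duration)
        else:
            tt = t - t0
            in_train = (tt >= 0) & (tt < protocol.train_duration)
            phase = np.mod(tt[in_train], 1.0 / protocol.prf)
            sub = np.zeros(n, dtype=bool)
            sub[in_train] = phase < protocol.tone_burst_duration
            gate |= sub
    trace = Trace(np.where(gate, carrier, 0.0), sampling_rate, ClampMode.VOLTAGE_CLAMP,
                  channel_meta={"units": "Pa", "signal": "pressure"})
    return trace


def _first_pulse(pressure: Trace, protocol: StimProtocol) -> np.ndarray:
    """Samples of the first gated pulse, located from the rectified envelope."""
    p = np.abs(pressure.samples)
    if p.max() <= 0:
        raise EmptyPulseError("waveform contains no pulse (all zeros)")
    # envelope by moving max over ~1.5 carrier cycles
    w = max(int(round(1.5 * pressure.sampling_rate / protocol.carrier_frequency)), 1)
    nwin = p.size // w
    coarse = p[: nwin * w].reshape(nwin, w).max(axis=1)
    on = coarse > 0.05 * coarse.max()
    start = int(np.argmax(on))
    stop = start
    while stop < nwin and on[stop]:
        stop += 1
    return pressure.samples[start * w: stop * w]


def intensity_metrics(
    protocol: StimProtocol,
    *,
    medium: Medium = WATER,
    pressure: Optional[Trace] = None,
    sampling_rate: Optional[float] = None,
) -> IntensityMetrics:
    """Full exposure metrics from a measured/synthesized waveform or closed form.

    With ``pressure`` given, PII is the trapezoidal integral of
    ``p^2/(rho c)`` over the first located pulse; otherwise the rectangular
    gated-sinusoid closed form ``p0^2 TBD / (2 rho c)`` is used.
    """
    timing = protocol_metrics(protocol)
    if pressure is not None:
        pulse = _first_pulse(pressure, protocol)
        if pulse.size < 2:
            raise EmptyPulseError("located pulse too short to integrate")
        dt = 1.0 / pressure.sampling_rate
        pii_si = np.trapezoid(pulse**2, dx=dt) / medium.impedance  # J/m^2
    else:
        pii_si = protocol.peak_pressure**2 * protocol.pulse_duration / (2.0 * medium.impedance)

    i_sppa_si = pii_si / protocol.pulse_duration                  # W/m^2
    if protocol.mode == "CW":
        i_spta_si = i_sppa_si
    else:
        i_spta_si = pii_si * protocol.prf
    timing.pii_mj_cm2 = pii_si * J_PER_M2_TO_MJ_PER_CM2
    timing.i_sppa_w_cm2 = i_sppa_si * W_PER_M2_TO_W_PER_CM2
    timing.i_spta_mw_cm2 = i_spta_si * W_PER_M2_TO_W_PER_CM2 * 1e3
    timing.medium = medium
    return timing


def metrics_from_pii(pii_mj_cm2: float, protocol: StimProtocol) -> IntensityMetrics:
    """Exposure metrics from a stated pulse intensity integral (mJ/cm^2).

    ``I_SPPA = PII / TBD`` (W/cm^2) and ``I_SPTA = PII x PRF`` (mW/cm^2);
    useful when the PII was measured with a hydrophone rather than derived
    from an idealized waveform.
    """
    if pii_mj_cm2 <= 0:
        raise InvalidParameterError("PII must be > 0")
    timing = protocol_metrics(protocol)
    pii_j_cm2 = pii_mj_cm2 * 1e-3
    timing.pii_mj_cm2 = pii_mj_cm2
    timing.i_sppa_w_cm2 = pii_j_cm2 / protocol.pulse_duration
    if protocol.mode == "CW":
        timing.i_spta_mw_cm2 = timing.i_sppa_w_cm2 * 1e3
    else:
        timing.i_spta_mw_cm2 = pii_mj_cm2 * protocol.prf
    return timing


# ---------------------------------------------------------------------------

def fwhm_from_map(pmap: PressureMap, axis: str = "axis1") -> float:
    """Full width at half maximum along one axis through the map peak.

    Half-maximum crossings are located by linear interpolation on the profile
    through the (unique) peak; the returned separation is in mm.
    """
    v = pmap.values_kpa
    vmax = v.max()
    if vmax <= v.min():
        raise OutOfExtentError("flat map: no half-maximum crossing exists")
    i, j = np.unravel_index(int(np.argmax(v)), v.shape)
    if axis == "axis1":
        coords, profile = pmap.axis1_mm, v[:, j]
        peak_idx = i
    elif axis == "axis2":
        coords, profile = pmap.axis2_mm, v[i, :]
        peak_idx = j
    else:
        raise InvalidParameterError("axis must be 'axis1' or 'axis2'")

    half = vmax / 2.0

    def _cross(direction: int) -> float:
        k = peak_idx
        while 0 <= k + direction < profile.size and profile[k + direction] >= half:
            k += direction
        k2 = k + direction
        if k2 < 0 or k2 >= profile.size:
            raise OutOfExtentError("half-maximum not bracketed within the grid")
        # linear interpolation between profile[k] (>= half) and profile[k2] (< half)
        f = (profile[k] - half) / (profile[k] - profile[k2])
        return float(coords[k] + f * (coords[k2] - coords[k]))

    return abs(_cross(+1) - _cross(-1))
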