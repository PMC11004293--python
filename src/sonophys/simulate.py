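"""Synthetic electrophysiology and hydrophone-scan generators with ground truth.

Every generator takes an integer seed and is bit-reproducible: one
``numpy.random.SeedSequence`` per call is split deterministically into
independent sub-streams per stochastic component (event times, amplitudes,
noise), so changing e.g. the noise level does not perturb the event placement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np
from scipy.signal import fftconvolve

from .core import (
    BiexpKernel,
    ClampMode,
    EventKind,
    EventList,
    EventSource,
    GroundTruth,
    InvalidParameterError,
    Trace,
)
from .dosimetry import PressureMap

__all__ = [
    "AmplitudeDistribution",
    "simulate_vc_trace",
    "simulate_cc_trace",
    "simulate_pressure_map",
    "simulate_tonic_block_experiment",
]


@dataclass(frozen=True)
class AmplitudeDistribution:
    """Log-normal miniature-event amplitude distribution (positive pA).

    Defaults (median 30 pA, sigma_log 0.35) are conventional for cultured
    hippocampal miniature PSCs; the source recordings do not constrain them.
    """

    median_pa: float = 30.0
    sigma_log: float = 0.35

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return np.exp(rng.normal(math.log(self.median_pa), self.sigma_log, size=n))


def _streams(seed: int, n: int):
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


# ---------------------------------------------------------------------------
# Voltage clamp
# ---------------------------------------------------------------------------

def simulate_vc_trace(
    duration: float,
    rate: float,
    *,
    kernel: BiexpKernel = BiexpKernel(),
    amplitude: AmplitudeDistribution = AmplitudeDistribution(),
    noise_sd: float = 3.0,
    baseline: float = -50.0,
    tonic_step: Optional[Tuple[float, float]] = None,
    event_window: Optional[Tuple[float, float]] = None,
    sampling_rate: float = 10_000.0,
    event_kind: EventKind = EventKind.MIPSC,
    polarity: int = -1,
    seed: int = 0,
) -> Tuple[Trace, GroundTruth]:
    """Simulate a voltage-clamp current trace with miniature PSCs.

    The trace is ``baseline + Gaussian noise + sum of biexponential event
    transients at homogeneous-Poisson times (+ step of dI after step time)``.
    Inward events (``polarity=-1``, the convention at −70 mV holding) deflect
    the current negative; truth amplitudes are positive magnitudes.

    Parameters
    ----------
    duration, rate : float
        Trace length (s) and Poisson event rate (Hz).
    tonic_step : (dI_pa, time_s), optional
        Holding-current step of ``dI_pa`` added from ``time_s`` onward —
        e.g. a positive step models a GABA_A blocker removing an inward
        tonic current.
    event_window : (t0, t1), optional
        Restrict events to this interval (default: the whole trace); used to
        model pharmacological abolition of miniature events.
    """
    if duration <= 0:
        raise InvalidParameterError("duration must be > 0")
    if sampling_rate <= 0:
        raise InvalidParameterError("sampling_rate must be > 0")
    if rate < 0:
        raise InvalidParameterError("rate must be >= 0")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")

    rng_times, rng_amps, rng_noise = _streams(seed, 3)
    n = int(round(duration * sampling_rate))
    samples = np.full(n, float(baseline))

    if event_window is None:
        event_window = (0.0, duration)
    w0, w1 = event_window
    w0, w1 = max(w0, 0.0), min(w1, duration)

    times = np.empty(0)
    amps = np.empty(0)
    if rate > 0 and w1 > w0:
        n_ev = rng_times.poisson(rate * (w1 - w0))
        times = np.sort(rng_times.uniform(w0, w1, size=n_ev))
        # strictly-increasing guarantee for the EventList invariant
        times = np.unique(times)
        amps = amplitude.draw(rng_amps, times.size)
        if times.size:
            k = kernel.sample(sampling_rate)
            impulses = np.zeros(n)
            idx = np.minimum((times * sampling_rate).round().astype(int), n - 1)
            np.add.at(impulses, idx, polarity * amps)
            samples += fftconvolve(impulses, k)[:n]

    step_pa, step_time = 0.0, None
    if tonic_step is not None:
        step_pa, step_time = float(tonic_step[0]), float(tonic_step[1])
        if not (0 <= step_time <= duration):
            raise InvalidParameterError("tonic step time must lie inside the trace")
        samples[int(round(step_time * sampling_rate)):] += step_pa

    if noise_sd > 0:
        samples = samples + rng_noise.normal(0.0, noise_sd, size=n)

    trace = Trace(samples, sampling_rate, ClampMode.VOLTAGE_CLAMP,
                  channel_meta={"holding_potential_mv": -70.0})
    truth = GroundTruth(
        events=EventList(event_kind, times, amps if times.size else np.empty(0),
                         EventSource.GROUND_TRUTH),
        tonic_step_pa=step_pa,
        tonic_step_time=step_time,
    )
    return trace, truth


def simulate_tonic_block_experiment(
    *,
    pre_duration: float = 10.0,
    post_duration: float = 10.0,
    tonic_amplitude_pa: float = 20.0,
    mipsc_rate: float = 10.0,
    noise_sd: float = 3.0,
    baseline: float = -80.0,
    kernel: BiexpKernel = BiexpKernel(),
    amplitude: AmplitudeDistribution = AmplitudeDistribution(),
    sampling_rate: float = 10_000.0,
    seed: int = 0,
) -> Tuple[Trace, GroundTruth]:
    """Simulate a GABA_A-blocker application experiment.

    Before the drug time (``pre_duration``) the cell carries an inward tonic
    current and miniature IPSCs at ``mipsc_rate``; the blocker abolishes both,
    stepping the holding current up by ``tonic_amplitude_pa`` (less negative)
    and silencing the events.  Ground truth records the step so the recovered
    tonic amplitude can be compared against ``tonic_amplitude_pa``.
    """
    duration = pre_duration + post_duration
    trace, truth = simulate_vc_trace(
        duration,
        mipsc_rate,
        kernel=kernel,
        amplitude=amplitude,
        noise_sd=noise_sd,
        baseline=baseline,
        tonic_step=(tonic_amplitude_pa, pre_duration),
        event_window=(0.0, pre_duration),
        sampling_rate=sampling_rate,
        seed=seed,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# Current clamp
# ---------------------------------------------------------------------------

SpikesPerBurst = Union[int, Tuple[str, float]]


def _burst_intensity(t: np.ndarray, rate: float, epoch, ratio: float, transition: str) -> np.ndarray:
    lam = np.full_like(t, rate, dtype=float)
    if epoch is None or ratio == 1.0:
        return lam
    onset, offset = epoch
    if transition == "step":
        lam[t >= onset] = rate * ratio
    else:  # linear ramp across the stimulation epoch
        ramp = (t >= onset) & (t < offset)
        frac = (t[ramp] - onset) / max(offset - onset, 1e-12)
        lam[ramp] = rate * (1 + frac * (ratio - 1))
        lam[t >= offset] = rate * ratio
    return lam


def simulate_cc_trace(
    duration: float,
    burst_rate: float,
    *,
    spikes_per_burst: SpikesPerBurst = ("poisson", 8.0),
    intraburst_isi: float = 0.02,
    resting_potential: float = -65.0,
    spike_amplitude: float = 100.0,
    spike_width: float = 0.002,
    stim_epoch: Optional[Tuple[float, float]] = None,
    suppression_ratio: float = 1.0,
    transition: str = "ramp",
    noise_sd: float = 1.0,
    sampling_rate: float = 2_000.0,
    seed: int = 0,
) -> Tuple[Trace, GroundTruth]:
    """Simulate recurrent burst firing whose rate drops after a stimulus epoch.

    Burst onsets follow an inhomogeneous Poisson process: rate ``burst_rate``
    before the epoch, ramping linearly (default) across the epoch to
    ``burst_rate * suppression_ratio``, constant thereafter.  Each burst holds
    a configurable number of stereotyped spikes (triangular template of
    ``spike_width`` and ``spike_amplitude`` from rest, crossing 0 mV).  Truth
    times are the rendered spike *peaks*, snapped to the sample grid, so a
    threshold detector can match them exactly on noise-free traces.
    """
    if duration <= 0 or sampling_rate <= 0:
        raise InvalidParameterError("duration and sampling_rate must be > 0")
    if not (0 < suppression_ratio <= 1):
        raise InvalidParameterError("suppression_ratio must be in (0, 1]")
    if burst_rate < 0:
        raise InvalidParameterError("burst_rate must be >= 0")
    if transition not in ("ramp", "step"):
        raise InvalidParameterError("transition must be 'ramp' or 'step'")

    rng_bursts, rng_counts, rng_noise = _streams(seed, 3)
    n = int(round(duration * sampling_rate))
    dt = 1.0 / sampling_rate
    v = np.full(n, float(resting_potential))

    spike_peaks: list[int] = []
    if burst_rate > 0:
        # thinning with lambda_max = burst_rate (suppression only reduces rate)
        n_cand = rng_bursts.poisson(burst_rate * duration)
        cand = np.sort(rng_bursts.uniform(0.0, duration, size=n_cand))
        lam = _burst_intensity(cand, burst_rate, stim_epoch, suppression_ratio, transition)
        keep = rng_bursts.uniform(0.0, burst_rate, size=n_cand) < lam
        burst_onsets = cand[keep]

        half_w = max(int(round(spike_width / 2 * sampling_rate)), 1)
        template = np.concatenate([
            np.linspace(0.0, 1.0, half_w + 1)[1:],
            np.linspace(1.0, 0.0, half_w + 1)[1:],
        ]) * spike_amplitude
        peak_local = half_w - 1  # index of the template maximum

        for onset in burst_onsets:
            if isinstance(spikes_per_burst, int):
                n_sp = spikes_per_burst
            else:
                dist, mean = spikes_per_burst
                if dist != "poisson":
                    raise InvalidParameterError(f"unknown spikes_per_burst distribution {dist!r}")
                n_sp = int(rng_counts.poisson(mean))
            for j in range(n_sp):
                peak_idx = int(round((onset + j * intraburst_isi) * sampling_rate)) + peak_local
                if peak_idx >= n:
                    break
                i0 = peak_idx - peak_local
                seg = template[max(-i0, 0):min(n - i0, template.size)]
                v[max(i0, 0):max(i0, 0) + seg.size] += seg
                spike_peaks.append(peak_idx)

    if noise_sd > 0:
        v = v + rng_noise.normal(0.0, noise_sd, size=n)

    peaks = np.unique(np.asarray(sorted(spike_peaks), dtype=int))
    truth_times = peaks * dt
    trace = Trace(v, sampling_rate, ClampMode.CURRENT_CLAMP,
                  channel_meta={"resting_potential_mv": float(resting_potential)})
    truth = GroundTruth(
        events=EventList(EventKind.SPIKE, truth_times, None, EventSource.GROUND_TRUTH),
        suppression_ratio=suppression_ratio,
        suppression_onset=None if stim_epoch is None else float(stim_epoch[0]),
    )
    return trace, truth


# ---------------------------------------------------------------------------
# Hydrophone raster scan
# ---------------------------------------------------------------------------

def simulate_pressure_map(
    *,
    extent_mm: Tuple[float, float] = (6.0, 6.0),
    step_mm: float = 0.1,
    peak_kpa: float = 150.0,
    fwhm_mm: float = 2.15,
    center_mm: Tuple[float, float] = (0.0, 0.0),
    noise_sd_kpa: float = 0.0,
    plane: str = "XY",
    seed: int = 0,
) -> PressureMap:
    """Simulate a 2-D hydrophone raster scan with a Gaussian focal profile.

    The noise-free map is ``peak * exp(-r^2 / (2 sigma^2))`` with
    ``sigma = fwhm / (2 sqrt(2 ln 2))``; measurement noise (hydrophone peak
    pressures are magnitudes) is clipped at zero.
    """
    if step_mm <= 0:
        raise InvalidParameterError("step_mm must be > 0")
    if fwhm_mm <= 0:
        raise InvalidParameterError("fwhm_mm must be > 0")
    if extent_mm[0] < step_mm or extent_mm[1] < step_mm:
        raise InvalidParameterError("extent must cover at least one step")

    def _axis(extent):
        half = math.floor(extent / 2 / step_mm)
        return np.arange(-half, half + 1) * step_mm

    ax1 = _axis(extent_mm[0]) + center_mm[0]
    ax2 = _axis(extent_mm[1]) + center_mm[1]
    sigma = fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    xx, yy = np.meshgrid(ax1 - center_mm[0], ax2 - center_mm[1], indexing="ij")
    values = peak_kpa * np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    if noise_sd_kpa > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        values = np.clip(values + rng.normal(0.0, noise_sd_kpa, size=values.shape), 0.0, None)
    return PressureMap(axis1_mm=ax1, axis2_mm=ax2, values_kpa=values, plane=plane)
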