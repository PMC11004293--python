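"""Detector truth-recovery, false-positive control, and QC rules."""

import numpy as np
import pytest

from sonophys import (
    DetectorConfig,
    QCReason,
    detect_psc_events,
    detect_spikes,
    qc_trace,
    simulate_cc_trace,
    simulate_vc_trace,
)
from sonophys.core import ClampMode, ConfigurationError, Trace, WrongClampModeError
from conftest import match_events


class TestPscDetection:
    def test_wrong_clamp_mode_raises(self):
        trace, _ = simulate_cc_trace(5.0, 0.0, seed=0)
        with pytest.raises(WrongClampModeError):
            detect_psc_events(trace)

    def test_noise_free_eventless_trace_yields_empty_list(self):
        trace, _ = simulate_vc_trace(10.0, 0.0, noise_sd=0.0, seed=0)
        assert len(detect_psc_events(trace)) == 0

    def test_injected_events_recovered_within_1ms(self, psc_detector):
        # ~50 events of median 30 pA in 2 pA noise
        trace, truth = simulate_vc_trace(100.0, 0.5, noise_sd=2.0, seed=5)
        detected = detect_psc_events(trace, psc_detector)
        pairs = match_events(truth.events.times, detected.times, tol=1e-3)
        assert len(pairs) >= len(truth.events) - 1

    def test_false_positive_rate_below_one_per_100s(self, psc_detector):
        n_fp = 0
        for seed in range(8):
            trace, _ = simulate_vc_trace(100.0, 0.0, noise_sd=2.0, seed=200 + seed)
            n_fp += len(detect_psc_events(trace, psc_detector))
        assert n_fp / 8 < 1.0

    def test_recall_precision_and_amplitude_bias_at_high_snr(self, psc_detector):
        # median 30 pA events in 3 pA noise (SNR 10), sparse enough that
        # sub-separation overlaps are rare
        recalls, precisions, biases = [], [], []
        for seed in (21, 22):
            trace, truth = simulate_vc_trace(200.0, 1.0, noise_sd=3.0, seed=seed)
            detected = detect_psc_events(trace, psc_detector)
            pairs = match_events(truth.events.times, detected.times, tol=2e-3)
            recalls.append(len(pairs) / len(truth.events))
            precisions.append(len(pairs) / len(detected))
            for t, a in zip(truth.events.times, truth.events.amplitudes):
                i = np.argmin(np.abs(detected.times - t))
                if abs(detected.times[i] - t) < 2e-3:
                    biases.append(detected.amplitudes[i] / a - 1.0)
        assert np.mean(recalls) >= 0.98
        assert np.mean(precisions) >= 0.98
        assert abs(np.mean(biases)) < 0.05

    def test_translation_equivariance(self, psc_detector):
        trace, _ = simulate_vc_trace(60.0, 1.0, noise_sd=2.0, seed=13)
        shifted = Trace(trace.samples.copy(), trace.sampling_rate,
                        trace.clamp_mode, start_time=trace.start_time + 12.5)
        a = detect_psc_events(trace, psc_detector)
        b = detect_psc_events(shifted, psc_detector)
        assert len(a) == len(b)
        assert np.allclose(b.times - a.times, 12.5)
        assert np.allclose(a.amplitudes, b.amplitudes)


class TestSpikeDetection:
    def test_wrong_clamp_mode_raises(self):
        trace, _ = simulate_vc_trace(5.0, 0.0, seed=0)
        with pytest.raises(WrongClampModeError):
            detect_spikes(trace)

    def test_noise_free_truth_recovered_exactly(self):
        # single-spike bursts: all truth spikes separated beyond the refractory
        trace, truth = simulate_cc_trace(400.0, 0.4, spikes_per_burst=1,
                                         noise_sd=0.0, seed=3)
        assert len(truth.events) > 120
        assert np.diff(truth.events.times).min() > 3e-3
        detected = detect_spikes(trace)
        assert len(detected) == len(truth.events)
        assert np.abs(detected.times - truth.events.times).max() <= 1.0 / trace.sampling_rate

    def test_flat_trace_yields_empty_list(self):
        trace = Trace(np.full(2000, -65.0), 1000.0, ClampMode.CURRENT_CLAMP)
        assert len(detect_spikes(trace)) == 0

    def test_refractory_merges_spikes_closer_than_refractory(self):
        # two 100-mV spikes 1 ms apart, refractory 2 ms -> one detection
        fs = 20_000.0
        v = np.full(int(0.1 * fs), -65.0)
        tri = np.concatenate([np.linspace(0, 100, 11), np.linspace(100, 0, 11)[1:]]) - 65.0
        for onset in (0.050, 0.051):
            i = int(onset * fs)
            v[i:i + tri.size] = np.maximum(v[i:i + tri.size], tri)
        trace = Trace(v, fs, ClampMode.CURRENT_CLAMP)
        assert len(detect_spikes(trace, DetectorConfig(spike_refractory_ms=2.0))) == 1


class TestQC:
    def _trace(self, v, fs=1000.0, meta=None):
        return Trace(np.asarray(v, float), fs, ClampMode.CURRENT_CLAMP,
                     channel_meta=meta or {})

    def test_depolarized_baseline_rejected(self):
        res = qc_trace(self._trace(np.full(30_000, -55.0)))
        assert not res.accepted and res.reason is QCReason.DEPOLARIZED_BASELINE

    def test_steep_stim_depolarization_rejected(self):
        fs = 1000.0
        t = np.arange(int(40 * fs)) / fs
        v = np.full(t.size, -70.0)
        # 5 mV/s ramp from t=10 s to -45 mV, held for 5 s inside the stim epoch
        ramp = (t >= 10.0) & (t < 15.0)
        v[ramp] = -70.0 + 5.0 * (t[ramp] - 10.0)
        v[(t >= 15.0) & (t < 20.0)] = -45.0
        v[t >= 20.0] = -70.0
        res = qc_trace(self._trace(v, fs), stim_epoch=(8.0, 21.0))
        assert not res.accepted and res.reason is QCReason.STIM_DEPOLARIZATION

    def test_good_recording_accepted(self):
        res = qc_trace(self._trace(np.full(30_000, -70.0),
                                   meta={"series_resistance_mohm": 15.0}),
                       stim_epoch=(10.0, 20.0))
        assert res.accepted and res.reason is QCReason.OK

    def test_series_resistance_out_of_range_rejected(self):
        res = qc_trace(self._trace(np.full(30_000, -70.0),
                                   meta={"series_resistance_mohm": 30.0}))
        assert not res.accepted
        assert res.reason is QCReason.SERIES_RESISTANCE_OUT_OF_RANGE

    def test_missing_epoch_with_stim_rule_required_raises(self):
        with pytest.raises(ConfigurationError):
            qc_trace(self._trace(np.full(3000, -70.0)), require_stim_rule=True)
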