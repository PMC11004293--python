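"""Simulator ground-truth guarantees: zero-event cases, Poisson statistics,
tonic steps, amplitude conservation, suppression ratios, focal profiles."""

import numpy as np
import pytest
from scipy import stats as sps

from sonophys import (
    fwhm_from_map,
    simulate_cc_trace,
    simulate_pressure_map,
    simulate_vc_trace,
)
from sonophys.core import ClampMode, InvalidParameterError


class TestVoltageClamp:
    def test_zero_rate_zero_noise_is_constant_baseline(self):
        trace, truth = simulate_vc_trace(10.0, 0.0, noise_sd=0.0, baseline=-50.0, seed=1)
        assert trace.clamp_mode is ClampMode.VOLTAGE_CLAMP
        assert np.all(trace.samples == -50.0)
        assert len(truth.events) == 0

    def test_poisson_event_count_within_central_interval(self):
        # central 99.9% interval of Poisson(500) from the exact CDF
        lo, hi = sps.poisson.ppf([0.0005, 0.9995], 500)
        _, truth = simulate_vc_trace(100.0, 5.0, seed=7)
        assert lo <= len(truth.events) <= hi

    def test_tonic_step_identity(self):
        trace, truth = simulate_vc_trace(
            60.0, 0.0, noise_sd=0.0, baseline=-50.0, tonic_step=(-20.0, 30.0), seed=3)
        i = trace.index_at(30.0)
        assert trace.samples[i:].mean() - trace.samples[:i].mean() == pytest.approx(-20.0)
        assert truth.tonic_step_pa == -20.0

    def test_event_count_mean_matches_rate_times_duration(self):
        counts = [len(simulate_vc_trace(50.0, 4.0, seed=s)[1].events) for s in range(40)]
        expected = 4.0 * 50.0
        se = np.sqrt(expected / len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_isolated_event_peak_equals_drawn_amplitude(self):
        # rate low enough that kernels never overlap
        trace, truth = simulate_vc_trace(200.0, 0.1, noise_sd=0.0, baseline=0.0, seed=11)
        assert len(truth.events) > 5
        for t, a in zip(truth.events.times, truth.events.amplitudes):
            i0 = trace.index_at(t)
            i1 = min(i0 + int(0.12 * trace.sampling_rate), trace.n_samples)
            peak = -trace.samples[i0:i1].min()
            assert peak == pytest.approx(a, rel=0.01)

    def test_bit_identical_for_identical_seed(self):
        a, _ = simulate_vc_trace(5.0, 10.0, seed=42)
        b, _ = simulate_vc_trace(5.0, 10.0, seed=42)
        assert np.array_equal(a.samples, b.samples)

    @pytest.mark.parametrize("kwargs", [
        {"duration": 0.0, "rate": 1.0},
        {"duration": 10.0, "rate": -1.0},
        {"duration": 10.0, "rate": 1.0, "noise_sd": -1.0},
        {"duration": 10.0, "rate": 1.0, "sampling_rate": 0.0},
    ])
    def test_invalid_parameters_raise(self, kwargs):
        with pytest.raises(InvalidParameterError):
            simulate_vc_trace(**kwargs, seed=0)


class TestCurrentClamp:
    def test_zero_burst_rate_is_flat_resting_trace(self):
        trace, truth = simulate_cc_trace(20.0, 0.0, noise_sd=0.0, seed=1)
        assert np.all(trace.samples == -65.0)
        assert len(truth.events) == 0

    def test_no_suppression_leaves_rates_statistically_equal(self):
        # single-spike bursts make the spike train a homogeneous Poisson process
        _, truth = simulate_cc_trace(
            400.0, 0.5, spikes_per_burst=1, stim_epoch=(200.0, 200.0 + 1e-6),
            suppression_ratio=1.0, transition="step", seed=5)
        pre = truth.events.count_in(0.0, 200.0)
        post = truth.events.count_in(200.0, 400.0)
        ci = sps.binomtest(post, pre + post, 0.5).proportion_ci(0.999)
        assert ci.low <= 0.5 <= ci.high

    def test_half_suppression_recovered_within_binomial_error(self):
        _, truth = simulate_cc_trace(
            1200.0, 0.5, spikes_per_burst=1, stim_epoch=(600.0, 600.0 + 1e-6),
            suppression_ratio=0.5, transition="step", seed=6)
        pre = truth.events.count_in(0.0, 600.0)
        post = truth.events.count_in(600.0, 1200.0)
        # post ~ Binomial(pre+post, 1/3) given the totals under a true ratio 0.5
        ci = sps.binomtest(post, pre + post).proportion_ci(0.999)
        assert ci.low <= 1.0 / 3.0 <= ci.high

    def test_spikes_cross_zero_and_truth_times_on_grid(self):
        trace, truth = simulate_cc_trace(60.0, 0.3, noise_sd=0.0, seed=9)
        assert trace.samples.max() > 0.0
        on_grid = truth.events.times * trace.sampling_rate
        assert np.allclose(on_grid, np.round(on_grid))

    def test_invalid_suppression_raises(self):
        with pytest.raises(InvalidParameterError):
            simulate_cc_trace(10.0, 1.0, suppression_ratio=0.0, seed=0)


class TestPressureMap:
    def test_peak_value_and_location(self):
        pmap = simulate_pressure_map(peak_kpa=150.0, noise_sd_kpa=0.0)
        assert pmap.peak_kpa == pytest.approx(150.0)
        i, j = np.unravel_index(np.argmax(pmap.values_kpa), pmap.values_kpa.shape)
        assert pmap.axis1_mm[i] == pytest.approx(0.0)
        assert pmap.axis2_mm[j] == pytest.approx(0.0)

    def test_half_maximum_at_half_fwhm_radius(self):
        pmap = simulate_pressure_map(peak_kpa=150.0, fwhm_mm=2.15, step_mm=0.025,
                                     noise_sd_kpa=0.0)
        j0 = int(np.argmin(np.abs(pmap.axis2_mm)))
        i = int(np.argmin(np.abs(pmap.axis1_mm - 1.075)))
        assert pmap.values_kpa[i, j0] == pytest.approx(75.0, rel=5e-3)

    def test_reflection_symmetry_about_center(self):
        pmap = simulate_pressure_map(noise_sd_kpa=0.0)
        v = pmap.values_kpa
        assert np.allclose(v, v[::-1, :])
        assert np.allclose(v, v[:, ::-1])

    def test_fwhm_recovered_from_simulated_scan(self):
        pmap = simulate_pressure_map(fwhm_mm=2.15, step_mm=0.05, noise_sd_kpa=0.0)
        assert fwhm_from_map(pmap) == pytest.approx(2.15, abs=0.05)

    def test_extent_smaller_than_step_raises(self):
        with pytest.raises(InvalidParameterError):
            simulate_pressure_map(extent_mm=(0.05, 6.0), step_mm=0.1)
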