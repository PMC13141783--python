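"""Unit tests for the robust signal-processing primitives."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import signal as _sig

from glycofp import UniformTrace
from glycofp.signal_core import (
    MAD_SCALE,
    baseline_subtract,
    causal_moving_average,
    despike_flags,
    despike_mad,
    finite_difference_derivative,
    lowpass_zero_phase,
    median_filter_centered,
    regress_out_reference,
    robust_scale,
    zscore_baseline,
)


def trace(values, t0=0.0):
    return UniformTrace(np.asarray(values, dtype=float), t0=t0)


class TestUniformTrace:
    def test_time_axis(self):
        tr = trace([1, 2, 3, 4], t0=-2.0)
        assert np.array_equal(tr.t, [-2.0, -1.0, 0.0, 1.0])
        assert tr.dt == 1.0

    def test_window_mask_half_open(self):
        tr = trace(np.arange(10), t0=0.0)
        mask = tr.window_mask(2.0, 5.0)
        assert np.array_equal(np.flatnonzero(mask), [2, 3, 4])

    def test_window_values_empty_raises(self):
        tr = trace(np.arange(10), t0=0.0)
        with pytest.raises(ValueError):
            tr.window_values(100.0, 200.0)

    def test_index_of_time_clips(self):
        tr = trace(np.arange(10), t0=0.0)
        assert tr.index_of_time(-50.0) == 0
        assert tr.index_of_time(3.4) == 3
        assert tr.index_of_time(99.0) == 9

    def test_rejects_bad_shapes(self):
        with pytest.raises(ValueError):
            UniformTrace(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            UniformTrace(np.zeros(1))


class TestRobustScale:
    def test_matches_manual(self, rng):
        x = rng.normal(0, 3, 501)
        rs = robust_scale(x)
        med = np.median(x)
        assert rs.center == med
        assert rs.scale == pytest.approx(MAD_SCALE * np.median(np.abs(x - med)))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            robust_scale(np.array([]))


class TestDespike:
    def test_constant_trace_unchanged(self):
        tr = trace([5, 5, 5, 5, 5])
        out = despike_mad(tr, 2.0)
        assert np.array_equal(out.values, [5, 5, 5, 5, 5])

    def test_isolated_spike_interpolates(self):
        tr = trace([0, 0, 0, 100, 0, 0, 0])
        out = despike_mad(tr, 2.0)
        assert np.array_equal(out.values, np.zeros(7))

    def test_flags_match_rule_on_noise_with_spikes(self, rng):
        x = rng.normal(0, 1, 600)
        spike_idx = rng.choice(600, 10, replace=False)
        x[spike_idx] += 20.0 * rng.choice([-1.0, 1.0], 10)
        flags = despike_flags(x, 2.0)
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        expected = np.abs(x - med) > 2.0 * mad
        assert np.array_equal(flags, expected)
        assert set(spike_idx).issubset(set(np.flatnonzero(flags)))

    def test_unflagged_samples_bit_identical(self, rng):
        x = rng.normal(0, 1, 300)
        x[50] = 40.0
        tr = trace(x)
        out = despike_mad(tr, 2.0)
        flags = despike_flags(x, 2.0)
        assert np.array_equal(out.values[~flags], x[~flags])

    def test_boundary_spike_takes_nearest_unflagged(self, rng):
        x = np.zeros(50)
        x += rng.normal(0, 0.1, 50)
        x[0] = 100.0
        out = despike_mad(trace(x), 2.0)
        assert out.values[0] == out.values[1]

    def test_all_flagged_raises(self):
        # two wildly different halves with detrending disabled cannot all
        # flag under the global rule, so force the degenerate case directly
        x = np.array([0.0, 1e9, 0.0, 1e9])
        with pytest.raises(ValueError):
            # every sample deviates from the median by the same huge amount
            despike_mad(trace(x), 0.4)

    def test_nan_input_raises(self):
        x = np.zeros(10)
        x[3] = np.nan
        with pytest.raises(ValueError):
            despike_mad(trace(x), 2.0)

    def test_detrended_variant_spares_slow_excursion(self, rng):
        # a large slow excursion plus isolated spikes: the global rule
        # flattens the excursion, the detrended rule removes only the spikes
        t = np.arange(2000.0)
        slow = 100.0 * np.exp(-0.5 * ((t - 1000) / 200.0) ** 2)
        x = slow + rng.normal(0, 1.0, t.size)
        spikes = [300, 900, 1500]
        clean = x.copy()
        for i in spikes:
            x[i] += 80.0
        out = despike_mad(trace(x), 2.0, detrend_window=31)
        # spikes removed
        assert np.all(np.abs(out.values[spikes] - clean[spikes]) < 10.0)
        # excursion preserved
        assert out.values.max() > 90.0


class TestMedianFilter:
    def test_interior_matches_bruteforce(self, rng):
        x = rng.normal(0, 1, 101)
        out = median_filter_centered(trace(x), 7).values
        for i in range(3, 98):
            assert out[i] == np.median(x[i - 3: i + 4])

    def test_edges_use_shrunken_windows(self, rng):
        x = rng.normal(0, 1, 50)
        out = median_filter_centered(trace(x), 5).values
        assert out[0] == np.median(x[:3])
        assert out[1] == np.median(x[:4])
        assert out[-1] == np.median(x[-3:])

    def test_window_one_is_identity(self, rng):
        x = rng.normal(0, 1, 20)
        assert np.array_equal(median_filter_centered(trace(x), 1).values, x)

    def test_even_window_raises(self):
        with pytest.raises(ValueError):
            median_filter_centered(trace(np.zeros(10)), 4)


class TestCausalMovingAverage:
    def test_matches_bruteforce(self, rng):
        x = rng.normal(0, 1, 200)
        out = causal_moving_average(trace(x), 60).values
        for i in range(200):
            lo = max(0, i - 59)
            assert out[i] == pytest.approx(np.mean(x[lo: i + 1]), rel=1e-12)

    def test_strictly_causal(self, rng):
        # changing future samples never changes past outputs
        x = rng.normal(0, 1, 100)
        full = causal_moving_average(trace(x), 10).values
        y = x.copy()
        y[50:] += 100.0
        mutated = causal_moving_average(trace(y), 10).values
        assert np.array_equal(full[:50], mutated[:50])

    def test_constant_invariant(self):
        x = np.full(30, 7.5)
        assert np.allclose(causal_moving_average(trace(x), 8).values, 7.5)


class TestDerivative:
    def test_linear_ramp(self):
        x = 2.0 * np.arange(100.0)
        d = finite_difference_derivative(trace(x), 1).values
        assert d[0] == 0.0
        assert np.allclose(d[1:], 2.0)

    def test_smoothing_is_causal_ma_of_differences(self, rng):
        x = rng.normal(0, 1, 150)
        d = finite_difference_derivative(trace(x), 20).values
        raw = np.concatenate([[0.0], np.diff(x)])
        expected = causal_moving_average(trace(raw), 20).values
        assert np.allclose(d, expected)


class TestBaselineOps:
    def test_baseline_subtract_median(self, rng):
        x = rng.normal(50, 5, 300)
        tr = trace(x, t0=-150.0)
        out, base = baseline_subtract(tr, (-150.0, 0.0))
        assert base == np.median(x[:150])
        assert np.allclose(out.values, x - base)

    def test_zscore_baseline_stats(self, rng):
        x = rng.normal(3, 2, 400)
        tr = trace(x, t0=-200.0)
        z = zscore_baseline(tr, (-200.0, 0.0))
        assert np.mean(z.values[:200]) == pytest.approx(0.0, abs=1e-12)
        assert np.std(z.values[:200]) == pytest.approx(1.0, rel=1e-12)

    def test_zscore_constant_baseline_raises(self):
        x = np.concatenate([np.zeros(100), np.arange(100.0)])
        with pytest.raises(ValueError):
            zscore_baseline(trace(x, t0=-100.0), (-100.0, 0.0))


class TestLowpass:
    def test_preserves_dc_and_slow(self):
        t = np.arange(3600.0)
        # 30-min period sine: far below the 4-min cutoff
        x = 5.0 + np.sin(2 * np.pi * t / 1800.0)
        out = lowpass_zero_phase(trace(x), 4.0).values
        assert np.max(np.abs(out[600:-600] - x[600:-600])) < 0.02

    def test_attenuates_fast(self):
        t = np.arange(3600.0)
        # 30-s period sine: far above the cutoff
        x = np.sin(2 * np.pi * t / 30.0)
        out = lowpass_zero_phase(trace(x), 4.0).values
        assert np.max(np.abs(out[600:-600])) < 1e-3

    def test_zero_phase_no_shift(self):
        t = np.arange(7200.0)
        x = np.exp(-0.5 * ((t - 3600.0) / 600.0) ** 2)
        out = lowpass_zero_phase(trace(x), 4.0).values
        # peak stays at the same sample (no group delay)
        assert abs(int(np.argmax(out)) - 3600) <= 1

    def test_short_trace_raises(self):
        with pytest.raises(ValueError):
            lowpass_zero_phase(trace(np.zeros(10)), 4.0)


class TestReferenceRegression:
    def test_exact_removal_of_affine_reference(self, rng):
        ref = rng.normal(0, 1, 500)
        resid = rng.normal(0, 0.1, 500)
        resid -= np.polyval(np.polyfit(ref, resid, 1), ref)  # orthogonalize
        y = 3.0 * ref + 2.0 + resid
        out = regress_out_reference(trace(y), trace(ref))
        assert np.allclose(out.values, resid, atol=1e-9)

    def test_output_orthogonal_to_reference(self, rng):
        ref = rng.normal(0, 1, 400)
        y = rng.normal(0, 1, 400)
        out = regress_out_reference(trace(y), trace(ref)).values
        assert abs(np.dot(out - out.mean(), ref - ref.mean())) < 1e-8

    def test_constant_reference_mean_subtracts(self, rng):
        y = rng.normal(5, 1, 100)
        out = regress_out_reference(trace(y), trace(np.full(100, 2.0)))
        assert np.allclose(out.values, y - y.mean())

    def test_mismatched_axes_raise(self):
        with pytest.raises(ValueError):
            regress_out_reference(trace(np.zeros(10)), trace(np.zeros(11)))
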