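"""Unit and property tests for the shared signal primitives."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.signal import butter, freqz

from pfk.core import (
    BaselineStats,
    EmptyIntervalError,
    FilterSpec,
    InvalidParameterError,
    SeriesTooShortError,
    UniformTimeSeries,
    baseline_stats,
    butterworth_dual_pass,
    onset_by_threshold,
    rms_displacement,
)

from .conftest import FS, make_series


class TestUniformTimeSeries:
    def test_sample_times_follow_t0_plus_i_over_fs(self):
        s = make_series([0, 1, 2, 3], fs=2.0, t0=1.5)
        assert np.allclose(s.times(), [1.5, 2.0, 2.5, 3.0])
        assert s.t_end == 3.0

    @pytest.mark.parametrize(
        "values,fs",
        [([1.0], 10.0), ([1.0, np.nan], 10.0), ([1.0, 2.0], 0.0), ([1.0, 2.0], -5.0)],
    )
    def test_rejects_invalid_construction(self, values, fs):
        with pytest.raises((SeriesTooShortError, InvalidParameterError)):
            UniformTimeSeries(np.asarray(values), fs=fs)

    def test_half_open_interval_excludes_end_sample(self):
        s = make_series(np.arange(11), fs=10.0)
        assert s.segment((0.0, 0.5)).tolist() == [0, 1, 2, 3, 4]
        with pytest.raises(EmptyIntervalError):
            s.index_range((0.5, 0.5))


class TestDualPassFilter:
    def test_dc_gain_is_unity(self):
        s = make_series(np.full(500, 5.0))
        out = butterworth_dual_pass(s, FilterSpec(cutoff=10.0))
        assert np.abs(out.values - 5.0).max() < 1e-12

    def test_zero_phase_on_passband_tone(self, sine_series):
        s = sine_series(1.0, duration=20.0)
        y = butterworth_dual_pass(s, FilterSpec(cutoff=10.0)).values
        lag = np.argmax(np.correlate(s.values, y, mode="full")) - (s.n - 1)
        assert lag == 0

    def test_cutoff_gain_matches_squared_analytic_magnitude(self, sine_series):
        """At the cutoff the two-pass gain is the single-pass |H|^2 = 1/2."""
        spec = FilterSpec(cutoff=10.0, order_per_pass=2)
        s = sine_series(10.0, duration=20.0)
        y = butterworth_dual_pass(s, spec).values
        t = s.times()
        mid = slice(s.n // 4, 3 * s.n // 4)
        amp = 2.0 * np.abs(np.mean(y[mid] * np.exp(-2j * np.pi * 10.0 * t[mid])))
        b, a = butter(spec.order_per_pass, spec.cutoff, btype="low", fs=s.fs)
        _, h = freqz(b, a, worN=[spec.cutoff], fs=s.fs)
        analytic = np.abs(h[0]) ** 2
        assert analytic == pytest.approx(0.5, abs=1e-9)
        assert amp == pytest.approx(analytic, rel=0.01)

    def test_preserves_length_rate_and_origin(self, sine_series):
        s = sine_series(2.0, duration=5.0, t0=3.0)
        out = butterworth_dual_pass(s)
        assert (out.n, out.fs, out.t0) == (s.n, s.fs, s.t0)

    def test_rejects_cutoff_at_nyquist_and_short_series(self):
        s = make_series(np.ones(500))
        with pytest.raises(InvalidParameterError):
            butterworth_dual_pass(s, FilterSpec(cutoff=100.0))
        with pytest.raises(SeriesTooShortError):
            butterworth_dual_pass(make_series(np.ones(10)), FilterSpec(cutoff=10.0))

    def test_cutoff_correction_moves_combined_minus3db_to_nominal(self, sine_series):
        spec = FilterSpec(cutoff=10.0, order_per_pass=2, correct_cutoff=True)
        s = sine_series(10.0, duration=20.0)
        y = butterworth_dual_pass(s, spec).values
        t = s.times()
        mid = slice(s.n // 4, 3 * s.n // 4)
        amp = 2.0 * np.abs(np.mean(y[mid] * np.exp(-2j * np.pi * 10.0 * t[mid])))
        assert amp == pytest.approx(1.0 / np.sqrt(2.0), rel=0.01)

    @given(a=st.floats(-3, 3), b=st.floats(-3, 3))
    def test_linearity(self, a, b):
        rng = np.random.default_rng(7)
        x = rng.normal(size=400)
        y = rng.normal(size=400)
        spec = FilterSpec(cutoff=10.0)
        lhs = butterworth_dual_pass(make_series(a * x + b * y), spec).values
        rhs = a * butterworth_dual_pass(make_series(x), spec).values
        rhs += b * butterworth_dual_pass(make_series(y), spec).values
        assert np.abs(lhs - rhs).max() < 1e-9


class TestBaselineStats:
    def test_hand_arithmetic(self):
        s = make_series([1, 1, 1, 1, 2, 3], fs=1.0)
        flat = baseline_stats(s, (0.0, 3.0))
        assert (flat.mean, flat.sd, flat.n) == (1.0, 0.0, 3)
        ramp = baseline_stats(s, (3.0, 6.0))
        assert (ramp.mean, ramp.sd) == (2.0, 1.0)

    def test_matches_bruteforce_summation(self):
        rng = np.random.default_rng(42)
        x = rng.normal(0.0, 1.0, 1000)
        s = make_series(x, fs=100.0)
        stats = baseline_stats(s, (0.0, 10.0))
        # independent oracle: plain python accumulation
        mean = sum(x) / len(x)
        var = sum((v - mean) ** 2 for v in x) / (len(x) - 1)
        assert stats.mean == pytest.approx(mean, abs=1e-12)
        assert stats.sd == pytest.approx(var**0.5, abs=1e-12)

    def test_empty_interval_is_an_error(self):
        s = make_series(np.arange(10), fs=10.0)
        with pytest.raises(EmptyIntervalError):
            baseline_stats(s, (5.0, 6.0))


class TestOnsetByThreshold:
    def test_ideal_step_detected_at_step_time(self):
        fs = 100.0
        x = np.zeros(1000)
        x[int(5.0 * fs) :] = 1.0
        s = make_series(x, fs=fs)
        base = baseline_stats(s, (0.0, 1.0))
        onset = onset_by_threshold(s, base, search_from=1.0, min_hold=0.0)
        assert onset == pytest.approx(5.0, abs=1e-12)

    def test_ramp_crossing_at_hand_solved_time(self):
        # x(t) = 5 (t - 1) for t >= 1; threshold mean + 2 sd = 2 crossed at
        # t* = 1.4; first sample strictly beyond is one sample later.
        fs = 100.0
        t = np.arange(1000) / fs
        x = np.where(t >= 1.0, 5.0 * (t - 1.0), 0.0)
        s = make_series(x, fs=fs)
        base = BaselineStats(interval=(0.0, 1.0), mean=0.0, sd=1.0, n=100)
        onset = onset_by_threshold(s, base, k=2.0, search_from=1.0, min_hold=0.0, polarity="above")
        assert onset == pytest.approx(1.4 + 1.0 / fs, abs=1e-9)

    def test_no_crossing_returns_none(self):
        s = make_series(np.zeros(400), fs=100.0)
        base = baseline_stats(s, (0.0, 1.0))
        assert onset_by_threshold(s, base, search_from=1.0) is None

    def test_min_hold_rejects_single_sample_spike(self):
        fs = 100.0
        x = np.zeros(1000)
        x[300] = 10.0  # 10 ms spike
        x[600:] = 10.0  # sustained step
        s = make_series(x, fs=fs)
        base = baseline_stats(s, (0.0, 1.0))
        onset = onset_by_threshold(s, base, search_from=1.0, min_hold=0.05)
        assert onset == pytest.approx(6.0, abs=1e-12)

    @given(shift=st.integers(min_value=-100, max_value=100))
    def test_translation_equivariance(self, shift):
        fs = 100.0
        x = np.zeros(1200)
        x[500 + shift :] = 1.0
        s = make_series(x, fs=fs)
        base = BaselineStats(interval=(0.0, 1.0), mean=0.0, sd=0.0, n=100)
        onset = onset_by_threshold(s, base, search_from=0.0, min_hold=0.0)
        assert onset == pytest.approx((500 + shift) / fs, abs=1e-12)


class TestRmsDisplacement:
    def test_constant_signal_cases(self):
        s = make_series(np.full(100, 3.0), fs=10.0)
        assert rms_displacement(s, (0.0, 5.0), reference=3.0) == 0.0
        assert rms_displacement(s, (0.0, 5.0), reference=1.0) == pytest.approx(2.0)

    def test_sinusoid_whole_periods_gives_amp_over_sqrt2(self, sine_series):
        s = sine_series(2.0, amp=3.0, duration=10.0, offset=1.0)
        assert rms_displacement(s, (0.0, 5.0), reference=1.0) == pytest.approx(
            3.0 / np.sqrt(2.0), abs=1e-6
        )

    @given(c=st.floats(0.1, 50.0))
    def test_scales_linearly_about_reference(self, c):
        rng = np.random.default_rng(3)
        x = rng.normal(2.0, 1.0, 500)
        s1 = make_series(x, fs=100.0)
        s2 = make_series(2.0 + c * (x - 2.0), fs=100.0)
        r1 = rms_displacement(s1, (0.0, 5.0), reference=2.0)
        r2 = rms_displacement(s2, (0.0, 5.0), reference=2.0)
        assert r2 == pytest.approx(c * r1, rel=1e-9)

    def test_order_invariance_within_interval(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=300)
        s1 = make_series(x, fs=100.0)
        s2 = make_series(x[::-1].copy(), fs=100.0)
        assert rms_displacement(s1, (0.0, 3.0), 0.0) == pytest.approx(
            rms_displacement(s2, (0.0, 3.0), 0.0), rel=1e-12
        )
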