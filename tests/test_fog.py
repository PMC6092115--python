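"""Freezing-of-gait spectral analysis: PSD windows, index, event calling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pfk.core import EmptyIntervalError, InvalidTrialError, SeriesTooShortError, UniformTimeSeries
from pfk.fog import BandSpec, band_peak, detect_fog, fog_index, gait_time, window_psd
from pfk.synth import FreezeEpisode, WalkGenSpec, gen_walk_trial

from .conftest import FS, make_series

SPAN = 7.5


def _tone_window(freqs_amps, span=SPAN, fs=FS):
    n = int(round(span * fs))
    t = np.arange(n + 40) / fs
    x = np.zeros_like(t)
    for f, a in freqs_amps:
        x += a * np.sin(2 * np.pi * f * t)
    return UniformTimeSeries(x, fs=fs)


class TestWindowPsd:
    def test_pure_tone_peaks_at_nearest_bin(self):
        s = _tone_window([(2.0, 1.0)])
        freqs, power = window_psd(s, t_center=SPAN / 2, span=SPAN)
        assert abs(freqs[np.argmax(power)] - 2.0) <= freqs[1] - freqs[0]

    def test_frequency_resolution_is_inverse_span(self):
        s = _tone_window([(2.0, 1.0)])
        freqs, _ = window_psd(s, t_center=SPAN / 2, span=SPAN)
        assert freqs[1] - freqs[0] == pytest.approx(1.0 / SPAN, rel=1e-12)

    def test_two_tone_power_ratio_matches_amplitude_square(self):
        # both tones on exact bins of the 7.5 s window (k/7.5 Hz)
        s = _tone_window([(2.0, 1.0), (5.2, 2.0)])
        freqs, power = window_psd(s, t_center=SPAN / 2, span=SPAN)
        p2 = power[np.argmin(np.abs(freqs - 2.0))]
        p5 = power[np.argmin(np.abs(freqs - 5.2))]
        assert p5 / p2 == pytest.approx(4.0, rel=0.05)

    def test_matches_bruteforce_dft_summation(self):
        rng = np.random.default_rng(11)
        s = make_series(rng.normal(size=int(SPAN * FS) + 10), fs=FS)
        freqs, power = window_psd(s, t_center=SPAN / 2, span=SPAN)
        # independent oracle: direct DFT-definition summation with Hann taper
        n = int(round(SPAN * FS))
        x = s.values[:n] - np.mean(s.values[:n])
        w = 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / n))
        k = np.arange(n // 2 + 1)
        ph = np.exp(-2j * np.pi * np.outer(k, np.arange(n)) / n)
        X = ph @ (w * x)
        scale = 1.0 / (FS * np.sum(w**2))
        expected = 2.0 * scale * np.abs(X) ** 2
        expected[0] /= 2.0
        if n % 2 == 0:
            expected[-1] /= 2.0
        assert np.allclose(power, expected, rtol=1e-9, atol=1e-12)

    def test_zero_signal_gives_zero_power(self):
        s = make_series(np.zeros(2000), fs=FS)
        _, power = window_psd(s, t_center=SPAN / 2, span=SPAN)
        assert np.all(power == 0.0)

    def test_window_past_series_is_an_error(self):
        s = make_series(np.zeros(1000), fs=FS)
        with pytest.raises(EmptyIntervalError):
            window_psd(s, t_center=4.0, span=SPAN)


class TestFogIndex:
    def test_ratio_arithmetic(self):
        freqs = np.array([0.5, 2.0, 3.0, 5.0, 8.0])
        power = np.array([0.0, 3.0, 0.0, 6.0, 0.0])
        assert fog_index(freqs, power) == pytest.approx(2.0)

    def test_pure_locomotor_tone_classified_non_freeze(self):
        s = _tone_window([(2.0, 1.0)])
        freqs, power = window_psd(s, t_center=SPAN / 2, span=SPAN)
        idx = fog_index(freqs, power)
        assert idx < 2.0

    def test_loco_peak_below_floor_flags_invalid(self):
        freqs = np.array([1.0, 5.0])
        power = np.array([1e-15, 1.0])
        assert np.isnan(fog_index(freqs, power, power_floor=1e-12))

    @given(c=st.floats(0.01, 100.0))
    def test_scale_invariance(self, c):
        s = _tone_window([(2.0, 1.0), (5.2, 1.3)])
        f1, p1 = window_psd(s, t_center=SPAN / 2, span=SPAN)
        s2 = s.with_values(c * s.values)
        f2, p2 = window_psd(s2, t_center=SPAN / 2, span=SPAN)
        assert fog_index(f2, p2) == pytest.approx(fog_index(f1, p1), rel=1e-9)


class TestDetectFog:
    def test_recovers_single_injected_freeze_duration(self):
        spec = WalkGenSpec(
            duration=60.0,
            walk_stop=58.5,
            freeze_episodes=(FreezeEpisode(26.0, 34.0),),
            seed=12,
        )
        series, truth = gen_walk_trial(spec)
        result = detect_fog(series, walk_marks=(1.5, 58.5))
        assert len(result.events) == 1
        assert result.total_fog_time == pytest.approx(8.0, abs=1.0)
        assert result.total_fog_time <= result.gait_time

    def test_no_freeze_injected_yields_no_events(self):
        series, _ = gen_walk_trial(WalkGenSpec(duration=30.0, seed=5))
        result = detect_fog(series, walk_marks=(1.5, 28.5))
        assert result.events == ()
        assert result.total_fog_time == 0.0

    def test_two_separated_freezes_yield_two_events(self):
        spec = WalkGenSpec(
            duration=60.0,
            walk_stop=58.5,
            freeze_episodes=(FreezeEpisode(14.0, 22.0), FreezeEpisode(36.0, 44.0)),
            seed=21,
        )
        series, _ = gen_walk_trial(spec)
        result = detect_fog(series, walk_marks=(1.5, 58.5))
        assert len(result.events) == 2

    def test_series_shorter_than_span_is_an_error(self):
        s = make_series(np.random.default_rng(0).normal(size=600), fs=FS)
        with pytest.raises(SeriesTooShortError):
            detect_fog(s, walk_marks=(0.0, 3.0))

    def test_freeze_count_recovered_over_seeded_replicates(self):
        """Episodes >= span separated by >= span are counted exactly."""
        for seed in range(20):
            spec = WalkGenSpec(
                duration=60.0,
                walk_stop=58.5,
                freeze_episodes=(FreezeEpisode(12.0, 20.0), FreezeEpisode(30.0, 38.0)),
                seed=seed,
            )
            series, _ = gen_walk_trial(spec)
            result = detect_fog(series, walk_marks=(1.5, 58.5))
            assert len(result.events) == 2, f"seed {seed}"

    def test_total_fog_time_monotone_in_injected_duration(self):
        totals = []
        for dur in (4.0, 6.0, 8.0, 10.0):
            spec = WalkGenSpec(
                duration=60.0,
                walk_stop=58.5,
                freeze_episodes=(FreezeEpisode(20.0, 20.0 + dur),),
                seed=9,
            )
            series, _ = gen_walk_trial(spec)
            totals.append(detect_fog(series, walk_marks=(1.5, 58.5)).total_fog_time)
        assert totals == sorted(totals)


class TestGaitTime:
    def test_marks_take_precedence(self):
        s = make_series(np.zeros(4000), fs=FS)
        assert gait_time(s, walk_marks=(1.0, 13.5)) == pytest.approx(12.5)

    def test_detects_extent_of_locomotor_oscillation(self):
        spec = WalkGenSpec(duration=16.0, walk_start=2.0, walk_stop=14.0, noise_sd=0.0, seed=0)
        series, _ = gen_walk_trial(spec)
        assert gait_time(series) == pytest.approx(12.0, abs=0.5)

    def test_flat_trace_without_marks_is_an_error(self):
        s = make_series(np.zeros(4000), fs=FS)
        with pytest.raises(InvalidTrialError):
            gait_time(s)


def test_band_peak_includes_band_edges():
    freqs = np.array([0.5, 3.0, 8.0])
    power = np.array([1.0, 5.0, 2.0])
    assert band_peak(freqs, power, (0.5, 3.0)) == 5.0
    assert band_peak(freqs, power, (3.0, 8.0)) == 5.0
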