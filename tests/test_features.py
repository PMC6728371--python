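"""SQIs, swing, spectral and RR/HR run statistics against oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icualarms.features import (
    WindowSpec,
    blank_area_swing,
    feature_registry,
    rr_hr_features,
    spectral_features,
    sqi_correlation,
    sqi_peak_height_stability,
    sqi_periodicity,
    sqi_sharpness,
    swing_features,
)
from icualarms.records import Arrhythmia, BeatSeries
from tests.conftest import FS, make_ecg


def beats_at(times, amps=None, vent=None):
    times = np.asarray(times, float)
    return BeatSeries(
        times=times,
        amplitudes=np.ones(times.size) if amps is None else np.asarray(amps),
        ventricular=vent,
    )


class TestCorrelation:
    def test_identical_beats_give_unity(self):
        ecg, beats = make_ecg(np.arange(0.5, 19.5, 1.0), duration_s=20,
                              noise_sigma=0.0)
        r = sqi_correlation(ecg, FS, beats_at(beats))
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_white_noise_beats_decorrelate(self, rng):
        vals = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            x = r.standard_normal(int(25 * FS))
            t = np.arange(1.0, 24.0, 1.0)
            vals.append(sqi_correlation(x, FS, beats_at(t)))
        assert np.mean(np.abs(vals)) < 0.3

    def test_under_three_beats_missing(self):
        x = np.zeros(int(5 * FS))
        assert np.isnan(sqi_correlation(x, FS, beats_at([1.0, 2.0])))


class TestPeakHeightStability:
    def test_equal_amplitudes(self):
        assert sqi_peak_height_stability(
            beats_at([1, 2, 3, 4], amps=[2, 2, 2, 2])) == 1.0

    def test_outlier_cohort_excluded(self):
        # median sits in the 6-beat cohort; the 10x outliers fall outside
        amps = [2.0] * 6 + [20.0] * 5
        v = sqi_peak_height_stability(beats_at(np.arange(11), amps=amps))
        assert v == pytest.approx(6 / 11)

    def test_uniform_amplitudes_match_analytic_probability(self):
        # |A| ~ U[0.5m, 1.5m]: median m, P(|A-m| <= 0.3m) = 0.6
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(200):
            amps = rng.uniform(0.5, 1.5, 101)
            vals.append(sqi_peak_height_stability(
                beats_at(np.arange(101), amps=amps)))
        assert np.mean(vals) == pytest.approx(0.6, abs=0.02)


class TestSharpness:
    def test_impulse_train_is_sharp(self):
        x = np.zeros(int(10 * FS))
        t = np.arange(1.0, 9.0, 1.0)
        x[(t * FS).astype(int)] = 1.0
        x += 1e-6  # avoid an exactly-zero denominator
        assert sqi_sharpness(x, FS, beats_at(t)) >= 10.0

    def test_sine_crest_matches_closed_form(self):
        f0 = 1.0
        t_axis = np.arange(int(20 * FS)) / FS
        x = np.sin(2 * np.pi * f0 * t_axis)
        crests = np.arange(0.25, 19.0, 1.0)  # sin peaks
        got = sqi_sharpness(x, FS, beats_at(crests))
        half = int(0.06 * FS)
        tau = (np.arange(-half, half + 1)) / FS
        seg = np.abs(np.cos(2 * np.pi * f0 * tau))  # |sin| around a crest
        keep = np.ones(seg.size, bool)
        keep[half - 1:half + 2] = False
        expected = 1.0 / seg[keep].mean()
        assert got == pytest.approx(expected, rel=0.01)

    def test_spiky_sharper_than_smooth(self):
        t = np.arange(1.0, 9.0, 1.0)
        spiky = np.zeros(int(10 * FS))
        spiky[(t * FS).astype(int)] = 1.0
        spiky += 0.01
        t_axis = np.arange(int(10 * FS)) / FS
        sine = np.sin(2 * np.pi * 1.0 * (t_axis - 1.0) + np.pi / 2)
        assert (sqi_sharpness(spiky, FS, beats_at(t))
                > sqi_sharpness(sine, FS, beats_at(t)))


class TestPeriodicity:
    def test_periodic_signal_near_one(self):
        t = np.arange(int(10 * FS)) / FS
        x = np.sin(2 * np.pi * t / 0.8)
        assert sqi_periodicity(x, FS) >= 0.99

    def test_white_noise_low(self):
        vals = [sqi_periodicity(
            np.random.default_rng(s).standard_normal(int(10 * FS)), FS)
            for s in range(10)]
        assert np.mean(vals) < 0.3

    def test_ramp_below_periodic_case(self):
        # a trend has high short-lag correlation but never reaches the
        # self-similarity of a truly periodic signal
        ramp = np.linspace(0, 1, int(10 * FS))
        t = np.arange(int(10 * FS)) / FS
        periodic = np.sin(2 * np.pi * t / 0.8)
        assert sqi_periodicity(ramp, FS) < sqi_periodicity(periodic, FS)
        assert sqi_periodicity(ramp, FS) < 0.96

    def test_short_window_missing(self):
        assert np.isnan(sqi_periodicity(np.zeros(int(3 * FS)), FS))


class TestSwing:
    def test_constant_signal_zero(self):
        out = swing_features(np.full(int(10 * FS), 5.0), FS)
        assert out == {"swing_min": 0.0, "swing_max": 0.0, "swing_mean": 0.0}

    def test_sine_sub_window_swing_two(self):
        # 6.25 Hz puts crest and trough exactly on the sample grid
        t = np.arange(int(10 * FS)) / FS
        x = np.sin(2 * np.pi * 6.25 * t)
        out = swing_features(x, FS, sub_window_s=1.0)
        for v in out.values():
            assert v == pytest.approx(2.0, abs=1e-6)

    def test_quiet_sub_window_sets_minimum(self):
        x = np.sin(2 * np.pi * 6.25 * np.arange(int(10 * FS)) / FS)
        x[int(4 * FS):int(5 * FS)] *= 0.01
        out = swing_features(x, FS)
        assert out["swing_min"] == pytest.approx(0.02, rel=0.01)
        assert out["swing_max"] == pytest.approx(2.0, abs=1e-6)

    def test_fully_masked_missing(self):
        valid = np.zeros(int(4 * FS), bool)
        out = swing_features(np.zeros(int(4 * FS)), FS, valid=valid)
        assert all(np.isnan(v) for v in out.values())


class TestBlankAreaSwing:
    def test_flat_gap_near_zero(self):
        beats = np.concatenate([np.arange(0.5, 5.0, 0.8),
                                np.arange(10.0, 15.5, 0.8)])
        ecg, beats = make_ecg(beats, duration_s=16, noise_sigma=0.001)
        v = blank_area_swing(ecg, FS, beats_at(beats))
        assert v < 0.05

    def test_artifact_in_gap_much_larger(self, rng):
        beats = np.concatenate([np.arange(0.5, 5.0, 0.8),
                                np.arange(10.0, 15.5, 0.8)])
        ecg, beats = make_ecg(beats, duration_s=16, noise_sigma=0.001)
        noisy = ecg.copy()
        noisy[int(6 * FS):int(9 * FS)] += rng.standard_normal(int(3 * FS))
        assert (blank_area_swing(noisy, FS, beats_at(beats))
                >= 10 * blank_area_swing(ecg, FS, beats_at(beats)))

    def test_no_beats_constant_signal_zero(self):
        empty = BeatSeries(times=np.array([]), amplitudes=np.array([]))
        assert blank_area_swing(np.full(1000, 2.0), FS, empty) == 0.0


class TestSpectral:
    def test_pure_tone(self):
        # a bin-centered tone under the hann taper puts power (1/4, 1, 1/4)
        # (in amplitude) on three bins: peak share is exactly 2/3
        t = np.arange(int(16 * FS)) / FS
        out = spectral_features(np.sin(2 * np.pi * 5.0 * t), FS)
        assert out["mean_freq"] == pytest.approx(5.0, abs=0.1)
        assert out["median_freq"] == pytest.approx(5.0, abs=0.1)
        assert out["max_power_ratio"] == pytest.approx(2 / 3, abs=0.01)

    def test_two_tone_mean(self):
        t = np.arange(int(16 * FS)) / FS
        x = np.sin(2 * np.pi * 3.0 * t) + np.sin(2 * np.pi * 9.0 * t)
        out = spectral_features(x, FS)
        assert out["mean_freq"] == pytest.approx(6.0, abs=0.15)

    def test_white_noise_flat_spectrum(self):
        vals = [spectral_features(
            np.random.default_rng(s).standard_normal(int(10 * FS)),
            FS)["max_power_ratio"] for s in range(10)]
        assert max(vals) < 0.1

    def test_mean_freq_within_bin_width(self):
        for dur in (8.0, 16.0, 32.0):
            t = np.arange(int(dur * FS)) / FS
            out = spectral_features(np.sin(2 * np.pi * 7.3 * t), FS)
            assert abs(out["mean_freq"] - 7.3) <= 1.0 / dur + 0.05

    def test_short_signal_missing(self):
        out = spectral_features(np.zeros(int(2 * FS)), FS)
        assert all(np.isnan(v) for v in out.values())


def brute_force_rr(times, vent, win_start, win_end):
    """Independent enumeration oracle for the run statistics."""
    t = [x for x in times if win_start <= x < win_end]
    v = [vv for x, vv in zip(times, vent) if win_start <= x < win_end]
    edges = [win_start] + t + [win_end]
    max_rr = max(b - a for a, b in zip(edges, edges[1:]))

    def run_rate(i, n):
        return 60.0 * (n - 1) / (t[i + n - 1] - t[i])

    def stat(n, fn):
        rates = [run_rate(i, n) for i in range(len(t) - n + 1)]
        return fn(rates) if rates else np.nan

    best_len, best_rate = 0, np.nan
    i = 0
    while i < len(t):
        if v[i]:
            j = i
            while j + 1 < len(t) and v[j + 1]:
                j += 1
            L = j - i + 1
            if L > best_len:
                best_len = L
                best_rate = (60.0 * (L - 1) / (t[j] - t[i])
                             if L >= 2 else np.nan)
            i = j + 1
        else:
            i += 1
    return {
        "max_rr_s": max_rr,
        "min_hr_5beat_bpm": stat(5, min),
        "max_hr_17beat_bpm": stat(17, max),
        "slowest_4beat_bpm": stat(4, min),
        "vt_run_max_len": float(best_len),
        "vt_run_max_rate_bpm": best_rate,
    }


class TestRrHrFeatures:
    def test_regular_two_second_beats(self):
        t = np.arange(0.5, 29.5, 2.0)
        win = WindowSpec(Arrhythmia.BRADYCARDIA, 0.0, 30.0)
        out = rr_hr_features(beats_at(t), win)
        assert out["min_hr_5beat_bpm"] == pytest.approx(30.0)
        assert out["max_rr_s"] == pytest.approx(2.0)

    def test_fast_train_17beat_rate(self):
        t = np.arange(0.0, 8.0, 0.4)[:20]
        win = WindowSpec(Arrhythmia.TACHYCARDIA, -0.1, 10.0)
        out = rr_hr_features(beats_at(t), win)
        assert out["max_hr_17beat_bpm"] == pytest.approx(150.0)

    def test_empty_window_max_rr_is_window_length(self):
        win = WindowSpec(Arrhythmia.ASYSTOLE, 284.0, 300.0)
        out = rr_hr_features(beats_at([]), win)
        assert out["max_rr_s"] == pytest.approx(16.0)
        assert np.isnan(out["min_hr_5beat_bpm"])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_enumeration(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(0, 60))
        times = np.sort(r.uniform(0.0, 30.0, n))
        times = times[np.concatenate([[True], np.diff(times) > 0.21]) if n else
                      np.zeros(0, bool)]
        vent = r.random(times.size) < 0.3
        win = WindowSpec(Arrhythmia.VTACH, 2.0, 28.0)
        got = rr_hr_features(beats_at(times, vent=vent), win)
        want = brute_force_rr(times, vent, 2.0, 28.0)
        for key, val in want.items():
            if isinstance(val, float) and np.isnan(val):
                assert np.isnan(got[key]), key
            else:
                assert got[key] == pytest.approx(val), key


class TestRegistry:
    def test_asystole_registry_membership(self):
        names = feature_registry(Arrhythmia.ASYSTOLE)
        assert "ecg1_max_rr_s" in names and "ppg_max_rr_s" in names
        assert "ecg1_blank_area_swing" in names
        assert not any("mean_freq" in n for n in names)

    def test_vfib_spectral_on_ecg_only(self):
        names = feature_registry(Arrhythmia.VFIB)
        assert "ecg1_max_power_ratio" in names
        assert "ppg_max_power_ratio" not in names

    def test_counts_near_published_sizes(self):
        sizes = {a: len(feature_registry(a)) for a in Arrhythmia}
        assert 20 <= min(sizes.values()) and max(sizes.values()) <= 40


class TestScaleInvariance:
    def test_sqis_invariant_to_positive_scaling(self):
        ecg, beats = make_ecg(np.arange(0.5, 29.5, 0.8), duration_s=30,
                              seed=3)
        b = beats_at(beats, amps=np.abs(np.random.default_rng(0)
                                        .normal(1, 0.1, beats.size)))
        for scale in (0.1, 7.5):
            assert sqi_correlation(scale * ecg, FS, b) == pytest.approx(
                sqi_correlation(ecg, FS, b), abs=1e-9)
            assert sqi_sharpness(scale * ecg, FS, b) == pytest.approx(
                sqi_sharpness(ecg, FS, b), rel=1e-9)
            assert sqi_periodicity(scale * ecg, FS) == pytest.approx(
                sqi_periodicity(ecg, FS), abs=1e-9)
        b10 = beats_at(beats, amps=10 * b.amplitudes)
        assert sqi_peak_height_stability(b10) == sqi_peak_height_stability(b)
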