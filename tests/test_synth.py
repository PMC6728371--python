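"""Ground-truth annotator and the synthetic alarm generator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icualarms import io_wfdb
from icualarms.records import Arrhythmia, Label
from icualarms.synth import (
    annotate_truth,
    default_spec,
    generate_benchmark,
    generate_record,
)


class TestAnnotateTruth:
    @pytest.mark.parametrize("gap,expected", [(3.9, False), (4.0, True)])
    def test_asystole_gap_boundary(self, gap, expected):
        before = np.arange(0.5, 50.0, 0.8)
        after = np.arange(before[-1] + gap, 100.0, 0.8)
        v = annotate_truth(np.concatenate([before, after]), duration_s=100.0)
        assert v[Arrhythmia.ASYSTOLE] is expected

    @pytest.mark.parametrize("bpm,expected", [(39, True), (40, False), (41, False)])
    def test_bradycardia_rate_boundary(self, bpm, expected):
        t = np.arange(5) * (60.0 / bpm)
        v = annotate_truth(t, duration_s=t[-1] + 1.0)
        assert v[Arrhythmia.BRADYCARDIA] is expected

    @pytest.mark.parametrize("n,bpm,expected", [
        (17, 145, True), (16, 145, False), (17, 140, False), (17, 139, False),
    ])
    def test_tachycardia_run_boundary(self, n, bpm, expected):
        t = np.arange(n) * (60.0 / bpm)
        v = annotate_truth(t, duration_s=t[-1] + 0.3)
        assert v[Arrhythmia.TACHYCARDIA] is expected

    @pytest.mark.parametrize("n_vt,bpm,expected", [
        (5, 120, True), (4, 120, False), (5, 100, False), (6, 99, False),
    ])
    def test_vt_run_boundary(self, n_vt, bpm, expected):
        normal = np.arange(0.5, 8.0, 0.75)
        run = normal[-1] + 0.75 + np.arange(n_vt) * (60.0 / bpm)
        t = np.concatenate([normal, run])
        vent = np.concatenate([np.zeros(normal.size, bool),
                               np.ones(n_vt, bool)])
        v = annotate_truth(t, vent, duration_s=t[-1] + 0.75)
        assert v[Arrhythmia.VTACH] is expected

    @pytest.mark.parametrize("length,expected", [(3.9, False), (4.0, True)])
    def test_vf_interval_boundary(self, length, expected):
        t = np.arange(0.5, 60.0, 0.8)
        v = annotate_truth(t, duration_s=60.0,
                           vf_intervals=[(10.0, 10.0 + length)])
        assert v[Arrhythmia.VFIB] is expected

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(0, 80))
        t = np.sort(r.uniform(0.0, 40.0, n))
        keep = (np.concatenate([[True], np.diff(t) > 0.21])
                if n else np.zeros(0, bool))
        t = t[keep]
        vent = r.random(t.size) < 0.35
        dur = 42.0
        got = annotate_truth(t, vent, dur)
        # brute force: enumerate every run / gap
        edges = np.concatenate([[0.0], t, [dur]])
        asys = any(b - a >= 4.0 for a, b in zip(edges, edges[1:]))
        brady = any(60.0 * 4 / (t[i + 4] - t[i]) < 40.0 - 1e-9
                    for i in range(t.size - 4))
        tachy = any(60.0 * 16 / (t[i + 16] - t[i]) > 140.0 + 1e-9
                    for i in range(t.size - 16))
        vtach = False
        for i in range(t.size):
            for j in range(i, t.size):
                if not all(vent[i:j + 1]):
                    continue
                is_maximal = ((i == 0 or not vent[i - 1])
                              and (j == t.size - 1 or not vent[j + 1]))
                L = j - i + 1
                if (is_maximal and L >= 5
                        and 60.0 * (L - 1) / (t[j] - t[i]) > 100.0 + 1e-9):
                    vtach = True
        assert got[Arrhythmia.ASYSTOLE] == asys
        assert got[Arrhythmia.BRADYCARDIA] == brady
        assert got[Arrhythmia.TACHYCARDIA] == tachy
        assert got[Arrhythmia.VTACH] == vtach


class TestGenerateRecord:
    def test_same_seed_bit_identical(self):
        spec = default_spec(Arrhythmia.VFIB, Label.TRUE_ALARM, seed=99)
        r1, t1 = generate_record(spec)
        r2, t2 = generate_record(default_spec(Arrhythmia.VFIB,
                                              Label.TRUE_ALARM, seed=99))
        assert np.array_equal(t1.beat_times, t2.beat_times)
        for a, b in zip(r1.channels, r2.channels):
            assert np.array_equal(a.samples, b.samples)

    @pytest.mark.parametrize("arr", list(Arrhythmia))
    def test_true_alarm_episode_overlaps_final_ten_seconds(self, arr):
        for seed in range(5):
            rec, truth = generate_record(
                default_spec(arr, Label.TRUE_ALARM, seed=200 + seed))
            assert truth.verdicts[arr] is True
            if arr is Arrhythmia.VFIB:
                s, e = truth.vf_intervals[0]
                assert e > 290.0 and s < 300.0

    @pytest.mark.parametrize("arr", list(Arrhythmia))
    def test_false_alarm_has_no_qualifying_episode(self, arr):
        for seed in range(5):
            rec, truth = generate_record(
                default_spec(arr, Label.FALSE_ALARM, seed=300 + seed))
            assert truth.verdicts[arr] is False

    def test_contradictory_spec_rejected(self):
        spec = default_spec(Arrhythmia.ASYSTOLE, Label.TRUE_ALARM, seed=5)
        spec.episode = {}  # "true asystole" with continuous beats
        with pytest.raises(ValueError, match="verdict"):
            generate_record(spec)

    def test_true_asystole_gap_is_quiet(self):
        rec, truth = generate_record(
            default_spec(Arrhythmia.ASYSTOLE, Label.TRUE_ALARM, seed=17))
        gaps = np.diff(truth.beat_times)
        k = int(np.argmax(gaps))
        s = truth.beat_times[k] + 0.6
        e = truth.beat_times[k + 1] - 0.3
        fs = rec.fs
        seg = rec.channels[0].samples[int(s * fs):int(e * fs)]
        # only noise and wander in the gap: swing well below QRS amplitude
        assert seg.max() - seg.min() < 0.7


class TestBenchmark:
    def test_layout_counts_and_answers(self, tmp_path):
        out = generate_benchmark(tmp_path / "bench", 2, master_seed=5,
                                 duration_s=300.0)
        heas = sorted(out.glob("*.hea"))
        assert len(heas) == 20  # 5 types x 2 labels x 2
        answers = io_wfdb.load_answers(out / "answers.csv")
        assert len(answers) == 20
        prefixes = {h.stem[0] for h in heas}
        assert prefixes == {"a", "b", "t", "f", "v"}
        rec = io_wfdb.read_alarm_record(heas[0], answers)
        assert rec.label in (Label.TRUE_ALARM, Label.FALSE_ALARM)

    def test_benchmark_deterministic(self, tmp_path):
        a = generate_benchmark(tmp_path / "a", 1, master_seed=9)
        b = generate_benchmark(tmp_path / "b", 1, master_seed=9)
        for fa in sorted(a.iterdir()):
            fb = b / fa.name
            assert fb.exists()
            assert fa.read_bytes() == fb.read_bytes()
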