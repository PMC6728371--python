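"""Shared fixtures: compact synthetic signals and records."""

from __future__ import annotations

import numpy as np
import pytest

from icualarms.records import AlarmRecord, Arrhythmia, Channel, ChannelKind
from icualarms.synth import ecg_signal, pulse_signal

FS = 250.0


def make_ecg(beat_times, fs=FS, duration_s=60.0, ventricular=None,
             noise_sigma=0.02, seed=0, **kw):
    """Clean-ish ECG from explicit beat times (sample-aligned)."""
    beat_times = np.round(np.asarray(beat_times, float) * fs) / fs
    n = int(duration_s * fs)
    vent = (np.zeros(beat_times.size, bool) if ventricular is None
            else np.asarray(ventricular, bool))
    x = ecg_signal(beat_times, vent, fs, n, **kw)
    if noise_sigma:
        x = x + noise_sigma * np.random.default_rng(seed).standard_normal(n)
    return x, beat_times


def make_pulse(onset_times, fs=FS, duration_s=60.0, kind="abp",
               noise_sigma=None, seed=0):
    n = int(duration_s * fs)
    shape = pulse_signal(np.asarray(onset_times, float), fs, n)
    rng = np.random.default_rng(seed)
    if kind == "abp":
        sigma = 1.0 if noise_sigma is None else noise_sigma
        return 78.0 + 42.0 * shape + sigma * rng.standard_normal(n)
    sigma = 0.02 if noise_sigma is None else noise_sigma
    return 0.1 + shape + sigma * rng.standard_normal(n)


def make_record(arrhythmia=Arrhythmia.ASYSTOLE, beat_bpm=75.0,
                duration_s=300.0, fs=FS, seed=0, with_ppg=True):
    """Minimal hand-built record with a constant-rate rhythm."""
    n = int(duration_s * fs)
    interval = int(round(fs * 60.0 / beat_bpm))
    beats = np.arange(int(0.4 * fs), n - int(0.4 * fs), interval) / fs
    vent = np.zeros(beats.size, bool)
    rng = np.random.default_rng(seed)
    channels = [
        Channel("II", ChannelKind.ECG, fs,
                ecg_signal(beats, vent, fs, n) + 0.02 * rng.standard_normal(n)),
        Channel("V", ChannelKind.ECG, fs,
                0.9 * ecg_signal(beats, vent, fs, n)
                + 0.02 * rng.standard_normal(n)),
    ]
    if with_ppg:
        channels.append(Channel(
            "PLETH", ChannelKind.PPG, fs,
            0.1 + pulse_signal(beats + 0.2, fs, n)
            + 0.02 * rng.standard_normal(n)))
    code = {"ASYSTOLE": "a", "BRADYCARDIA": "b", "TACHYCARDIA": "t",
            "VFIB": "f", "VTACH": "v"}[Arrhythmia(arrhythmia).value]
    return AlarmRecord(record_id=f"{code}{seed:04d}l",
                       arrhythmia=Arrhythmia(arrhythmia),
                       channels=channels, alarm_time_s=duration_s), beats


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
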