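"""Synthetic bedside-monitor alarm generator with exact ground truth.

Emulates the challenge layout the pipeline consumes: 250 Hz multi-channel
records (two ECG leads plus optional PPG/ABP), 300 s long, alarm at 300 s,
one arrhythmia type per record and a true/false label.  True alarms embed a
qualifying episode per the arrhythmia definitions (asystole: no QRS for at
least 4 s; extreme bradycardia: rate below 40 bpm over 5 consecutive beats;
extreme tachycardia: rate above 140 bpm over 17 consecutive beats;
ventricular tachycardia: 5 or more ventricular beats above 100 bpm;
ventricular flutter/fibrillation: oscillatory waveform for at least 4 s)
ending near the alarm.  False alarms contain no qualifying episode but carry
the artifact processes that fool monitors: noise bursts, flat lines (probe
disconnection), pacing spikes, tall T waves, noisy pulse channels.

Waveform realism is intentionally minimal — QRS complexes are
Gaussian-second-derivative (Mexican-hat) templates, pulses are
rise-and-decay bumps — what matters is that detectors and features face the
named failure modes with known beat times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .records import AlarmRecord, Arrhythmia, Channel, ChannelKind, Label

__all__ = [
    "SynthSpec",
    "GroundTruth",
    "annotate_truth",
    "generate_record",
    "generate_benchmark",
    "ecg_signal",
    "pulse_signal",
]

# numeric guard for strict-inequality rate boundaries (see annotate_truth)
_EPS = 1e-9

ASYSTOLE_GAP_S = 4.0
BRADY_RATE_BPM = 40.0
BRADY_RUN_BEATS = 5
TACHY_RATE_BPM = 140.0
TACHY_RUN_BEATS = 17
VT_RATE_BPM = 100.0
VT_RUN_BEATS = 5
VF_MIN_DURATION_S = 4.0

_PULSE_TRANSIT_S = 0.2


@dataclass
class SynthSpec:
    """Full description of one synthetic alarm record."""

    seed: int
    arrhythmia: Arrhythmia
    label: Label
    record_id: str = ""
    fs: float = 250.0
    duration_s: float = 300.0
    alarm_time_s: float = 300.0
    channel_names: tuple[str, ...] = ("II", "V", "PLETH")
    base_hr_bpm: float = 75.0
    rr_jitter: float = 0.015
    episode: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    scenario: str = ""


@dataclass
class GroundTruth:
    """Exact per-record truth: beat times, flags, episode, verdicts."""

    beat_times: np.ndarray
    ventricular: np.ndarray
    pulse_times: np.ndarray
    vf_intervals: list[tuple[float, float]]
    verdicts: dict[Arrhythmia, bool]


def _run_rate_bpm(times: np.ndarray, i: int, n: int) -> float:
    """Rate of the n-beat run starting at index i: 60*(n-1)/(t_last-t_first)."""
    span = times[i + n - 1] - times[i]
    return 60.0 * (n - 1) / span if span > 0 else np.inf


def annotate_truth(
    beat_times: np.ndarray,
    ventricular: np.ndarray | None = None,
    duration_s: float | None = None,
    vf_intervals: list[tuple[float, float]] | None = None,
) -> dict[Arrhythmia, bool]:
    """Apply the five arrhythmia definitions literally to true beat times.

    Boundary semantics: durations are inclusive (a 4.0-s QRS-free gap is
    asystole), rate thresholds are strict (exactly 40 bpm is not extreme
    bradycardia, exactly 140 bpm is not extreme tachycardia, exactly
    100 bpm is not VT-qualifying).  Gaps to the record edges count as
    QRS-free time.  The flutter/fibrillation verdict keys off the supplied
    oscillatory-waveform intervals, not beat gaps.
    """
    t = np.sort(np.asarray(beat_times, dtype=float))
    vent = (np.zeros(t.size, dtype=bool) if ventricular is None
            else np.asarray(ventricular, dtype=bool))
    if duration_s is None:
        duration_s = float(t[-1]) if t.size else 0.0
    verdicts: dict[Arrhythmia, bool] = {}

    # asystole: any QRS-free span of at least 4 s (edges included)
    edges = np.concatenate([[0.0], t, [duration_s]])
    gaps = np.diff(edges)
    verdicts[Arrhythmia.ASYSTOLE] = bool(
        gaps.size and gaps.max() >= ASYSTOLE_GAP_S - _EPS
    )

    brady = False
    for i in range(t.size - BRADY_RUN_BEATS + 1):
        if _run_rate_bpm(t, i, BRADY_RUN_BEATS) < BRADY_RATE_BPM - _EPS:
            brady = True
            break
    verdicts[Arrhythmia.BRADYCARDIA] = brady

    tachy = False
    for i in range(t.size - TACHY_RUN_BEATS + 1):
        if _run_rate_bpm(t, i, TACHY_RUN_BEATS) > TACHY_RATE_BPM + _EPS:
            tachy = True
            break
    verdicts[Arrhythmia.TACHYCARDIA] = tachy

    vtach = False
    i = 0
    while i < t.size:
        if vent[i]:
            j = i
            while j + 1 < t.size and vent[j + 1]:
                j += 1
            run_len = j - i + 1
            if run_len >= VT_RUN_BEATS and (
                _run_rate_bpm(t, i, run_len) > VT_RATE_BPM + _EPS
            ):
                vtach = True
                break
            i = j + 1
        else:
            i += 1
    verdicts[Arrhythmia.VTACH] = vtach

    verdicts[Arrhythmia.VFIB] = bool(
        vf_intervals
        and max(e - s for s, e in vf_intervals) >= VF_MIN_DURATION_S - _EPS
    )
    return verdicts


# ---------------------------------------------------------------------------
# waveform primitives


def _mexican_hat(tau: np.ndarray, sigma: float) -> np.ndarray:
    z = tau / sigma
    return (1.0 - z * z) * np.exp(-0.5 * z * z)


def _gauss(tau: np.ndarray, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * (tau / sigma) ** 2)


def ecg_signal(
    beat_times: np.ndarray,
    ventricular: np.ndarray,
    fs: float,
    n_samples: int,
    qrs_amp: float = 1.0,
    t_amp: float = 0.22,
    qrs_sigma_s: float = 0.013,
    vt_sigma_s: float = 0.027,
) -> np.ndarray:
    """Clean ECG from beat times: narrow Mexican-hat QRS (~80 ms support)
    with P/T bumps for normal beats, wide smooth complexes (~160 ms) for
    ventricular beats."""
    x = np.zeros(n_samples)
    t_axis = np.arange(n_samples) / fs
    vent = np.asarray(ventricular, dtype=bool)
    for tb, v in zip(np.asarray(beat_times, dtype=float), vent):
        sigma = vt_sigma_s if v else qrs_sigma_s
        half = 4.0 * sigma + (0.45 if not v else 0.1)
        i0 = max(int((tb - half) * fs), 0)
        i1 = min(int((tb + half) * fs) + 1, n_samples)
        if i1 <= i0:
            continue
        tau = t_axis[i0:i1] - tb
        if v:
            x[i0:i1] += 1.15 * qrs_amp * _mexican_hat(tau, sigma)
        else:
            x[i0:i1] += qrs_amp * _mexican_hat(tau, sigma)
            x[i0:i1] += 0.08 * qrs_amp * _gauss(tau + 0.18, 0.04)   # P
            x[i0:i1] += t_amp * qrs_amp * _gauss(tau - 0.30, 0.06)  # T
    return x


def pulse_signal(
    onset_times: np.ndarray,
    fs: float,
    n_samples: int,
    rise_s: float = 0.12,
    decay_s: float = 0.22,
) -> np.ndarray:
    """Unit-amplitude pulse waveform: half-cosine upstroke from each onset
    followed by an exponential decay (asymmetric arterial-pulse shape)."""
    x = np.zeros(n_samples)
    t_axis = np.arange(n_samples) / fs
    dur = rise_s + 5.0 * decay_s
    for tb in np.asarray(onset_times, dtype=float):
        i0 = max(int(tb * fs), 0)
        i1 = min(int((tb + dur) * fs) + 1, n_samples)
        if i1 <= i0:
            continue
        tau = t_axis[i0:i1] - tb
        shape = np.where(
            tau < rise_s,
            0.5 * (1.0 - np.cos(np.pi * np.clip(tau, 0, rise_s) / rise_s)),
            np.exp(-(tau - rise_s) / decay_s),
        )
        x[i0:i1] += shape
    return x


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                lo: float, hi: float) -> np.ndarray:
    from scipy import signal as sps

    white = rng.standard_normal(n)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    out = sps.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(out ** 2))
    return out / rms if rms > 0 else out


# ---------------------------------------------------------------------------
# beat-train construction


def _beat_train(spec: SynthSpec, rng: np.random.Generator):
    """Ground-truth cardiac beat times and ventricular flags per scenario."""
    fs = spec.fs
    dur = spec.duration_s
    ep = spec.episode
    base_rr = 60.0 / spec.base_hr_bpm
    times: list[float] = []
    vent: list[bool] = []

    def hr_at(t: float) -> float:
        if ep.get("type") == "rate" and ep["start"] <= t < ep.get("end", dur):
            return ep["hr_bpm"]
        return spec.base_hr_bpm

    t = rng.uniform(0.1, 0.1 + base_rr)
    vt_done = False
    while t < dur - 0.05:
        if ep.get("type") == "vt_run" and not vt_done and t >= ep["start"]:
            rr = 60.0 / ep["hr_bpm"]
            for k in range(ep["n_beats"]):
                tb = t + k * rr
                if tb < dur - 0.05:
                    times.append(tb)
                    vent.append(True)
            t = t + ep["n_beats"] * rr
            vt_done = True
            continue
        in_gap = False
        for s, e in _quiet_intervals(spec):
            if s <= t < e:
                t = e + 0.1
                in_gap = True
                break
        if in_gap:
            continue
        times.append(t)
        vent.append(False)
        rr = 60.0 / hr_at(t)
        t = t + rr * float(np.exp(rng.normal(0.0, spec.rr_jitter)))
    tt = np.array(times)
    # snap to the sample grid so detector fiducials can match exactly
    tt = np.round(tt * fs) / fs
    keep = np.concatenate([[True], np.diff(tt) > 0.21])
    return tt[keep], np.array(vent)[keep]


def _quiet_intervals(spec: SynthSpec) -> list[tuple[float, float]]:
    """Beat-free intervals: the asystole gap and any VF episode."""
    ep = spec.episode
    out = []
    if ep.get("type") == "gap":
        out.append((ep["start"], ep["end"]))
    if ep.get("type") == "vf":
        out.append((ep["start"], ep["end"]))
    return out


# ---------------------------------------------------------------------------
# scenario catalogue


def _true_episode(arr: Arrhythmia, rng: np.random.Generator, dur: float) -> dict:
    if arr is Arrhythmia.ASYSTOLE:
        gap = rng.uniform(4.3, 5.2)
        end = rng.uniform(dur - 2.0, dur - 0.5)
        return {"type": "gap", "start": end - gap, "end": end}
    if arr is Arrhythmia.BRADYCARDIA:
        return {"type": "rate", "start": rng.uniform(dur - 14.0, dur - 11.0),
                "end": dur, "hr_bpm": rng.uniform(31.0, 36.0)}
    if arr is Arrhythmia.TACHYCARDIA:
        return {"type": "rate", "start": rng.uniform(dur - 13.0, dur - 10.0),
                "end": dur, "hr_bpm": rng.uniform(155.0, 180.0)}
    if arr is Arrhythmia.VTACH:
        return {"type": "vt_run", "start": rng.uniform(dur - 9.0, dur - 6.0),
                "hr_bpm": rng.uniform(130.0, 170.0),
                "n_beats": int(rng.integers(9, 16))}
    # VF: oscillatory episode running into the alarm
    start = rng.uniform(dur - 9.0, dur - 5.5)
    return {"type": "vf", "start": start, "end": dur,
            "freq_hz": rng.uniform(4.0, 6.5)}


_FALSE_SCENARIOS = {
    Arrhythmia.ASYSTOLE: ("ppg_flatline", "burst_ecg2", "pacing", "low_amp_ecg2"),
    Arrhythmia.BRADYCARDIA: ("noisy_ppg", "burst_ecg2", "noisy_ppg", "pacing"),
    Arrhythmia.TACHYCARDIA: ("tall_t", "burst_ecg2", "tall_t", "noisy_ppg"),
    Arrhythmia.VFIB: ("burst_window", "noisy_all", "burst_window", "ppg_flatline"),
    Arrhythmia.VTACH: ("wide_burst", "burst_ecg1", "wide_burst", "wide_burst"),
}


def default_spec(
    arrhythmia: Arrhythmia,
    label: Label,
    seed: int,
    record_id: str = "",
    duration_s: float = 300.0,
    fs: float = 250.0,
) -> SynthSpec:
    """Build the study-condition spec for one alarm (scenario chosen by seed)."""
    rng = np.random.default_rng(seed)
    arr = Arrhythmia(arrhythmia)
    label = Label(label)
    layouts = (
        ("II", "V", "PLETH"),
        ("II", "V", "ABP"),
        ("II", "V", "PLETH", "ABP"),
        ("II", "V", "PLETH"),
    )
    channels = layouts[int(rng.integers(0, len(layouts)))]
    episode: dict = {}
    scenario = "true_episode"
    base_hr = float(rng.uniform(62.0, 88.0))
    if label is Label.TRUE_ALARM:
        episode = _true_episode(arr, rng, duration_s)
    else:
        options = _FALSE_SCENARIOS[arr]
        scenario = str(options[int(rng.integers(0, len(options)))])
        if arr is Arrhythmia.TACHYCARDIA:
            base_hr = float(rng.uniform(95.0, 120.0))
    noise = {
        "white_sigma": float(rng.uniform(0.015, 0.04)),
        "wander_amp": float(rng.uniform(0.05, 0.25)),
        "wander_freq_hz": float(rng.uniform(0.15, 0.35)),
    }
    return SynthSpec(
        seed=seed,
        arrhythmia=arr,
        label=label,
        record_id=record_id,
        fs=fs,
        duration_s=duration_s,
        channel_names=channels,
        base_hr_bpm=base_hr,
        episode=episode,
        noise=noise,
        scenario=scenario,
    )


# ---------------------------------------------------------------------------
# record assembly


def generate_record(spec: SynthSpec) -> tuple[AlarmRecord, GroundTruth]:
    """Render one alarm record and its exact ground truth.

    Deterministic given ``spec.seed``.  Raises if the rendered beat train
    contradicts the requested label for the record's own arrhythmia type
    (e.g. a "true asystole" spec whose gap is too short).
    """
    rng = np.random.default_rng(spec.seed)
    fs, dur = spec.fs, spec.duration_s
    n = int(round(dur * fs))
    beats, vent = _beat_train(spec, rng)
    vf_intervals = (
        [(spec.episode["start"], spec.episode["end"])]
        if spec.episode.get("type") == "vf" else []
    )
    verdicts = annotate_truth(beats, vent, dur, vf_intervals)
    want = spec.label is Label.TRUE_ALARM
    if spec.label is not Label.UNKNOWN and verdicts[spec.arrhythmia] != want:
        raise ValueError(
            f"spec (seed={spec.seed}, {spec.arrhythmia.value}, "
            f"{spec.label.value}, scenario={spec.scenario!r}) rendered a beat "
            f"train whose ground-truth verdict is {verdicts[spec.arrhythmia]}"
        )

    scen = spec.scenario
    t_amp = 0.55 if scen == "tall_t" else 0.22
    t_axis = np.arange(n) / fs
    ecg_clean = ecg_signal(beats, vent, fs, n, t_amp=t_amp)
    if vf_intervals:
        s, e = vf_intervals[0]
        f0 = spec.episode.get("freq_hz", 5.0)
        seg = (t_axis >= s) & (t_axis < e)
        am = 0.75 * (1.0 + 0.3 * np.sin(2 * np.pi * 0.8 * t_axis[seg]))
        ecg_clean[seg] += am * np.sin(2 * np.pi * f0 * (t_axis[seg] - s))

    white = spec.noise.get("white_sigma", 0.02)
    wamp = spec.noise.get("wander_amp", 0.15)
    wf = spec.noise.get("wander_freq_hz", 0.25)

    def ecg_channel(name: str, lead_gain: float, lead_seed: int) -> np.ndarray:
        r = np.random.default_rng([spec.seed, lead_seed])
        x = lead_gain * ecg_clean.copy()
        x += wamp * np.sin(2 * np.pi * wf * t_axis + r.uniform(0, 2 * np.pi))
        x += white * r.standard_normal(n)
        return x

    # pulse channels follow the cardiac beats (quiet intervals — asystole
    # gaps, VF episodes — contain no beats, hence no pulses)
    pulse_times = beats + _PULSE_TRANSIT_S
    pulse_times = pulse_times[pulse_times < dur - 0.05]

    channels: list[Channel] = []
    ecg_i = 0
    for name in spec.channel_names:
        kind = (ChannelKind.PPG if "PLETH" in name.upper()
                else ChannelKind.ABP if ("ABP" in name.upper() or "ART" in name.upper())
                else ChannelKind.ECG)
        if kind is ChannelKind.ECG:
            ecg_i += 1
            gain = 1.0 if ecg_i == 1 else float(rng.uniform(0.7, 1.1))
            x = ecg_channel(name, gain, 100 + ecg_i)
        else:
            r = np.random.default_rng([spec.seed, 200 + len(channels)])
            shape = pulse_signal(pulse_times, fs, n)
            if kind is ChannelKind.ABP:
                x = 78.0 + 42.0 * shape + 1.0 * r.standard_normal(n)
            else:
                x = 0.1 + shape + 0.02 * r.standard_normal(n)
                x += 0.05 * np.sin(2 * np.pi * wf * t_axis + r.uniform(0, 2 * np.pi))
        channels.append(Channel(name=name, kind=kind, fs=fs, samples=x))

    _apply_artifacts(spec, rng, channels, t_axis)

    record = AlarmRecord(
        record_id=spec.record_id or f"{_code(spec.arrhythmia)}{spec.seed % 100000}l",
        arrhythmia=spec.arrhythmia,
        channels=channels,
        alarm_time_s=spec.alarm_time_s,
        label=spec.label,
    )
    truth = GroundTruth(
        beat_times=beats,
        ventricular=vent,
        pulse_times=pulse_times,
        vf_intervals=vf_intervals,
        verdicts=verdicts,
    )
    return record, truth


def _code(arr: Arrhythmia) -> str:
    return {
        Arrhythmia.ASYSTOLE: "a",
        Arrhythmia.BRADYCARDIA: "b",
        Arrhythmia.TACHYCARDIA: "t",
        Arrhythmia.VFIB: "f",
        Arrhythmia.VTACH: "v",
    }[arr]


def _apply_artifacts(spec, rng, channels, t_axis) -> None:
    """In-place artifact processes for the false-alarm scenarios."""
    scen = spec.scenario
    fs, dur, n = spec.fs, spec.duration_s, t_axis.size

    def ch(kind: ChannelKind, index: int = 0) -> Channel | None:
        found = [c for c in channels if c.kind is kind]
        return found[index] if index < len(found) else None

    def flat(channel: Channel, start: float, length: float) -> None:
        i0 = int(start * fs)
        i1 = min(int((start + length) * fs), n)
        channel.samples[i0:i1] = channel.samples[i0]

    def burst(channel: Channel, start: float, length: float, amp: float) -> None:
        i0 = int(start * fs)
        i1 = min(int((start + length) * fs), n)
        m = i1 - i0
        if m <= 8:
            return
        win = np.hanning(m)
        channel.samples[i0:i1] += amp * win * _band_noise(rng, m, fs, 3.0, 40.0)

    w0 = dur - 18.0  # artifacts land inside the analysis windows
    if scen == "ppg_flatline":
        target = ch(ChannelKind.PPG) or ch(ChannelKind.ABP)
        if target is not None:
            flat(target, rng.uniform(w0, dur - 6.0), rng.uniform(3.0, 5.0))
    elif scen == "burst_ecg2":
        target = ch(ChannelKind.ECG, 1)
        if target is not None:
            burst(target, rng.uniform(w0, dur - 4.0), rng.uniform(1.5, 3.0),
                  rng.uniform(2.0, 4.0))
    elif scen == "pacing":
        for idx in (0, 1):
            target = ch(ChannelKind.ECG, idx)
            if target is None:
                continue
            tp = rng.uniform(0.0, 0.4)
            period = 60.0 / rng.uniform(70.0, 80.0)
            spikes = np.arange(tp, dur, period)
            si = (spikes * fs).astype(int)
            si = si[si < n]
            target.samples[si] += rng.uniform(2.0, 3.0)
    elif scen == "low_amp_ecg2":
        target = ch(ChannelKind.ECG, 1)
        if target is not None:
            target.samples *= 0.15
    elif scen == "noisy_ppg":
        target = ch(ChannelKind.PPG) or ch(ChannelKind.ABP)
        if target is not None:
            scale = 25.0 if target.kind is ChannelKind.ABP else 0.6
            target.samples += scale * _band_noise(rng, n, fs, 0.5, 20.0)
    elif scen == "burst_ecg1":
        target = ch(ChannelKind.ECG, 0)
        if target is not None:
            burst(target, rng.uniform(dur - 9.0, dur - 6.0),
                  rng.uniform(3.0, 5.0), rng.uniform(2.0, 4.0))
    elif scen == "burst_window":
        target = ch(ChannelKind.ECG, 1) or ch(ChannelKind.ECG, 0)
        if target is not None:
            burst(target, rng.uniform(w0, dur - 4.0), rng.uniform(2.0, 3.5),
                  rng.uniform(2.0, 4.0))
    elif scen == "noisy_all":
        for c in channels:
            scale = 8.0 if c.kind is ChannelKind.ABP else 0.35
            c.samples += scale * _band_noise(rng, n, fs, 1.0, 45.0)
    elif scen == "wide_burst":
        # irregular wide bumps on the analyzed ECG lead mimicking
        # ventricular complexes (motion artifact, lead problems)
        target = ch(ChannelKind.ECG, 0)
        if target is not None:
            t0 = rng.uniform(dur - 9.5, dur - 8.0)
            t_bump = t0
            while t_bump < min(t0 + rng.uniform(5.0, 8.0), dur - 0.3):
                sigma = rng.uniform(0.015, 0.07)
                amp = rng.uniform(0.6, 2.5) * rng.choice([-1.0, 1.0])
                i0 = max(int((t_bump - 4 * sigma) * fs), 0)
                i1 = min(int((t_bump + 4 * sigma) * fs), n)
                tau = t_axis[i0:i1] - t_bump
                target.samples[i0:i1] += amp * _mexican_hat(tau, sigma)
                t_bump += rng.uniform(0.25, 0.6)


# ---------------------------------------------------------------------------
# benchmark


def generate_benchmark(
    out_dir: str | Path,
    n_per_type_per_label: int,
    master_seed: int,
    duration_s: float = 300.0,
    fmt: str = "wfdb",
) -> Path:
    """Write a challenge-layout benchmark directory plus an answers file.

    Produces ``n_per_type_per_label`` records for every arrhythmia x
    {true, false} combination, named with the type-code prefix convention,
    and ``answers.csv`` mapping record id to 1 (true) / 0 (false).
    Deterministic given ``master_seed``.
    """
    from . import io_wfdb

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    answers: list[tuple[str, int]] = []
    for a_idx, arr in enumerate(Arrhythmia):
        for l_idx, label in enumerate((Label.TRUE_ALARM, Label.FALSE_ALARM)):
            for i in range(n_per_type_per_label):
                seed = int(
                    np.random.SeedSequence(
                        [master_seed, a_idx, l_idx, i]
                    ).generate_state(1)[0] % (2 ** 31)
                )
                rid = f"{_code(arr)}{l_idx}{i:03d}l"
                spec = default_spec(arr, label, seed, record_id=rid,
                                    duration_s=duration_s)
                record, _ = generate_record(spec)
                io_wfdb.write_alarm_record(record, out, fmt=fmt)
                answers.append((rid, 1 if label is Label.TRUE_ALARM else 0))
    with open(out / "answers.csv", "w") as fh:
        for rid, lab in answers:
            fh.write(f"{rid},{lab}\n")
    return out
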