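"""Signal screening that gates all downstream analysis.

Three gates: flat-line detection (probe disconnection shows up as an exactly
constant waveform), polynomial baseline-wander removal for ECG, and per-beat
abnormality screening of the arterial-pressure waveform using beat-morphology
criteria (pressures outside physiological range, vanishing pulse pressure,
implausibly steep decay, large beat-to-beat jumps).
"""

from __future__ import annotations

import numpy as np

from .config import PreprocessConfig
from .records import AlarmRecord, BeatSeries, ChannelKind, ValidityMask

__all__ = [
    "detect_flat_line",
    "remove_baseline",
    "bp_abnormality",
    "build_validity_mask",
]


def detect_flat_line(
    samples: np.ndarray,
    fs: float,
    min_duration_s: float = 2.0,
    tol: float = 0.0,
) -> list[tuple[int, int]]:
    """Find maximal constant runs lasting at least ``min_duration_s``.

    A run is constant when consecutive differences satisfy ``|dx| <= tol``
    (``tol=0`` means exactly repeated samples, the signature of a
    disconnected probe).  Returns half-open ``[start, end)`` sample
    intervals, 0-based.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        return []
    min_len = int(round(min_duration_s * fs))
    const = np.abs(np.diff(x)) <= tol
    # runs of True in `const`: diff run [i, j) covers samples [i, j+1)
    edges = np.flatnonzero(np.diff(const.astype(np.int8)))
    starts = [0] if const[0] else []
    starts += [int(e) + 1 for e in edges if not const[e]]
    ends = [int(e) + 1 for e in edges if const[e]]
    if const[-1]:
        ends.append(const.size)
    out = []
    for s, e in zip(starts, ends):
        n = e + 1 - s  # samples spanned
        if n >= min_len:
            out.append((s, e + 1))
    return out


def remove_baseline(ecg: np.ndarray, fs: float, order: int = 5) -> np.ndarray:
    """Subtract a least-squares polynomial fit of the given order.

    Intended to run per analysis window; a low-order polynomial tracks the
    slow baseline wander while leaving the QRS-scale content untouched.
    Exactly linear in the input and annihilates polynomials up to ``order``.
    """
    x = np.asarray(ecg, dtype=float)
    if x.size < order + 1:
        raise ValueError(
            f"window of {x.size} samples too short for order-{order} fit"
        )
    t = np.arange(x.size, dtype=float)
    fit = np.polynomial.Polynomial.fit(t, x, order)
    return x - fit(t)


def _beat_intervals(times: np.ndarray, fs: float, n: int) -> list[tuple[int, int]]:
    """Sample interval [onset, next onset) for each beat; the last beat runs
    to at most 1.5 s past its onset."""
    idx = np.round(times * fs).astype(int)
    out = []
    for k, i in enumerate(idx):
        j = idx[k + 1] if k + 1 < idx.size else min(i + int(1.5 * fs), n)
        out.append((max(i, 0), min(max(j, i + 1), n)))
    return out


def bp_abnormality(
    bp: np.ndarray,
    fs: float,
    beats: BeatSeries,
    cfg: PreprocessConfig | None = None,
) -> np.ndarray:
    """Per-beat abnormality flags for an arterial-pressure waveform.

    A beat is abnormal when any enabled criterion fires: systolic above
    300 mmHg, diastolic below 20 mmHg, mean pressure outside 30-200 mmHg,
    pulse pressure below 20 mmHg, mean negative slope steeper than
    -40 mmHg per 100 ms, or a beat-to-beat systolic/diastolic jump above
    20 mmHg.
    Heart-rate-range and beat-period-change criteria are implemented but
    disabled by default.
    """
    cfg = cfg or PreprocessConfig()
    x = np.asarray(bp, dtype=float)
    times = beats.accepted().times
    if times.size == 0:
        return np.zeros(0, dtype=bool)
    flags = np.zeros(times.size, dtype=bool)
    sys_v = np.empty(times.size)
    dia_v = np.empty(times.size)
    for k, (i, j) in enumerate(_beat_intervals(times, fs, x.size)):
        seg = x[i:j]
        sys_v[k] = seg.max()
        dia_v[k] = seg.min()
        mean_p = seg.mean()
        pulse_p = sys_v[k] - dia_v[k]
        d = np.diff(seg)
        neg = d[d < 0]
        neg_slope = neg.mean() * fs if neg.size else 0.0
        if (
            sys_v[k] > cfg.bp_systolic_max
            or dia_v[k] < cfg.bp_diastolic_min
            or mean_p < cfg.bp_map_min
            or mean_p > cfg.bp_map_max
            or pulse_p < cfg.bp_pulse_pressure_min
            or neg_slope < cfg.bp_neg_slope_max
        ):
            flags[k] = True
    # beat-to-beat jump criteria
    if times.size > 1:
        d_sys = np.abs(np.diff(sys_v))
        d_dia = np.abs(np.diff(dia_v))
        jump = (d_sys > cfg.bp_delta_systolic_max) | (d_dia > cfg.bp_delta_diastolic_max)
        flags[1:] |= jump
    if cfg.bp_use_hr_criterion and times.size > 1:
        hr = 60.0 / np.diff(times)
        bad_hr = (hr < cfg.bp_hr_min_bpm) | (hr > cfg.bp_hr_max_bpm)
        flags[1:] |= bad_hr
    if cfg.bp_use_period_change_criterion and times.size > 2:
        dper = np.abs(np.diff(np.diff(times)))
        flags[2:] |= dper > cfg.bp_period_change_max_s
    return flags


def build_validity_mask(
    record: AlarmRecord,
    beats_per_channel: dict[str, BeatSeries] | None = None,
    cfg: PreprocessConfig | None = None,
) -> dict[str, ValidityMask]:
    """Per-channel analyzability masks.

    Marks flat-line runs on every channel and abnormal-beat spans on
    arterial-pressure channels; downstream feature extraction ignores
    masked spans.
    """
    cfg = cfg or PreprocessConfig()
    beats_per_channel = beats_per_channel or {}
    masks: dict[str, ValidityMask] = {}
    for ch in record.channels:
        valid = ~ch.missing.copy()
        reasons: list[tuple[int, int, str]] = []
        for s, e in _runs(ch.missing):
            reasons.append((s, e, "MISSING"))
        for s, e in detect_flat_line(
            ch.samples, ch.fs, cfg.flat_min_duration_s, cfg.flat_tolerance
        ):
            valid[s:e] = False
            reasons.append((s, e, "FLATLINE"))
        if ch.kind is ChannelKind.ABP and ch.name in beats_per_channel:
            beats = beats_per_channel[ch.name]
            flags = bp_abnormality(ch.samples, ch.fs, beats, cfg)
            times = beats.accepted().times
            for k, (i, j) in enumerate(
                _beat_intervals(times, ch.fs, ch.samples.size)
            ):
                if k < flags.size and flags[k]:
                    valid[i:j] = False
                    reasons.append((i, j, "ABNORMAL_BP"))
        masks[ch.name] = ValidityMask(valid=valid, reasons=reasons)
    return masks


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    m = np.asarray(mask, dtype=bool)
    if m.size == 0 or not m.any():
        return []
    edges = np.flatnonzero(np.diff(m.astype(np.int8)))
    starts = ([0] if m[0] else []) + [int(e) + 1 for e in edges if not m[e]]
    ends = [int(e) + 1 for e in edges if m[e]] + ([m.size] if m[-1] else [])
    return list(zip(starts, ends))
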