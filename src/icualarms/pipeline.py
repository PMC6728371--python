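"""Per-record orchestration: screening -> beat detection -> features.

Ties the stages together for one alarm record: build validity masks, run
the QRS detector on baseline-removed ECG and the double-SSF onset detector
on pulsatile channels, reject false peaks and flag ventricular complexes
using the band envelopes, then assemble the feature vector(s) for the
record's arrhythmia type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import beat_detect, features, preprocess
from .config import PipelineConfig
from .records import AlarmRecord, Arrhythmia, BeatSeries, ChannelKind, Label

__all__ = ["RecordAnalysis", "analyze_record", "feature_rows"]

#: context added before the analysis window so detectors see enough beats
_DETECT_MARGIN_S = 12.0


@dataclass
class RecordAnalysis:
    """Detection artifacts for one record, in record-time coordinates."""

    record: AlarmRecord
    window: features.WindowSpec
    beats_per_role: dict[str, BeatSeries]
    valid_per_role: dict[str, np.ndarray]   # full-record validity masks
    env_width_per_role: dict[str, float]


def analyze_record(record: AlarmRecord, cfg: PipelineConfig | None = None
                   ) -> RecordAnalysis:
    """Run screening and beat detection for one alarm record."""
    cfg = cfg or PipelineConfig()
    fs = record.fs
    window = features.window_for(record.arrhythmia, cfg.features,
                                 record.alarm_time_s)
    seg_start = max(0.0, window.start_s - _DETECT_MARGIN_S)
    i0 = int(round(seg_start * fs))
    i1 = int(round(record.alarm_time_s * fs))

    masks = preprocess.build_validity_mask(record, cfg=cfg.preprocess)
    roles = record.channel_roles()
    beats_per_role: dict[str, BeatSeries] = {}
    valid_per_role: dict[str, np.ndarray] = {}
    env_width: dict[str, float] = {}

    for role, ch in roles.items():
        seg = ch.samples[i0:i1]
        valid_seg = masks[ch.name].valid[i0:i1]
        if ch.kind is ChannelKind.ECG:
            clean = preprocess.remove_baseline(
                seg, fs, cfg.preprocess.baseline_poly_order)
            beats = beat_detect.detect_qrs(
                clean, fs, cfg.detect, valid=valid_seg, channel_name=ch.name)
            env = beat_detect.estimate_envelopes(
                clean, fs,
                {"low": cfg.detect.band_low, "qrs": cfg.detect.band_qrs,
                 "high": cfg.detect.band_high},
                cfg.detect.envelope_smooth_s)
            beats = beat_detect.reject_false_peaks(beats, env, cfg.detect)
            beats = beat_detect.flag_ventricular(beats, env, fs, cfg.detect)
            acc = beats.accepted()
            in_win = acc.times + seg_start >= window.start_s
            widths = beat_detect.envelope_widths(acc, env, fs)[in_win]
            env_width[role] = (float(np.nanmean(widths))
                               if np.isfinite(widths).any() else np.nan)
        else:
            beats = beat_detect.detect_pulse_onsets(
                seg, fs, cfg.detect, valid=valid_seg, channel_name=ch.name)
            env_width[role] = np.nan
        beats_per_role[role] = BeatSeries(
            times=beats.times + seg_start,
            amplitudes=beats.amplitudes,
            channel_name=beats.channel_name,
            detector=beats.detector,
            rejected=beats.rejected,
            ventricular=beats.ventricular,
        )
        valid_per_role[role] = masks[ch.name].valid

    # arterial-pressure abnormality screening needs the pulse beats
    abp = roles.get("abp")
    if abp is not None and "abp" in beats_per_role:
        masks2 = preprocess.build_validity_mask(
            record, {abp.name: beats_per_role["abp"]}, cfg.preprocess)
        valid_per_role["abp"] = masks2[abp.name].valid

    return RecordAnalysis(
        record=record, window=window, beats_per_role=beats_per_role,
        valid_per_role=valid_per_role, env_width_per_role=env_width,
    )


def _window_slices(record: AlarmRecord, analysis: RecordAnalysis,
                   win: features.WindowSpec, cfg: PipelineConfig):
    fs = record.fs
    w0 = int(round(win.start_s * fs))
    w1 = int(round(win.end_s * fs))
    sigs: dict[str, np.ndarray] = {}
    valids: dict[str, np.ndarray] = {}
    for role, ch in record.channel_roles().items():
        raw = ch.samples[w0:w1]
        if ch.kind is ChannelKind.ECG:
            sigs[role] = preprocess.remove_baseline(
                raw, fs, cfg.preprocess.baseline_poly_order)
        else:
            sigs[role] = raw
        valids[role] = analysis.valid_per_role[role][w0:w1]
    return sigs, valids


def feature_rows(record: AlarmRecord, cfg: PipelineConfig | None = None,
                 training: bool = False,
                 analysis: RecordAnalysis | None = None
                 ) -> list[tuple[float, dict[str, float]]]:
    """Feature vector(s) for one record as ``(window_start, features)`` pairs.

    Normally one pair per record; a true-VF alarm in training mode yields
    four (the augmented window starts, each running to the alarm).
    """
    cfg = cfg or PipelineConfig()
    analysis = analysis or analyze_record(record, cfg)
    if (training and record.arrhythmia is Arrhythmia.VFIB
            and record.label is Label.TRUE_ALARM):
        shift = record.alarm_time_s - 300.0
        windows = [
            features.WindowSpec(Arrhythmia.VFIB, s + shift, record.alarm_time_s)
            for s in cfg.features.vf_augment_starts
        ]
    else:
        windows = [analysis.window]
    out = []
    for win in windows:
        sigs, valids = _window_slices(record, analysis, win, cfg)
        rows = features.extract_features(
            record, win, sigs, analysis.beats_per_role, valids,
            analysis.env_width_per_role, cfg.features, training=False)
        out.append((win.start_s, rows[0][1]))
    return out
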