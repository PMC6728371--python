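"""Rule-based bradycardia classifier.

Extreme-bradycardia alarms are decided by a transparent rule instead of the
forest: pick the most reliable channel (highest beat-template correlation
in the analysis window), measure its slowest 4-consecutive-beat rate, and
call the alarm true when that rate is slower than 46 bpm.  Records on which
no channel qualifies default to a true alarm — missing a real extreme
bradycardia carries the fivefold score penalty, so the safe answer is true.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .config import BradyConfig, PipelineConfig
from .features import WindowSpec, sqi_correlation, _run_rates
from .pipeline import RecordAnalysis, _window_slices, analyze_record
from .records import AlarmRecord, BeatSeries, Label

__all__ = [
    "UnclassifiableRecord",
    "most_reliable_channel",
    "classify_bradycardia",
    "BradycardiaRule",
]

_ROLE_ORDER = ("ecg1", "ecg2", "ppg", "abp")


class UnclassifiableRecord(ValueError):
    """No channel has enough usable beats; callers fail safe to TRUE_ALARM."""


def _window_beats(beats: BeatSeries, window: WindowSpec) -> BeatSeries:
    acc = beats.accepted()
    m = (acc.times >= window.start_s) & (acc.times < window.end_s)
    return BeatSeries(times=acc.times[m] - window.start_s,
                      amplitudes=acc.amplitudes[m],
                      channel_name=acc.channel_name, detector=acc.detector,
                      ventricular=acc.ventricular[m])


def most_reliable_channel(
    record: AlarmRecord,
    analysis: RecordAnalysis,
    cfg: PipelineConfig | None = None,
) -> str:
    """Channel role with the highest correlation SQI in the window.

    Ties resolve in channel order (ECG leads first).  Raises
    :class:`UnclassifiableRecord` when no channel has 3 usable beats.
    """
    cfg = cfg or PipelineConfig()
    sigs, _ = _window_slices(record, analysis, analysis.window, cfg)
    best_role = None
    best_corr = -np.inf
    for role in _ROLE_ORDER:
        if role not in sigs:
            continue
        local = _window_beats(analysis.beats_per_role[role], analysis.window)
        corr = sqi_correlation(sigs[role], record.fs, local,
                               cfg.features.sqi_beat_half_window_s)
        if np.isfinite(corr) and corr > best_corr:
            best_corr = corr
            best_role = role
    if best_role is None:
        raise UnclassifiableRecord(
            f"record {record.record_id!r}: no channel with >= 3 beats in window"
        )
    return best_role


def classify_bradycardia(
    record: AlarmRecord,
    analysis: RecordAnalysis | None = None,
    cfg: PipelineConfig | None = None,
) -> Label:
    """Slowest-4-beat-rate rule on the most reliable channel.

    TRUE_ALARM iff the slowest rate over 4 consecutive beats is strictly
    below the threshold (46 bpm); fewer than 4 beats in the window — or no
    usable channel at all — also yields TRUE_ALARM (fail-safe).
    """
    cfg = cfg or PipelineConfig()
    analysis = analysis or analyze_record(record, cfg)
    try:
        role = most_reliable_channel(record, analysis, cfg)
    except UnclassifiableRecord:
        return Label.TRUE_ALARM
    local = _window_beats(analysis.beats_per_role[role], analysis.window)
    rates = _run_rates(local.times, cfg.brady.run_beats)
    if rates.size == 0:
        return Label.TRUE_ALARM
    slowest = float(rates.min())
    return (Label.TRUE_ALARM if slowest < cfg.brady.threshold_bpm
            else Label.FALSE_ALARM)


class BradycardiaRule(BaseEstimator, ClassifierMixin):
    """Estimator facade over the rule for pipeline composition.

    ``fit`` only records the configuration (the rule has no trainable
    state); ``predict`` maps alarm records to true/false labels.
    """

    def __init__(self, threshold_bpm: float = 46.0, run_beats: int = 4):
        self.threshold_bpm = threshold_bpm
        self.run_beats = run_beats

    def fit(self, X=None, y=None):
        self.classes_ = np.array([Label.FALSE_ALARM, Label.TRUE_ALARM])
        return self

    def _cfg(self) -> PipelineConfig:
        cfg = PipelineConfig()
        cfg.brady = BradyConfig(threshold_bpm=self.threshold_bpm,
                                run_beats=self.run_beats)
        return cfg

    def predict(self, X) -> np.ndarray:
        """X: sequence of AlarmRecord (or (record, RecordAnalysis) pairs)."""
        cfg = self._cfg()
        out = []
        for item in X:
            record, analysis = (item if isinstance(item, tuple)
                                else (item, None))
            out.append(classify_bradycardia(record, analysis, cfg))
        return np.array(out, dtype=object)
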