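"""Core containers for alarm records, beat series and feature tables.

A bedside-monitor alarm event is a short multi-channel recording (two ECG
leads plus optionally a photoplethysmogram and/or an arterial blood-pressure
line) with the alarm raised at a fixed time near the end of the record.  The
containers here carry those signals together with the arrhythmia type that
triggered the alarm and, when known, the expert true/false annotation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ChannelKind",
    "Arrhythmia",
    "Label",
    "Channel",
    "AlarmRecord",
    "BeatSeries",
    "EnvelopeSet",
    "ValidityMask",
    "FeatureTable",
    "classify_channel_kind",
    "arrhythmia_from_record_id",
    "ARRHYTHMIA_CODES",
    "REFRACTORY_S",
]

#: Minimum physiological spacing between beats (300 bpm ceiling).
REFRACTORY_S = 0.2


class ChannelKind(str, enum.Enum):
    ECG = "ECG"
    PPG = "PPG"
    ABP = "ABP"


class Arrhythmia(str, enum.Enum):
    ASYSTOLE = "ASYSTOLE"
    BRADYCARDIA = "BRADYCARDIA"
    TACHYCARDIA = "TACHYCARDIA"
    VFIB = "VFIB"
    VTACH = "VTACH"


class Label(str, enum.Enum):
    TRUE_ALARM = "TRUE_ALARM"
    FALSE_ALARM = "FALSE_ALARM"
    UNKNOWN = "UNKNOWN"


#: Record-id prefix convention of the challenge data layout.
ARRHYTHMIA_CODES = {
    "a": Arrhythmia.ASYSTOLE,
    "b": Arrhythmia.BRADYCARDIA,
    "t": Arrhythmia.TACHYCARDIA,
    "f": Arrhythmia.VFIB,
    "v": Arrhythmia.VTACH,
}


def classify_channel_kind(name: str) -> ChannelKind:
    """Classify a signal by its header name.

    Names containing ``PLETH`` are photoplethysmograms, names containing
    ``ABP`` or ``ART`` are arterial pressure lines, everything else is
    treated as an ECG lead.  Pure function of the name.
    """
    upper = name.upper()
    if "PLETH" in upper:
        return ChannelKind.PPG
    if "ABP" in upper or "ART" in upper:
        return ChannelKind.ABP
    return ChannelKind.ECG


def arrhythmia_from_record_id(record_id: str) -> Arrhythmia:
    """Decode the alarm type from the first character of a record id."""
    if not record_id:
        raise ValueError("empty record id")
    code = record_id[0].lower()
    try:
        return ARRHYTHMIA_CODES[code]
    except KeyError:
        raise ValueError(
            f"record id {record_id!r}: unknown arrhythmia type code {code!r} "
            f"(expected one of {sorted(ARRHYTHMIA_CODES)})"
        ) from None


@dataclass
class Channel:
    """One monitored waveform.

    ``samples`` are in arbitrary units for ECG/PPG and in mmHg for ABP.
    ``missing`` marks samples that carry no signal (e.g. padding).
    """

    name: str
    kind: ChannelKind
    fs: float
    samples: np.ndarray
    missing: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.missing is None:
            self.missing = np.zeros(self.samples.shape, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.fs <= 0:
            raise ValueError(f"channel {self.name!r}: fs must be positive")
        if self.missing.shape != self.samples.shape:
            raise ValueError(
                f"channel {self.name!r}: missing mask length "
                f"{self.missing.size} != samples length {self.samples.size}"
            )

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class AlarmRecord:
    """One alarm event: channels, alarm metadata and optional truth label."""

    record_id: str
    arrhythmia: Arrhythmia
    channels: list[Channel]
    alarm_time_s: float = 300.0
    label: Label = Label.UNKNOWN

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError(f"record {self.record_id!r}: no channels")
        # Normalize to ECG-first ordering (stable within kinds).
        self.channels = sorted(
            self.channels, key=lambda c: 0 if c.kind is ChannelKind.ECG else 1
        )
        if self.channels[0].kind is not ChannelKind.ECG:
            raise ValueError(f"record {self.record_id!r}: no ECG channel present")
        fs0 = self.channels[0].fs
        n0 = self.channels[0].samples.size
        for ch in self.channels[1:]:
            if ch.fs != fs0 or ch.samples.size != n0:
                raise ValueError(
                    f"record {self.record_id!r}: channel {ch.name!r} does not "
                    f"share fs/length with {self.channels[0].name!r}"
                )
        if n0 / fs0 < self.alarm_time_s - 1e-9:
            raise ValueError(
                f"record {self.record_id!r}: duration {n0 / fs0:.3f} s shorter "
                f"than alarm time {self.alarm_time_s} s"
            )

    @property
    def fs(self) -> float:
        return self.channels[0].fs

    @property
    def n_samples(self) -> int:
        return self.channels[0].samples.size

    def channels_of_kind(self, kind: ChannelKind) -> list[Channel]:
        return [c for c in self.channels if c.kind is kind]

    def channel_roles(self) -> dict[str, Channel]:
        """Map channels to the fixed feature-naming roles.

        ECG leads become ``ecg1``/``ecg2`` in record order; the first PPG
        becomes ``ppg`` and the first ABP ``abp``.
        """
        roles: dict[str, Channel] = {}
        ecg_i = 0
        for ch in self.channels:
            if ch.kind is ChannelKind.ECG:
                ecg_i += 1
                if ecg_i <= 2:
                    roles[f"ecg{ecg_i}"] = ch
            elif ch.kind is ChannelKind.PPG and "ppg" not in roles:
                roles["ppg"] = ch
            elif ch.kind is ChannelKind.ABP and "abp" not in roles:
                roles["abp"] = ch
        return roles


class RejectReason(str, enum.Enum):
    NONE = "NONE"
    PACING_SPIKE = "PACING_SPIKE"
    T_WAVE = "T_WAVE"


@dataclass
class BeatSeries:
    """Fiducial times and amplitudes for one channel.

    ``rejected`` carries a per-beat rejection reason (``NONE`` for accepted
    beats); rejected beats are excluded from every rate/RR feature.
    ``ventricular`` marks wide, smooth (ventricular-looking) complexes.
    """

    times: np.ndarray
    amplitudes: np.ndarray
    channel_name: str = ""
    detector: str = "wavelet_qrs"  # or "double_ssf"
    rejected: np.ndarray = None  # type: ignore[assignment]
    ventricular: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        n = self.times.size
        if self.amplitudes.size != n:
            raise ValueError("times and amplitudes differ in length")
        if self.rejected is None:
            self.rejected = np.array([RejectReason.NONE] * n, dtype=object)
        self.rejected = np.asarray(self.rejected, dtype=object)
        if self.ventricular is None:
            self.ventricular = np.zeros(n, dtype=bool)
        self.ventricular = np.asarray(self.ventricular, dtype=bool)
        if n > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    @property
    def accepted_mask(self) -> np.ndarray:
        return np.array([r is RejectReason.NONE or r == RejectReason.NONE.value
                         for r in self.rejected], dtype=bool)

    def accepted(self) -> "BeatSeries":
        """The sub-series of beats that survived false-peak rejection."""
        m = self.accepted_mask
        return BeatSeries(
            times=self.times[m],
            amplitudes=self.amplitudes[m],
            channel_name=self.channel_name,
            detector=self.detector,
            ventricular=self.ventricular[m],
        )


@dataclass
class EnvelopeSet:
    """Per-band amplitude envelopes of one channel (all non-negative)."""

    fs: float
    bands: dict[str, tuple[float, float]]
    envelopes: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, env in self.envelopes.items():
            env = np.asarray(env, dtype=float)
            if np.any(env < -1e-12):
                raise ValueError(f"envelope {name!r} has negative values")
            self.envelopes[name] = np.maximum(env, 0.0)

    def at_times(self, band: str, times: np.ndarray) -> np.ndarray:
        idx = np.clip(np.round(np.asarray(times) * self.fs).astype(int),
                      0, self.envelopes[band].size - 1)
        return self.envelopes[band][idx]


@dataclass
class ValidityMask:
    """Per-sample analyzability mask with reason-coded invalid runs."""

    valid: np.ndarray
    reasons: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.valid = np.asarray(self.valid, dtype=bool)

    def fraction_valid(self, start: int | None = None, end: int | None = None) -> float:
        seg = self.valid[start:end]
        return float(seg.mean()) if seg.size else 0.0


class FeatureTable:
    """Rectangular per-alarm feature matrix for one arrhythmia type.

    Thin wrapper around a pandas DataFrame of float features plus aligned
    labels and provenance (record id and extraction-window start).  A true
    ventricular-fibrillation alarm may contribute up to four rows (window
    augmentation); every other alarm contributes exactly one.
    """

    def __init__(
        self,
        arrhythmia: Arrhythmia,
        features: pd.DataFrame,
        labels: list[Label] | np.ndarray,
        record_ids: list[str],
        window_starts: list[float] | np.ndarray,
    ) -> None:
        if features.columns.duplicated().any():
            dupes = features.columns[features.columns.duplicated()].tolist()
            raise ValueError(f"duplicate feature names: {dupes}")
        n = len(features)
        if not (len(labels) == len(record_ids) == len(window_starts) == n):
            raise ValueError("labels/record_ids/window_starts must align with rows")
        self.arrhythmia = Arrhythmia(arrhythmia)
        self.features = features.astype(float).reset_index(drop=True)
        self.labels = [Label(l) for l in labels]
        self.record_ids = list(record_ids)
        self.window_starts = [float(w) for w in window_starts]

    def __len__(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def y(self) -> np.ndarray:
        """Binary target: 1 for a true alarm, 0 for a false alarm."""
        return np.array([1 if l is Label.TRUE_ALARM else 0 for l in self.labels])

    def subset_features(self, names: list[str]) -> "FeatureTable":
        missing = [n for n in names if n not in self.features.columns]
        if missing:
            raise KeyError(f"unknown feature names: {missing}")
        return FeatureTable(
            self.arrhythmia, self.features[names], self.labels,
            self.record_ids, self.window_starts,
        )

    def subset_rows(self, idx: np.ndarray) -> "FeatureTable":
        idx = np.asarray(idx)
        return FeatureTable(
            self.arrhythmia,
            self.features.iloc[idx],
            [self.labels[i] for i in idx],
            [self.record_ids[i] for i in idx],
            [self.window_starts[i] for i in idx],
        )
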