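"""On-disk conventions: alarm records, answers tables, feature tables.

Alarm records use the waveform-database (WFDB) header+signal layout in its
16-bit format dialect: a ``.hea`` text header declaring channel names,
gains and lengths, and a ``.dat`` file of interleaved little-endian int16
samples.  Physical units are recovered on read as ``(digital - baseline) /
gain``.  A plain-CSV fallback keeps test fixtures human-readable.

The record id's first character encodes the alarm type (a/b/t/f/v for
asystole, bradycardia, tachycardia, ventricular flutter/fibrillation and
ventricular tachycardia) — the naming convention of the challenge layout.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .records import (
    AlarmRecord,
    Arrhythmia,
    Channel,
    FeatureTable,
    Label,
    arrhythmia_from_record_id,
    classify_channel_kind,
)

__all__ = [
    "read_alarm_record",
    "write_alarm_record",
    "load_answers",
    "write_feature_table",
    "read_feature_table",
]

_DEFAULT_GAIN = {"ECG": 1000.0, "PPG": 1000.0, "ABP": 100.0}


class HeaderParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# WFDB dialect


def write_alarm_record(record: AlarmRecord, out_dir: str | Path,
                       fmt: str = "wfdb") -> Path:
    """Write one alarm record; returns the header (or CSV) path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        return _write_csv(record, out)
    if fmt != "wfdb":
        raise ValueError(f"unknown format {fmt!r}")
    rid = record.record_id
    n = record.n_samples
    nsig = len(record.channels)
    digital = np.empty((n, nsig), dtype="<i2")
    lines = [f"{rid} {nsig} {record.fs:g} {n}"]
    for j, ch in enumerate(record.channels):
        gain = _DEFAULT_GAIN[ch.kind.value]
        d = np.clip(np.round(ch.samples * gain), -32768, 32767).astype("<i2")
        digital[:, j] = d
        lines.append(
            f"{rid}.dat 16 {gain:g}(0)/{'mmHg' if ch.kind.value == 'ABP' else 'mV'}"
            f" 16 0 {int(d[0])} 0 0 {ch.name}"
        )
    hea = out / f"{rid}.hea"
    hea.write_text("\n".join(lines) + "\n")
    (out / f"{rid}.dat").write_bytes(digital.tobytes())
    return hea


def read_alarm_record(
    header_path: str | Path,
    answers: dict[str, Label] | None = None,
) -> AlarmRecord:
    """Read an alarm record from a ``.hea`` header (or ``.csv`` fallback).

    Channel kinds are classified from signal names, the arrhythmia type is
    decoded from the record id's first character, and the truth label is
    looked up in ``answers`` when given (``UNKNOWN`` otherwise).
    """
    path = Path(header_path)
    if path.suffix == ".csv":
        return _read_csv(path, answers)
    text = path.read_text().splitlines()
    if not text:
        raise HeaderParseError(f"{path}: empty header")
    head = text[0].split()
    if len(head) < 4:
        raise HeaderParseError(f"{path}: malformed record line: {text[0]!r}")
    rid, nsig_s, fs_s, n_s = head[:4]
    try:
        nsig, fs, n = int(nsig_s), float(fs_s), int(n_s)
    except ValueError:
        raise HeaderParseError(
            f"{path}: malformed record line: {text[0]!r}"
        ) from None
    if nsig < 1 or n < 1:
        raise HeaderParseError(
            f"{path}: degenerate record line (nsig={nsig}, samples={n})"
        )
    sig_lines = [l for l in text[1:1 + nsig] if l.strip()]
    if len(sig_lines) != nsig:
        raise HeaderParseError(f"{path}: expected {nsig} signal lines")
    names: list[str] = []
    gains: list[float] = []
    baselines: list[float] = []
    dat_name = None
    for line in sig_lines:
        parts = line.split()
        if len(parts) < 3:
            raise HeaderParseError(f"{path}: malformed signal line: {line!r}")
        if parts[1] != "16":
            raise HeaderParseError(
                f"{path}: unsupported signal format on line: {line!r}"
            )
        dat_name = parts[0]
        gain_field = parts[2].split("/")[0]
        if "(" in gain_field:
            g, b = gain_field.rstrip(")").split("(")
        else:
            g, b = gain_field, "0"
        try:
            gains.append(float(g))
            baselines.append(float(b))
        except ValueError:
            raise HeaderParseError(
                f"{path}: malformed gain field on line: {line!r}"
            ) from None
        names.append(parts[-1])
    raw = np.frombuffer((path.parent / dat_name).read_bytes(), dtype="<i2")
    if raw.size != n * nsig:
        raise HeaderParseError(
            f"{path}: signal file holds {raw.size} samples, header declares "
            f"{n * nsig}"
        )
    digital = raw.reshape(n, nsig)
    channels = []
    for j, name in enumerate(names):
        physical = (digital[:, j].astype(float) - baselines[j]) / gains[j]
        channels.append(Channel(
            name=name, kind=classify_channel_kind(name), fs=fs, samples=physical,
        ))
    return _assemble(rid, channels, answers)


def _assemble(rid: str, channels: list[Channel],
              answers: dict[str, Label] | None) -> AlarmRecord:
    arr = arrhythmia_from_record_id(rid)
    label = (answers or {}).get(rid, Label.UNKNOWN)
    return AlarmRecord(record_id=rid, arrhythmia=arr, channels=channels,
                       alarm_time_s=min(300.0, channels[0].duration_s),
                       label=label)


# ---------------------------------------------------------------------------
# CSV fallback


def _write_csv(record: AlarmRecord, out: Path) -> Path:
    path = out / f"{record.record_id}.csv"
    df = pd.DataFrame({ch.name: ch.samples for ch in record.channels})
    with open(path, "w") as fh:
        fh.write(f"# fs={record.fs:g}\n")
        df.to_csv(fh, index=False)
    return path


def _read_csv(path: Path, answers: dict[str, Label] | None) -> AlarmRecord:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# fs="):
            raise HeaderParseError(f"{path}: missing '# fs=' line, got {first!r}")
        fs = float(first.split("=", 1)[1])
        df = pd.read_csv(fh)
    if df.empty:
        raise HeaderParseError(f"{path}: no samples")
    channels = [
        Channel(name=c, kind=classify_channel_kind(c), fs=fs,
                samples=df[c].to_numpy(float))
        for c in df.columns
    ]
    return _assemble(path.stem, channels, answers)


# ---------------------------------------------------------------------------
# answers


def load_answers(path: str | Path) -> dict[str, Label]:
    """Read a two-column ``record_id,label`` table (label 1=true, 0=false)."""
    out: dict[str, Label] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.replace(",", " ").split()]
            if len(parts) != 2 or parts[1] not in {"0", "1"}:
                raise ValueError(f"{path}: unparseable row {lineno}: {line!r}")
            out[parts[0]] = (
                Label.TRUE_ALARM if parts[1] == "1" else Label.FALSE_ALARM
            )
    return out


# ---------------------------------------------------------------------------
# feature tables


_META_COLS = ["record_id", "window_start", "label"]


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """CSV with provenance columns first, then features in table order."""
    df = table.features.copy()
    for name in df.columns:
        if name in _META_COLS:
            raise ValueError(f"feature name {name!r} collides with metadata")
    df.insert(0, "label", [l.value for l in table.labels])
    df.insert(0, "window_start", table.window_starts)
    df.insert(0, "record_id", table.record_ids)
    with open(path, "w") as fh:
        fh.write(f"# arrhythmia={table.arrhythmia.value}\n")
        df.to_csv(fh, index=False)


def read_feature_table(path: str | Path) -> FeatureTable:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# arrhythmia="):
            raise ValueError(f"{path}: missing arrhythmia line, got {first!r}")
        arr = Arrhythmia(first.split("=", 1)[1])
        df = pd.read_csv(fh)
    feature_cols = [c for c in df.columns if c not in _META_COLS]
    return FeatureTable(
        arrhythmia=arr,
        features=df[feature_cols],
        labels=[Label(v) for v in df["label"]],
        record_ids=df["record_id"].astype(str).tolist(),
        window_starts=df["window_start"].tolist(),
    )
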