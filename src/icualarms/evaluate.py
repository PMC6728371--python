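"""Confusion counts and the challenge performance metrics.

A true alarm classified false is a false negative (FN) — the dangerous
error — so the score weights FN five times an FP in its denominator:

    score = 100 * (TP + TN) / (TP + TN + FP + 5 * FN)

TP rate = TP/(TP+FN) and TN rate = TN/(TN+FP); a zero denominator yields a
missing value (NaN), not an error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .records import Arrhythmia, Label

__all__ = [
    "FN_WEIGHT",
    "tp_rate",
    "tn_rate",
    "challenge_score",
    "EvalReport",
    "evaluate_predictions",
]

FN_WEIGHT = 5.0


def _check(*counts: float) -> None:
    for c in counts:
        if c < 0:
            raise ValueError(f"negative count {c}")


def tp_rate(tp: float, fn: float) -> float:
    """Sensitivity TP/(TP+FN); NaN when no positives exist."""
    _check(tp, fn)
    return tp / (tp + fn) if tp + fn > 0 else float("nan")


def tn_rate(tn: float, fp: float) -> float:
    """Specificity TN/(TN+FP); NaN when no negatives exist."""
    _check(tn, fp)
    return tn / (tn + fp) if tn + fp > 0 else float("nan")


def challenge_score(tp: float, tn: float, fp: float, fn: float) -> float:
    """100*(TP+TN)/(TP+TN+FP+5*FN), in [0, 100]."""
    _check(tp, tn, fp, fn)
    denom = tp + tn + fp + FN_WEIGHT * fn
    if denom == 0:
        raise ValueError("all counts zero: score undefined")
    return 100.0 * (tp + tn) / denom


@dataclass
class EvalReport:
    """Per-arrhythmia and pooled confusion counts, rates and scores."""

    per_arrhythmia: dict[str, dict[str, float]] = field(default_factory=dict)
    pooled: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"per_arrhythmia": self.per_arrhythmia, "pooled": self.pooled},
            indent=2, allow_nan=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def table(self) -> str:
        """Printable table: TPR %, TNR %, score per arrhythmia and pooled."""
        lines = [f"{'':26s}{'TPR (%)':>9s}{'TNR (%)':>9s}{'Score':>9s}"]

        def fmt(name: str, d: dict[str, float]) -> str:
            def pct(v: float) -> str:
                return f"{100 * v:9.1f}" if np.isfinite(v) else f"{'-':>9s}"
            return (f"{name:26s}{pct(d['tp_rate'])}{pct(d['tn_rate'])}"
                    f"{d['score']:9.2f}")

        for name, d in self.per_arrhythmia.items():
            lines.append(fmt(name, d))
        lines.append(fmt("Pooled", self.pooled))
        return "\n".join(lines)


def _block(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    return {
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
        "tp_rate": tp_rate(tp, fn),
        "tn_rate": tn_rate(tn, fp),
        "score": challenge_score(tp, tn, fp, fn) if tp + tn + fp + fn else float("nan"),
    }


def evaluate_predictions(
    truth: dict[str, Label],
    predicted: dict[str, Label],
    arrhythmia_by_record: dict[str, Arrhythmia],
) -> EvalReport:
    """Build the per-arrhythmia and pooled report from record-level labels.

    Each record counts once (window-augmented rows must be collapsed to a
    record-level prediction before calling this).  Pooling is joint over
    all records, not a mean of per-arrhythmia scores.
    """
    if set(truth) != set(predicted):
        diff = set(truth) ^ set(predicted)
        raise ValueError(f"record sets differ: {sorted(diff)[:10]}")
    counts: dict[str, list[int]] = {}
    pooled = [0, 0, 0, 0]  # tp, tn, fp, fn
    for rid, t in truth.items():
        p = predicted[rid]
        arr = Arrhythmia(arrhythmia_by_record[rid]).value
        c = counts.setdefault(arr, [0, 0, 0, 0])
        if t is Label.TRUE_ALARM and p is Label.TRUE_ALARM:
            k = 0
        elif t is Label.FALSE_ALARM and p is Label.FALSE_ALARM:
            k = 1
        elif t is Label.FALSE_ALARM and p is Label.TRUE_ALARM:
            k = 2
        else:
            k = 3
        c[k] += 1
        pooled[k] += 1
    report = EvalReport()
    for arr in sorted(counts):
        report.per_arrhythmia[arr] = _block(*counts[arr])
    report.pooled = _block(*pooled)
    return report
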