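"""Signal-quality indices and arrhythmia-specific features.

Every alarm is summarized by one feature vector (true ventricular-
fibrillation alarms by four, one per augmented window start).  Two feature
families feed the classifiers:

* signal-quality indices (SQIs) — beat-template correlation, peak-height
  stability, peak sharpness and waveform periodicity — that separate
  noise/artifact from physiology regardless of arrhythmia type, and
* arrhythmia-specific features that mirror the alarm definitions: maximum
  RR interval and blank-area swing for asystole, minimum run heart rate for
  bradycardia, maximum run heart rate for tachycardia, band-power spectral
  summaries for fibrillation, and ventricular-run statistics for VT.

Features are named ``<role>_<feature>`` with roles ``ecg1``/``ecg2``/
``ppg``/``abp``; a missing channel leaves its features as NaN so tables
from heterogeneous channel layouts stay rectangular.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .config import FeatureConfig
from .records import AlarmRecord, Arrhythmia, BeatSeries

__all__ = [
    "WindowSpec",
    "sqi_correlation",
    "sqi_peak_height_stability",
    "sqi_sharpness",
    "sqi_periodicity",
    "swing_features",
    "blank_area_swing",
    "spectral_features",
    "rr_hr_features",
    "feature_registry",
    "extract_features",
]

_ROLES = ("ecg1", "ecg2", "ppg", "abp")


@dataclass
class WindowSpec:
    """Analysis window in seconds from record start (must end by the alarm)."""

    arrhythmia: Arrhythmia
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError("window start must precede end")

    @property
    def length_s(self) -> float:
        return self.end_s - self.start_s


def window_for(arrhythmia: Arrhythmia, cfg: FeatureConfig | None = None,
               alarm_time_s: float = 300.0) -> WindowSpec:
    cfg = cfg or FeatureConfig()
    table = {
        Arrhythmia.ASYSTOLE: cfg.window_asystole,
        Arrhythmia.BRADYCARDIA: cfg.window_bradycardia,
        Arrhythmia.TACHYCARDIA: cfg.window_tachycardia,
        Arrhythmia.VFIB: cfg.window_vfib,
        Arrhythmia.VTACH: cfg.window_vtach,
    }
    s, e = table[Arrhythmia(arrhythmia)]
    shift = alarm_time_s - 300.0
    return WindowSpec(Arrhythmia(arrhythmia), s + shift, e + shift)


# ---------------------------------------------------------------------------
# SQIs


def _beat_windows(x: np.ndarray, fs: float, times: np.ndarray,
                  half_s: float) -> np.ndarray:
    half = int(round(half_s * fs))
    rows = []
    for t in times:
        i = int(round(t * fs))
        if i - half < 0 or i + half + 1 > x.size:
            continue
        rows.append(x[i - half:i + half + 1])
    return np.array(rows) if rows else np.empty((0, 2 * half + 1))


def sqi_correlation(x: np.ndarray, fs: float, beats: BeatSeries,
                    half_window_s: float = 0.25) -> float:
    """Mean Pearson correlation of each beat with the mean-beat template.

    Uniform beat morphology (clean sinus rhythm, monomorphic VT) scores
    near 1; artifact-driven detections decorrelate.  NaN below 3 beats.
    """
    times = beats.accepted().times
    if times.size < 3:
        return np.nan
    rows = _beat_windows(np.asarray(x, float), fs, times, half_window_s)
    if rows.shape[0] < 3:
        return np.nan
    template = rows.mean(axis=0)
    tc = template - template.mean()
    denom_t = np.sqrt((tc ** 2).sum())
    rs = []
    for row in rows:
        rc = row - row.mean()
        denom = np.sqrt((rc ** 2).sum()) * denom_t
        rs.append((rc @ tc) / denom if denom > 0 else 0.0)
    return float(np.mean(rs))


def sqi_peak_height_stability(beats: BeatSeries, tol: float = 0.3) -> float:
    """Fraction of beats whose |amplitude| is within +-30% of the median."""
    amps = np.abs(beats.accepted().amplitudes)
    if amps.size < 3:
        return np.nan
    med = np.median(amps)
    if med == 0:
        return np.nan
    return float(np.mean(np.abs(amps - med) <= tol * med))


def sqi_sharpness(x: np.ndarray, fs: float, beats: BeatSeries,
                  half_window_s: float = 0.06) -> float:
    """Median over beats of |x(fiducial)| / mean |x| nearby.

    The fiducial and its immediate neighbours are excluded from the
    denominator; spiky fiducials (true R peaks) score high, smeared ones
    (noise, low-frequency waves) score near 1.
    """
    times = beats.accepted().times
    if times.size < 3:
        return np.nan
    x = np.asarray(x, float)
    half = int(round(half_window_s * fs))
    vals = []
    for t in times:
        i = int(round(t * fs))
        if i - half < 0 or i + half + 1 > x.size:
            continue
        seg = np.abs(x[i - half:i + half + 1])
        keep = np.ones(seg.size, dtype=bool)
        c = half
        keep[max(c - 1, 0):c + 2] = False
        denom = seg[keep].mean()
        if denom > 0:
            vals.append(abs(x[i]) / denom)
    if len(vals) < 3:
        return np.nan
    return float(np.median(vals))


def sqi_periodicity(x: np.ndarray, fs: float,
                    lag_range_s: tuple[float, float] = (0.24, 2.4)) -> float:
    """Peak normalized autocorrelation over physiological lags (25-250 bpm).

    Unbiased (each lag divided by its overlap length), mean-removed,
    clipped to [0, 1].  NaN when fewer than 5 s of signal are available.
    """
    x = np.asarray(x, float)
    n = x.size
    if n < int(5.0 * fs):
        return np.nan
    xc = x - x.mean()
    var = float(xc @ xc) / n
    if var <= 0:
        return np.nan
    acf = sps.fftconvolve(xc, xc[::-1])[n - 1:]
    lags = np.arange(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (acf / (n - lags)) / var
    lo = max(1, int(round(lag_range_s[0] * fs)))
    hi = min(n - 1, int(round(lag_range_s[1] * fs)))
    if hi <= lo:
        return np.nan
    return float(np.clip(np.max(r[lo:hi + 1]), 0.0, 1.0))


# ---------------------------------------------------------------------------
# swing and spectral


def swing_features(x: np.ndarray, fs: float, sub_window_s: float = 1.0,
                   valid: np.ndarray | None = None) -> dict[str, float]:
    """Min/max/mean peak-to-peak swing over non-overlapping sub-windows.

    Sub-windows containing any masked sample are skipped.
    """
    x = np.asarray(x, float)
    w = int(round(sub_window_s * fs))
    n_sub = x.size // w
    swings = []
    for k in range(n_sub):
        seg = x[k * w:(k + 1) * w]
        if valid is not None and not np.all(valid[k * w:(k + 1) * w]):
            continue
        swings.append(float(seg.max() - seg.min()))
    if not swings:
        return {"swing_min": np.nan, "swing_max": np.nan, "swing_mean": np.nan}
    arr = np.array(swings)
    return {"swing_min": float(arr.min()), "swing_max": float(arr.max()),
            "swing_mean": float(arr.mean())}


def blank_area_swing(x: np.ndarray, fs: float, beats: BeatSeries) -> float:
    """Signal swing inside the longest beat-free span of the window.

    During true asystole the blank area is flat baseline (tiny swing);
    when an artifact merely hides the beats the blank area still moves.
    Window edges count as span boundaries; with no beats the whole window
    is the blank area.
    """
    x = np.asarray(x, float)
    times = beats.accepted().times
    n = x.size
    if times.size == 0:
        return float(x.max() - x.min()) if n else np.nan
    idx = np.clip(np.round(times * fs).astype(int), 0, n - 1)
    bounds = np.concatenate([[0], idx, [n - 1]])
    spans = np.diff(bounds)
    k = int(np.argmax(spans))
    i0, i1 = int(bounds[k]), int(bounds[k + 1])
    # leading margin skips the preceding beat's T wave, trailing margin the
    # next beat's P wave, so only the truly blank area is measured
    a = min(i0 + int(round(0.5 * fs)), i1)
    b = max(i1 - int(round(0.25 * fs)), a + 1)
    seg = x[a:b + 1]
    return float(seg.max() - seg.min()) if seg.size else 0.0


def spectral_features(x: np.ndarray, fs: float,
                      band: tuple[float, float] = (0.5, 15.0)) -> dict[str, float]:
    """Periodogram summaries over the analysis band.

    ``mean_freq`` is the power-weighted mean frequency, ``median_freq`` the
    smallest frequency reaching half the cumulative band power, and
    ``max_power_ratio`` the largest single-bin share of band power — near 1
    for the quasi-sinusoidal waveform of fibrillation/flutter, small for
    broadband artifact.
    """
    x = np.asarray(x, float)
    nan = {"mean_freq": np.nan, "median_freq": np.nan, "max_power_ratio": np.nan}
    if x.size < int(4.0 * fs):
        return nan
    f, p = sps.periodogram(x - x.mean(), fs=fs, window="hann")
    sel = (f >= band[0]) & (f <= band[1])
    f, p = f[sel], p[sel]
    total = p.sum()
    if total <= 0 or f.size == 0:
        return nan
    mean_f = float((f * p).sum() / total)
    cum = np.cumsum(p)
    median_f = float(f[np.searchsorted(cum, 0.5 * total)])
    return {"mean_freq": mean_f, "median_freq": median_f,
            "max_power_ratio": float(p.max() / total)}


# ---------------------------------------------------------------------------
# RR / heart-rate run statistics


def _run_rates(times: np.ndarray, n: int) -> np.ndarray:
    """Rates (bpm) of all n-beat consecutive runs: 60*(n-1)/(t_n - t_1)."""
    if times.size < n:
        return np.array([])
    spans = times[n - 1:] - times[:times.size - n + 1]
    with np.errstate(divide="ignore"):
        return 60.0 * (n - 1) / spans


def rr_hr_features(beats: BeatSeries, window: WindowSpec) -> dict[str, float]:
    """RR-interval and heart-rate run statistics within the window.

    ``max_rr_s`` includes the window-edge gaps (an empty window yields the
    window length — required for asystole).  Run rates use
    60*(n-1)/(t_n-t_1); run features are NaN when fewer beats than the run
    length exist.  Ventricular-run statistics cover maximal runs of
    ventricular-flagged beats.
    """
    acc = beats.accepted()
    m = (acc.times >= window.start_s) & (acc.times < window.end_s)
    t = acc.times[m]
    vent = acc.ventricular[m]
    out: dict[str, float] = {}
    edges = np.concatenate([[window.start_s], t, [window.end_s]])
    out["max_rr_s"] = float(np.diff(edges).max()) if edges.size > 1 else window.length_s

    r5 = _run_rates(t, 5)
    out["min_hr_5beat_bpm"] = float(r5.min()) if r5.size else np.nan
    r17 = _run_rates(t, 17)
    out["max_hr_17beat_bpm"] = float(r17.max()) if r17.size else np.nan
    r4 = _run_rates(t, 4)
    out["slowest_4beat_bpm"] = float(r4.min()) if r4.size else np.nan

    best_len = 0
    best_rate = np.nan
    i = 0
    while i < t.size:
        if vent[i]:
            j = i
            while j + 1 < t.size and vent[j + 1]:
                j += 1
            run_len = j - i + 1
            if run_len > best_len:
                best_len = run_len
                if run_len >= 2 and t[j] > t[i]:
                    best_rate = 60.0 * (run_len - 1) / (t[j] - t[i])
                else:
                    best_rate = np.nan
            i = j + 1
        else:
            i += 1
    out["vt_run_max_len"] = float(best_len)
    out["vt_run_max_rate_bpm"] = best_rate
    return out


# ---------------------------------------------------------------------------
# registry and assembly


_SQI_NAMES = ("correlation", "peak_height_stability", "sharpness", "periodicity")
_SWING_NAMES = ("swing_min", "swing_max", "swing_mean")
_SPECIFIC = {
    Arrhythmia.ASYSTOLE: ("max_rr_s", "blank_area_swing"),
    Arrhythmia.BRADYCARDIA: ("min_hr_5beat_bpm", "slowest_4beat_bpm"),
    Arrhythmia.TACHYCARDIA: ("max_hr_17beat_bpm",),
    Arrhythmia.VFIB: (),      # spectral block on ECG roles only, below
    Arrhythmia.VTACH: (),     # ventricular-run block on ECG roles only
}
_SPECTRAL_NAMES = ("mean_freq", "median_freq", "max_power_ratio")
_VT_NAMES = ("vt_run_max_len", "vt_run_max_rate_bpm", "env_width_ms")


def feature_registry(arrhythmia: Arrhythmia) -> list[str]:
    """Ordered feature names for one arrhythmia's table (all channel roles)."""
    arr = Arrhythmia(arrhythmia)
    names: list[str] = []
    for role in _ROLES:
        for f in _SQI_NAMES + _SWING_NAMES + _SPECIFIC[arr]:
            names.append(f"{role}_{f}")
        if arr is Arrhythmia.VFIB and role.startswith("ecg"):
            names.extend(f"{role}_{f}" for f in _SPECTRAL_NAMES)
        if arr is Arrhythmia.VTACH and role.startswith("ecg"):
            names.extend(f"{role}_{f}" for f in _VT_NAMES)
    return names


def extract_features(
    record: AlarmRecord,
    window: WindowSpec,
    signals: dict[str, np.ndarray],
    beats_per_role: dict[str, BeatSeries],
    valid_per_role: dict[str, np.ndarray] | None = None,
    env_width_per_role: dict[str, float] | None = None,
    cfg: FeatureConfig | None = None,
    training: bool = False,
) -> list[tuple[float, dict[str, float]]]:
    """Assemble the registry-defined feature vector for one alarm window.

    ``signals`` maps channel roles to samples sliced at ``window.start_s``
    (ECG baseline-removed); ``beats_per_role`` to record-time beat series.
    Returns ``[(window_start, features)]``.  True-VF window augmentation
    (four training rows with starts 293-296 s) is driven by the pipeline,
    which calls this once per augmented window with matching slices.
    """
    cfg = cfg or FeatureConfig()
    del training  # augmentation handled by the caller (see docstring)
    vec: dict[str, float] = {}
    for role in _ROLES:
        vec.update(_role_features(
            record, window, role,
            signals.get(role), beats_per_role.get(role),
            (valid_per_role or {}).get(role),
            (env_width_per_role or {}).get(role, np.nan),
            cfg,
        ))
    ordered = {name: vec.get(name, np.nan)
               for name in feature_registry(record.arrhythmia)}
    return [(window.start_s, ordered)]


def _role_features(record, win, role, sig, beats, valid, env_width, cfg):
    arr = record.arrhythmia
    prefix = f"{role}_"
    names = feature_registry(arr)
    mine = [n for n in names if n.startswith(prefix)]
    if sig is None or beats is None:
        return {n: np.nan for n in mine}
    fs = record.fs
    # window-relative beat series
    offset = win.start_s
    acc = beats.accepted()
    m = (acc.times >= win.start_s) & (acc.times < win.end_s)
    local = BeatSeries(times=acc.times[m] - offset,
                       amplitudes=acc.amplitudes[m],
                       channel_name=acc.channel_name,
                       detector=acc.detector,
                       ventricular=acc.ventricular[m])
    vals: dict[str, float] = {}
    vals[prefix + "correlation"] = sqi_correlation(
        sig, fs, local, cfg.sqi_beat_half_window_s)
    vals[prefix + "peak_height_stability"] = sqi_peak_height_stability(local)
    vals[prefix + "sharpness"] = sqi_sharpness(
        sig, fs, local, cfg.sharpness_half_window_s)
    vals[prefix + "periodicity"] = (
        sqi_periodicity(sig, fs, cfg.periodicity_lag_range_s)
        if valid is None or valid.mean() > 0.9 else np.nan
    )
    vals.update({prefix + k: v for k, v in swing_features(
        sig, fs, cfg.swing_sub_window_s, valid).items()})
    rr = rr_hr_features(beats, win)
    for f in _SPECIFIC[arr]:
        if f == "blank_area_swing":
            vals[prefix + f] = blank_area_swing(sig, fs, local)
        else:
            vals[prefix + f] = rr[f]
    if arr is Arrhythmia.VFIB and role.startswith("ecg"):
        vals.update({prefix + k: v for k, v in spectral_features(
            sig, fs, cfg.spectral_band).items()})
    if arr is Arrhythmia.VTACH and role.startswith("ecg"):
        vals[prefix + "vt_run_max_len"] = rr["vt_run_max_len"]
        vals[prefix + "vt_run_max_rate_bpm"] = rr["vt_run_max_rate_bpm"]
        vals[prefix + "env_width_ms"] = env_width
    return {n: vals.get(n, np.nan) for n in mine}
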