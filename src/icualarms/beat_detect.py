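"""Fiducial-point detection on ECG and pulsatile channels.

QRS complexes are found with an undecimated (a-trous) quadratic-spline
wavelet filter bank: the wavelet acts as a smoothed differentiator, so a QRS
produces a positive/negative modulus-maxima pair across dyadic scales whose
zero crossing marks the R peak.  Pulse onsets on blood-pressure and
photoplethysmogram channels are found by applying the slope sum function
(SSF) twice — which converts each pulse upstroke into a sharp QRS-like bump
while suppressing baseline wander — and running the same peak detector on
the result.  Band-limited amplitude envelopes support rejection of pacing
spikes and over-sensed T waves, and flag wide smooth (ventricular) beats.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .config import DetectConfig
from .records import BeatSeries, EnvelopeSet, RejectReason

__all__ = [
    "ssf",
    "detect_qrs",
    "detect_pulse_onsets",
    "estimate_envelopes",
    "reject_false_peaks",
    "flag_ventricular",
    "envelope_widths",
]

# Quadratic-spline filter pair: smoothing lowpass and derivative highpass.
_H0 = np.array([1.0, 3.0, 3.0, 1.0]) / 8.0
_G0 = np.array([2.0, -2.0])


def ssf(x: np.ndarray, fs: float, window_s: float = 0.128) -> np.ndarray:
    """Slope sum function: trailing-window sum of positive first differences.

    Causal; output has the same length as the input (leading windows are
    partial).  Emphasizes rising edges of pulse waves and is insensitive to
    slow baseline drift, whose slope contribution is small and spread out.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return x.copy()
    w = max(1, int(round(window_s * fs)))
    u = np.maximum(np.diff(x, prepend=x[:1]), 0.0)
    c = np.cumsum(u)
    y = c.copy()
    y[w:] = c[w:] - c[:-w]
    return y


def _upsample(f: np.ndarray, m: int) -> np.ndarray:
    if m == 1:
        return f
    out = np.zeros((f.size - 1) * m + 1)
    out[::m] = f
    return out


def _wavelet_bank(x: np.ndarray, levels: int = 4) -> list[np.ndarray]:
    """Undecimated dyadic wavelet transform, delay-compensated.

    Level k (1-based) uses filters with 2**(k-1)-fold holes; outputs are
    aligned to the input by slicing off the cumulative group delay.
    """
    n = x.size
    a = np.asarray(x, dtype=float)
    delay_a = 0.0
    ws: list[np.ndarray] = []
    for k in range(levels):
        m = 2 ** k
        w_full = np.convolve(a, _upsample(_G0, m))
        i0 = int(round(delay_a + 0.5 * m))
        w = w_full[i0:i0 + n]
        if w.size < n:
            w = np.pad(w, (0, n - w.size))
        ws.append(w)
        a = np.convolve(a, _upsample(_H0, m))
        delay_a += 1.5 * m
    return ws


def _find_candidates(detection: np.ndarray, fs: float, thr: float,
                     refractory_s: float) -> np.ndarray:
    dist = max(1, int(round(refractory_s * fs)))
    idx, _ = sps.find_peaks(detection, height=thr, distance=dist)
    return idx


def _localize(w2: np.ndarray, i: int, fs: float) -> tuple[int, float]:
    """Zero crossing between the modulus-maxima pair around ``i``.

    Returns the fiducial sample and an offset-invariant amplitude proxy
    (half the peak-to-peak wavelet excursion of the pair).
    """
    half = max(2, int(round(0.08 * fs)))
    s = max(i - half, 0)
    e = min(i + half + 1, w2.size)
    seg = w2[s:e]
    ip = s + int(np.argmax(seg))
    im = s + int(np.argmin(seg))
    amp = 0.5 * (w2[ip] - w2[im])
    a, b = sorted((ip, im))
    fid = i
    if b > a:
        sign_change = np.flatnonzero(np.diff(np.signbit(w2[a:b + 1])))
        if sign_change.size:
            # crossing nearest the candidate peak
            cross = a + sign_change
            fid = int(cross[np.argmin(np.abs(cross - i))])
        else:
            fid = (a + b) // 2
    return fid, float(abs(amp))


def _detect_core(
    x: np.ndarray,
    fs: float,
    cfg: DetectConfig,
    valid: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Shared wavelet peak detector: returns fiducial samples and amplitudes."""
    n = x.size
    if n < int(0.5 * fs):
        return np.array([], dtype=int), np.array([])
    ws = _wavelet_bank(x, levels=4)
    detection = np.abs(ws[1]) + np.abs(ws[2])
    scale = float(np.quantile(detection, 0.99))
    if scale <= 0.0:
        return np.array([], dtype=int), np.array([])
    thr = 0.3 * scale
    idx = _find_candidates(detection, fs, thr, cfg.refractory_s)
    # search-back: rescan long gaps at half threshold
    if idx.size >= 3:
        rr = np.diff(idx) / fs
        med = float(np.median(rr))
        extra = []
        for k, gap in enumerate(rr):
            if gap > 1.75 * med:
                s = idx[k] + int(cfg.refractory_s * fs)
                e = idx[k + 1] - int(cfg.refractory_s * fs)
                if e > s:
                    sub = _find_candidates(detection[s:e], fs, thr * 0.5,
                                           cfg.refractory_s)
                    extra.extend(int(s + j) for j in sub)
        if extra:
            idx = np.unique(np.concatenate([idx, np.array(extra, dtype=int)]))
    fids, amps = [], []
    for i in idx:
        fid, amp = _localize(ws[1], int(i), fs)
        fids.append(fid)
        amps.append(amp)
    if not fids:
        return np.array([], dtype=int), np.array([])
    order = np.argsort(fids)
    fids_arr = np.array(fids)[order]
    amps_arr = np.array(amps)[order]
    # enforce refractory after localization, keeping the larger excursion
    keep: list[int] = []
    min_gap = cfg.refractory_s * fs
    for k in range(fids_arr.size):
        if keep and fids_arr[k] - fids_arr[keep[-1]] < min_gap:
            if amps_arr[k] > amps_arr[keep[-1]]:
                keep[-1] = k
        else:
            keep.append(k)
    fids_arr = fids_arr[keep]
    amps_arr = amps_arr[keep]
    if valid is not None:
        valid = np.asarray(valid, dtype=bool)
        ok = valid[np.clip(fids_arr, 0, n - 1)]
        fids_arr, amps_arr = fids_arr[ok], amps_arr[ok]
    return fids_arr, amps_arr


def detect_qrs(
    ecg: np.ndarray,
    fs: float,
    cfg: DetectConfig | None = None,
    valid: np.ndarray | None = None,
    channel_name: str = "",
) -> BeatSeries:
    """Wavelet-transform QRS detection on a baseline-removed ECG.

    Adaptive thresholds are relative to the signal's own wavelet energy, so
    detections are invariant to positive amplitude scaling and to constant
    offsets.  A 0.2-s refractory period bounds the rate at 300 bpm and a
    reduced-threshold search-back recovers low-amplitude beats in long gaps.
    """
    cfg = cfg or DetectConfig()
    if fs < cfg.min_fs:
        raise ValueError(f"sampling rate {fs} Hz unsupported (need >= {cfg.min_fs})")
    fids, amps = _detect_core(np.asarray(ecg, dtype=float), fs, cfg, valid)
    return BeatSeries(
        times=fids / fs,
        amplitudes=amps,
        channel_name=channel_name,
        detector="wavelet_qrs",
    )


def detect_pulse_onsets(
    x: np.ndarray,
    fs: float,
    cfg: DetectConfig | None = None,
    valid: np.ndarray | None = None,
    channel_name: str = "",
) -> BeatSeries:
    """Pulse-onset detection on BP/PPG via the double slope sum function.

    ``S2 = SSF(SSF(x))`` turns each upstroke into a sharp bump; the wavelet
    peak detector locates the bumps and the onset is placed where the
    steepest-ascent tangent of the bump meets its local baseline — an
    estimate of where the upstroke (and hence the SSF response) started
    that does not depend on the pulse rise time.
    """
    cfg = cfg or DetectConfig()
    if fs < cfg.min_fs:
        raise ValueError(f"sampling rate {fs} Hz unsupported (need >= {cfg.min_fs})")
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < int(0.5 * fs):
        return BeatSeries(times=np.array([]), amplitudes=np.array([]),
                          channel_name=channel_name, detector="double_ssf")
    s2 = ssf(ssf(x, fs, cfg.ssf_window_s), fs, cfg.ssf_window_s)
    s2s = uniform_filter1d(s2, max(1, int(round(0.1 * fs))))
    ws = _wavelet_bank(s2s, levels=4)
    detection = np.abs(ws[1]) + np.abs(ws[2])
    scale = float(np.quantile(detection, 0.99))
    if scale <= 0.0:
        return BeatSeries(times=np.array([]), amplitudes=np.array([]),
                          channel_name=channel_name, detector="double_ssf")
    idx = _find_candidates(detection, fs, 0.45 * scale, cfg.refractory_s)
    # snap each wavelet response to the local maximum of the smoothed S2 bump
    half = int(round(0.15 * fs))
    peaks = sorted({
        max(i - half, 0) + int(np.argmax(s2s[max(i - half, 0):min(i + half, n)]))
        for i in idx
    })
    peaks_arr = np.array(peaks, dtype=int)
    if peaks_arr.size == 0:
        return BeatSeries(times=np.array([]), amplitudes=np.array([]),
                          channel_name=channel_name, detector="double_ssf")
    amps = s2s[peaks_arr]
    keep = amps > 0.5 * float(np.median(amps))
    peaks_arr, amps = peaks_arr[keep], amps[keep]
    # onset = steepest-ascent tangent of the S2 bump extrapolated to baseline
    times = []
    look = int(round(0.45 * fs))
    for pp in peaks_arr:
        lb = max(pp - look, 0)
        seg = s2s[lb:pp + 1]
        rel_pp = pp - lb
        base = float(np.quantile(seg, 0.05))
        grad = np.gradient(seg)
        k = int(np.argmax(grad))
        if grad[k] > 0:
            pos = k - (seg[k] - base) / grad[k]
            pos = min(max(pos, rel_pp - 0.3 * fs), float(rel_pp))
        else:
            pos = float(rel_pp)
        times.append((lb + pos) / fs)
    order = np.argsort(times)
    times_arr = np.array(times)[order]
    amps = amps[order]
    keep_idx = [0]
    for i in range(1, times_arr.size):
        if times_arr[i] - times_arr[keep_idx[-1]] >= cfg.refractory_s:
            keep_idx.append(i)
    times_arr, amps = times_arr[keep_idx], amps[keep_idx]
    ok = times_arr >= 0.0
    times_arr, amps = times_arr[ok], amps[ok]
    if valid is not None:
        valid = np.asarray(valid, dtype=bool)
        vi = valid[np.clip(np.round(times_arr * fs).astype(int), 0, n - 1)]
        times_arr, amps = times_arr[vi], amps[vi]
    return BeatSeries(
        times=times_arr,
        amplitudes=amps,
        channel_name=channel_name,
        detector="double_ssf",
    )


def estimate_envelopes(
    x: np.ndarray,
    fs: float,
    bands: dict[str, tuple[float, float]] | None = None,
    smooth_s: float = 0.1,
) -> EnvelopeSet:
    """Band-limited amplitude envelopes (rectify-and-smooth per band)."""
    cfg = DetectConfig()
    if bands is None:
        bands = {"low": cfg.band_low, "qrs": cfg.band_qrs, "high": cfg.band_high}
    x = np.asarray(x, dtype=float)
    nyq = fs / 2.0
    envs: dict[str, np.ndarray] = {}
    for name, (lo, hi) in bands.items():
        if not (0.0 < lo < hi < nyq):
            raise ValueError(f"band {name!r}=({lo}, {hi}) invalid for fs={fs}")
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        env = np.abs(sps.sosfiltfilt(sos, x))
        w = max(1, int(round(smooth_s * fs)))
        envs[name] = uniform_filter1d(env, size=w)
    return EnvelopeSet(fs=fs, bands=dict(bands), envelopes=envs)


def reject_false_peaks(
    beats: BeatSeries,
    env: EnvelopeSet,
    cfg: DetectConfig | None = None,
) -> BeatSeries:
    """Reject pacing-spike and T-wave-over-sensing detections.

    A detection is a pacing spike when its high-band envelope dominates the
    QRS band (broadband impulse); it is an over-sensed T wave when its
    QRS-band envelope is small against the median over the remaining beats
    (T waves carry little QRS-band energy).
    """
    cfg = cfg or DetectConfig()
    n = len(beats)
    if n == 0:
        return beats
    e_qrs = env.at_times("qrs", beats.times)
    e_high = env.at_times("high", beats.times)
    reasons = np.array([RejectReason.NONE] * n, dtype=object)
    pacing = e_high > cfg.kappa_pacing * e_qrs
    reasons[pacing] = RejectReason.PACING_SPIKE
    surviving = e_qrs[~pacing]
    if surviving.size:
        med = float(np.median(surviving))
        twave = (~pacing) & (e_qrs < cfg.kappa_twave * med)
        reasons[twave] = RejectReason.T_WAVE
    return BeatSeries(
        times=beats.times,
        amplitudes=beats.amplitudes,
        channel_name=beats.channel_name,
        detector=beats.detector,
        rejected=reasons,
        ventricular=beats.ventricular,
    )


def envelope_widths(beats: BeatSeries, env: EnvelopeSet, fs: float) -> np.ndarray:
    """Per-beat width (ms) of the QRS-band envelope at half its local max.

    Narrow supraventricular complexes stay well under ~140 ms; wide
    ventricular complexes exceed it.
    """
    e = env.envelopes["qrs"]
    half_span = int(round(0.3 * fs))
    widths = np.full(len(beats), np.nan)
    for k, t in enumerate(beats.times):
        i = int(round(t * fs))
        s = max(i - half_span, 0)
        end = min(i + half_span + 1, e.size)
        seg = e[s:end]
        if seg.size == 0:
            continue
        local_max = seg.max()
        if local_max <= 0:
            continue
        above = seg >= 0.5 * local_max
        ci = min(max(i - s, 0), seg.size - 1)
        if not above[ci]:
            ci = int(np.argmax(seg))
        lo = ci
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = ci
        while hi < above.size - 1 and above[hi + 1]:
            hi += 1
        widths[k] = (hi - lo + 1) / fs * 1000.0
    return widths


def flag_ventricular(
    beats: BeatSeries,
    env: EnvelopeSet,
    fs: float,
    cfg: DetectConfig | None = None,
) -> BeatSeries:
    """Mark wide, smooth complexes as ventricular.

    A wide ventricular complex concentrates its energy at lower
    frequencies than a narrow QRS, so its low-band amplitude envelope is
    elevated relative to the QRS band; requiring low high-band content at
    the same time excludes broadband artifact spikes.
    """
    cfg = cfg or DetectConfig()
    n = len(beats)
    if n == 0:
        return beats
    e_low = env.at_times("low", beats.times)
    e_high = env.at_times("high", beats.times)
    e_qrs = np.maximum(env.at_times("qrs", beats.times), 1e-12)
    smooth = (e_high / e_qrs) < cfg.vt_high_ratio_max
    vent = (e_low / e_qrs > cfg.vt_low_ratio_min) & smooth
    return BeatSeries(
        times=beats.times,
        amplitudes=beats.amplitudes,
        channel_name=beats.channel_name,
        detector=beats.detector,
        rejected=beats.rejected,
        ventricular=vent,
    )
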