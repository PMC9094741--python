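"""Recover R-peak, valve-opening and pulse-foot times from raw channels.

Detection never touches the truth annotations.  R-peaks come from an
adaptive amplitude threshold (median + k*MAD) with a refractory period and
parabolic peak interpolation.  The pulse foot uses the intersecting-tangent
convention: the crossing of the pre-upstroke baseline with the tangent at
the point of maximum upstroke slope (a maximum-second-derivative variant is
available for sensitivity analysis).  Valve opening is the first crossing
of a fractional-amplitude threshold on the Doppler envelope, corrected back
to baseline by linear extrapolation.

Individual bad beats are flagged (NaN) rather than raised; subject-level
timing later uses valid beats only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from .errors import InsufficientSignalError, InvalidInputError
from .signals import WaveformBundle

__all__ = [
    "DetectorConfig",
    "FiducialSet",
    "detect_r_peaks",
    "beat_windows",
    "detect_valve_opening",
    "detect_pulse_foot",
    "assemble_fiducials",
    "detect_fiducials",
]

FIDUCIAL_COLUMNS = ["beat_index", "t_r_hat", "t_valve_hat", "t_foot_hat", "valid"]


@dataclass(frozen=True)
class DetectorConfig:
    """Detector thresholds; defaults are the package's standard settings."""

    k_mad: float = 6.0            # R-peak threshold: median + k*MAD
    refractory: float = 0.3       # s between R-peaks
    envelope_frac: float = 0.10   # Doppler onset threshold (fraction of peak)
    foot_method: str = "tangent"  # or "second_derivative"
    smooth_ms: float = 25.0       # Savitzky-Golay window for cuff derivatives
    slope_fit_ms: float = 8.0     # half-width of the max-slope parabola fit
    envelope_smooth_ms: float = 15.0  # Doppler smoothing before thresholding
    valve_window: tuple[float, float] = (0.005, 0.35)  # s after each R-peak
    foot_window: tuple[float, float] = (0.05, 0.65)


@dataclass
class FiducialSet:
    """Per-beat detected event times with validity flags."""

    frame: pd.DataFrame
    subject_id: str | None = None

    def __post_init__(self) -> None:
        missing = [c for c in FIDUCIAL_COLUMNS if c not in self.frame.columns]
        if missing:
            raise InvalidInputError(f"fiducial frame missing columns: {missing}")

    @property
    def valid(self) -> pd.DataFrame:
        return self.frame[self.frame["valid"]]

    @property
    def n_valid(self) -> int:
        return int(self.frame["valid"].sum())


def _parabolic_refine(y: np.ndarray, i: int) -> tuple[float, float]:
    """Vertex (offset in samples, value) of the parabola through y[i-1:i+2]."""
    if i <= 0 or i >= len(y) - 1:
        return 0.0, float(y[i])
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if abs(denom) < 1e-12 * max(1.0, abs(y[i])):
        return 0.0, float(y[i])
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    value = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * delta
    return delta, float(value)


def detect_r_peaks(ecg: np.ndarray, sampling_rate: float,
                   k_mad: float = 6.0, refractory: float = 0.3) -> np.ndarray:
    """R-peak times via adaptive threshold and parabolic interpolation."""
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < 5.0 * sampling_rate:
        raise InvalidInputError("need at least 5 s of ECG signal")
    med = float(np.median(ecg))
    mad = float(np.median(np.abs(ecg - med)))
    span = float(np.max(ecg) - med)
    if span <= 0 or (mad > 0 and span < 2.0 * k_mad * mad):
        # QRS complexes must stand far above the noise floor
        raise InsufficientSignalError("no QRS-like activity above noise floor")
    threshold = med + k_mad * mad
    idx, _ = find_peaks(ecg, height=threshold if mad > 0 else None,
                        distance=max(int(round(refractory * sampling_rate)), 1))
    # reject residual noise spikes well below the QRS amplitude
    idx = idx[ecg[idx] > med + 0.5 * span]
    if len(idx) < 3:
        raise InsufficientSignalError(f"only {len(idx)} R-peaks found")
    times = np.empty(len(idx))
    for j, i in enumerate(idx):
        delta, _ = _parabolic_refine(ecg, int(i))
        times[j] = (i + delta) / sampling_rate
    return times


def beat_windows(r_times: np.ndarray, duration: float,
                 rel_window: tuple[float, float]) -> np.ndarray:
    """Per-beat search windows [r + lo, min(r + hi, next_r - 0.01)]."""
    r = np.asarray(r_times, dtype=float)
    lo, hi = rel_window
    nxt = np.empty_like(r)
    nxt[:-1] = r[1:]
    nxt[-1] = min(r[-1] + (np.median(np.diff(r)) if len(r) > 1 else hi + 0.02), duration)
    starts = r + lo
    ends = np.minimum(r + hi, nxt - 0.01)
    return np.column_stack([starts, np.minimum(ends, duration)])


def _window_slice(n: int, fs: float, window: tuple[float, float]) -> tuple[int, int]:
    i0 = max(int(np.ceil(window[0] * fs)), 0)
    i1 = min(int(np.floor(window[1] * fs)) + 1, n)
    return i0, i1


def detect_valve_opening(doppler_env: np.ndarray, sampling_rate: float,
                         search_windows: np.ndarray,
                         frac: float = 0.10,
                         smooth_ms: float = 15.0) -> np.ndarray:
    """Valve-opening times: fractional-amplitude crossing of the (smoothed)
    envelope, linearly extrapolated back to baseline.  Beats without a
    burst -> NaN."""
    x = np.asarray(doppler_env, dtype=float)
    fs = sampling_rate
    out = np.full(len(search_windows), np.nan)
    for b, win in enumerate(search_windows):
        i0, i1 = _window_slice(len(x), fs, win)
        if i1 - i0 < max(int(0.03 * fs), 8):
            continue
        seg = x[i0:i1]
        nb = max(int(round(0.015 * fs)), 5)
        base = seg[:nb]
        b0 = float(np.mean(base))
        sigma = 1.4826 * float(np.median(np.abs(base - b0)))
        swin = max(int(round(smooth_ms * fs / 1000.0)) | 1, 5)
        sm = savgol_filter(seg, swin, 2) if swin < len(seg) else seg
        amp = float(np.max(sm)) - b0
        if amp < 8.0 * sigma + 1e-9:
            continue  # no burst in this window
        if frac <= 0.0:
            above = np.nonzero(seg[nb:] > b0 + max(3.0 * sigma, 1e-12))[0]
            if len(above) == 0:
                continue
            out[b] = (i0 + nb + above[0] - 1) / fs  # last sample at baseline
            continue
        thr = b0 + frac * amp
        above = np.nonzero(sm >= thr)[0]
        above = above[above >= nb]
        if len(above) == 0:
            continue
        j = int(above[0])
        if j > 0 and sm[j] != sm[j - 1]:
            t_c = (i0 + j - 1 + (thr - sm[j - 1]) / (sm[j] - sm[j - 1])) / fs
        else:
            t_c = (i0 + j) / fs
        # local slope of the smoothed envelope around the crossing
        lo = max(j - 4, 0)
        hi = min(j + 5, len(seg))
        slope = (float(np.polyfit(np.arange(lo, hi) / fs, sm[lo:hi], 1)[0])
                 if hi - lo >= 3 else 0.0)
        if slope > 0:
            out[b] = min(max(t_c - (thr - b0) / slope, win[0]), t_c)
        else:
            out[b] = t_c
    return out


def _foot_in_window(x: np.ndarray, fs: float, i0: int, i1: int,
                    cfg: DetectorConfig) -> float:
    seg = x[i0:i1]
    if len(seg) < max(int(0.05 * fs), 16):
        return np.nan
    win = int(round(cfg.smooth_ms * fs / 1000.0))
    win = max(win | 1, 5)  # odd, >= 5
    if win >= len(seg):
        return np.nan
    sm = savgol_filter(seg, win, 2)
    deriv = savgol_filter(seg, win, 2, deriv=1) * fs

    b_rough = float(np.percentile(sm, 10))
    amp = float(np.max(sm)) - b_rough
    resid = seg - sm
    sigma = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    if amp < 8.0 * sigma + 1e-9:
        return np.nan  # flat window, no upstroke

    ipk = int(np.argmax(sm))
    if ipk < 2:
        return np.nan
    im = int(np.argmax(deriv[:ipk + 1]))
    smax = float(deriv[im])

    # pre-upstroke baseline: segment safely before the first departure
    low = np.nonzero(sm[:im + 1] < b_rough + 0.05 * amp)[0]
    if len(low) > 0:
        j_on = int(low[-1])
        s0 = max(j_on - int(0.07 * fs), 0)
        s1 = max(j_on - int(0.005 * fs), s0 + 1)
    else:
        s0, s1 = 0, max(int(0.02 * fs), 5)
    b0 = float(np.mean(seg[s0:s1]))

    # upstroke must rise significantly above baseline slope noise
    sigma_d = 1.4826 * float(np.median(np.abs(deriv[s0:s1] - np.median(deriv[s0:s1]))))
    if smax <= 0 or smax <= 6.0 * sigma_d:
        return np.nan

    if cfg.foot_method == "second_derivative":
        acc = savgol_filter(seg, win, 3, deriv=2) * fs * fs
        ia = int(np.argmax(acc[:im + 1]))
        delta, _ = _parabolic_refine(acc, ia)
        return (i0 + ia + delta) / fs

    # tangent slope and location: least-squares parabola on the smoothed
    # derivative around its maximum (robust to pointwise derivative noise)
    half = max(int(round(cfg.slope_fit_ms * fs / 1000.0)), 2)
    lo = max(im - half, 1)
    hi = min(im + half + 1, len(deriv) - 1)
    if hi - lo >= 5:
        pcoef = np.polyfit(np.arange(lo, hi, dtype=float), deriv[lo:hi], 2)
        if pcoef[0] < 0:
            pos = float(np.clip(-pcoef[1] / (2.0 * pcoef[0]), lo, hi - 1))
            s_ref = float(np.polyval(pcoef, pos))
        else:
            pos, s_ref = float(im), float(deriv[im])
        delta = pos - im
    else:
        delta, s_ref = _parabolic_refine(deriv, im)
    t_m = (i0 + im + delta) / fs
    # smoothed amplitude at the tangent point
    x_m = float(np.interp(im + delta, np.arange(len(sm)), sm))
    if s_ref <= 0:
        return np.nan
    foot = t_m - (x_m - b0) / s_ref
    if not (i0 / fs - 0.002 <= foot <= t_m):
        return np.nan
    return foot


def detect_pulse_foot(cuff: np.ndarray, sampling_rate: float,
                      search_windows: np.ndarray,
                      config: DetectorConfig | None = None) -> np.ndarray:
    """Pulse-arrival times via intersecting tangents; flagged beats -> NaN."""
    cfg = config or DetectorConfig()
    x = np.asarray(cuff, dtype=float)
    out = np.full(len(search_windows), np.nan)
    for b, win in enumerate(search_windows):
        i0, i1 = _window_slice(len(x), sampling_rate, win)
        out[b] = _foot_in_window(x, sampling_rate, i0, i1, cfg)
    return out


def assemble_fiducials(r_times, valve_times, foot_times,
                       subject_id: str | None = None) -> FiducialSet:
    """Greedy per-beat matching of detected events into a FiducialSet.

    Inputs must be time-sorted (NaN marks an already-flagged beat).  Each
    R-peak is paired with the first valve and foot event before the next
    R-peak; beats violating t_r < t_valve < t_foot are flagged.
    """
    r = np.asarray(r_times, dtype=float)
    valve = np.asarray(valve_times, dtype=float)
    foot = np.asarray(foot_times, dtype=float)
    if len(r) == 0:
        raise InsufficientSignalError("no R-peaks to assemble")
    for name, arr in (("r_times", r), ("valve_times", valve), ("foot_times", foot)):
        finite = arr[np.isfinite(arr)]
        if np.any(np.diff(finite) < 0):
            raise InvalidInputError(f"{name} must be time-sorted")

    horizon = np.empty_like(r)
    horizon[:-1] = r[1:]
    horizon[-1] = r[-1] + (np.median(np.diff(r)) if len(r) > 1 else np.inf)

    rows = []
    v_fin = valve[np.isfinite(valve)]
    f_fin = foot[np.isfinite(foot)]
    for i, tr in enumerate(r):
        tv = tf = np.nan
        cand_v = v_fin[(v_fin > tr) & (v_fin < horizon[i])]
        if len(cand_v):
            tv = float(cand_v[0])
            cand_f = f_fin[(f_fin > tv) & (f_fin < horizon[i])]
            if len(cand_f):
                tf = float(cand_f[0])
        valid = bool(np.isfinite(tv) and np.isfinite(tf) and tr < tv < tf)
        rows.append((i, tr, tv, tf, valid))
    frame = pd.DataFrame(rows, columns=FIDUCIAL_COLUMNS)
    if not frame["valid"].any():
        raise InsufficientSignalError("zero valid beats after assembly")
    return FiducialSet(frame=frame, subject_id=subject_id)


def detect_fiducials(bundle: WaveformBundle,
                     config: DetectorConfig | None = None) -> FiducialSet:
    """Full detection on one bundle: R-peaks, windows, valve, foot, assembly."""
    cfg = config or DetectorConfig()
    fs = bundle.sampling_rate
    r = detect_r_peaks(bundle.channels["ecg"], fs,
                       k_mad=cfg.k_mad, refractory=cfg.refractory)
    w_valve = beat_windows(r, bundle.duration, cfg.valve_window)
    w_foot = beat_windows(r, bundle.duration, cfg.foot_window)
    valve = detect_valve_opening(bundle.channels["doppler_env"], fs, w_valve,
                                 frac=cfg.envelope_frac,
                                 smooth_ms=cfg.envelope_smooth_ms)
    foot = detect_pulse_foot(bundle.channels["cuff"], fs, w_foot, cfg)
    return assemble_fiducials(r, valve, foot, subject_id=bundle.subject_id)
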