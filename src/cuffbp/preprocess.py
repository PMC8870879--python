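"""Signal cleaning and fiducial-point detection for ECG/PPG records.

The cleaning chain is: powerline notch (zero-phase IIR), linear-phase
FIR band-pass (causal, compensated by an integer ``order/2`` shift),
centered moving-average smoothing, baseline removal and min-max
normalization.  QRS complexes are located with a Pan-Tompkins style
detector (band-pass, five-point derivative, squaring, 150 ms
moving-window integration, dual adaptive thresholds with search-back
and a 200 ms refractory period).  PPG landmarks (foot, systolic peak,
dicrotic notch, diastolic peak, maximum-slope point) are found per
beat on a Daubechies-3 wavelet-denoised pulse, together with the
first-derivative interval dT, the crest time, and the second-derivative
a-e points used as arterial-stiffness markers.

Sample indices are 0-based; intervals are half-open; times are
``index / fs`` seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps

__all__ = [
    "WaveformRecord",
    "FilterSpec",
    "FiducialSet",
    "DegenerateSignalError",
    "filter_ecg",
    "compensate_group_delay",
    "remove_baseline",
    "normalize_signal",
    "detect_r_peaks",
    "wavelet_denoise",
    "detect_ppg_fiducials",
    "detect_ecg_waves",
    "extract_fiducials",
    "screen_quality",
]


class DegenerateSignalError(ValueError):
    """Raised for inputs the operation is undefined on (e.g. constants)."""


@dataclass
class WaveformRecord:
    """Synchronized ECG/PPG/ABP channels sharing one sampling rate."""

    ecg: np.ndarray
    ppg: np.ndarray
    abp: np.ndarray
    fs: float = 125.0
    record_id: str = ""
    quality_flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.ppg = np.asarray(self.ppg, dtype=float)
        self.abp = np.asarray(self.abp, dtype=float)
        if not (self.ecg.size == self.ppg.size == self.abp.size):
            raise ValueError("channel length mismatch")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return self.ecg.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class FilterSpec:
    """ECG cleaning parameters.

    The FIR order must be even so the linear-phase group delay is an
    integer number of samples and can be compensated exactly.
    """

    fir_order: int = 50
    band: tuple = (0.5, 100.0)
    notch_hz: float = 50.0
    moving_avg_window: int = 5

    def __post_init__(self) -> None:
        if self.fir_order % 2 != 0:
            raise ValueError("fir_order must be even (integer group delay)")
        low, high = self.band
        if not (0 < low < high):
            raise ValueError("band must satisfy 0 < low < high")
        if self.notch_hz not in (50.0, 60.0, 50, 60):
            raise ValueError("notch_hz must be 50 or 60")
        if self.moving_avg_window < 1:
            raise ValueError("moving_avg_window must be >= 1")


@dataclass
class FiducialSet:
    """Per-beat landmark indices for one record.

    Arrays are aligned on beats; missing landmarks are NaN and the
    corresponding ``valid`` entry is False.  ``beat_end`` is the next
    beat's pulse foot, closing the half-open beat interval.
    """

    fs: float
    r_peaks: np.ndarray
    foot: np.ndarray
    systolic_peak: np.ndarray
    dicrotic_notch: np.ndarray
    diastolic_peak: np.ndarray
    max_slope: np.ndarray
    beat_end: np.ndarray
    delta_t: np.ndarray
    crest_time: np.ndarray
    sdppg: dict
    ecg_waves: dict
    notch_fallback: np.ndarray
    valid: np.ndarray
    ecg_durations: dict = field(default_factory=dict)

    @property
    def n_beats(self) -> int:
        # r_peaks holds the full detected train (n_beats + 1 entries)
        return len(self.foot)

    def check_ordering(self) -> None:
        """Assert the landmark ordering invariant on every valid beat."""
        for i in np.flatnonzero(self.valid):
            seq = [self.foot[i], self.systolic_peak[i], self.dicrotic_notch[i],
                   self.diastolic_peak[i]]
            seq = [s for s in seq if np.isfinite(s)]
            if any(b <= a for a, b in zip(seq, seq[1:])):
                raise AssertionError(f"fiducial ordering violated at beat {i}: {seq}")

    def to_dict(self) -> dict:
        def arr(a):
            return [None if not np.isfinite(v) else float(v) for v in np.asarray(a, float)]
        return {
            "fs": self.fs,
            "r_peaks": [int(v) for v in self.r_peaks],
            "foot": arr(self.foot),
            "systolic_peak": arr(self.systolic_peak),
            "dicrotic_notch": arr(self.dicrotic_notch),
            "diastolic_peak": arr(self.diastolic_peak),
            "max_slope": arr(self.max_slope),
            "beat_end": arr(self.beat_end),
            "delta_t": arr(self.delta_t),
            "crest_time": arr(self.crest_time),
            "sdppg": {k: {"index": arr(v[0]), "amplitude": arr(v[1])}
                      for k, v in self.sdppg.items()},
            "ecg_waves": {k: {"index": arr(v[0]), "amplitude": arr(v[1])}
                          for k, v in self.ecg_waves.items()},
            "notch_fallback": [bool(v) for v in self.notch_fallback],
            "valid": [bool(v) for v in self.valid],
        }


# ---------------------------------------------------------------------------
# filtering


def filter_ecg(x, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Notch + causal linear-phase FIR band-pass + centered moving average.

    The FIR stage delays by ``fir_order/2`` samples; callers align with
    :func:`compensate_group_delay`.  An upper band edge at or above the
    Nyquist frequency is clipped to ``0.45*fs`` (the spec default of
    100 Hz cannot be realized at fs=125) and noted in the returned
    array's companion warning.
    """
    spec = spec or FilterSpec()
    x = np.asarray(x, dtype=float)
    if x.size <= 3 * spec.fir_order:
        raise ValueError("signal too short for the requested FIR order")
    low, high = float(spec.band[0]), float(spec.band[1])
    nyq = fs / 2.0
    if low >= nyq:
        raise ValueError(f"band low edge {low} Hz not below Nyquist {nyq} Hz")
    if high >= nyq:
        high = 0.45 * fs
        warnings.warn(f"upper band edge clipped to {high:.1f} Hz (Nyquist {nyq:.1f} Hz)",
                      stacklevel=2)
    # an order-50 kernel cannot realize a 0.5 Hz edge, so the DC offset is
    # removed up front; slow wander is handled by remove_baseline
    y = x - x.mean()
    if spec.notch_hz < nyq:
        b, a = sps.iirnotch(spec.notch_hz, Q=30.0, fs=fs)
        y = sps.filtfilt(b, a, y)
    taps = sps.firwin(spec.fir_order + 1, [low, high], pass_zero=False, fs=fs)
    y = sps.lfilter(taps, 1.0, y)
    if spec.moving_avg_window > 1:
        w = np.ones(spec.moving_avg_window) / spec.moving_avg_window
        y = np.convolve(y, w, mode="same")
    return y


def compensate_group_delay(x, fir_order: int) -> np.ndarray:
    """Advance a causally FIR-filtered signal by ``order/2`` samples."""
    if fir_order % 2 != 0:
        raise ValueError("fir_order must be even")
    if fir_order == 0:
        return np.asarray(x, dtype=float).copy()
    shift = fir_order // 2
    x = np.asarray(x, dtype=float)
    return np.concatenate([x[shift:], np.full(shift, x[-1])])


def remove_baseline(x, fs: float, cutoff_hz: float = 0.3) -> np.ndarray:
    """Zero-phase high-pass removing slow wander and DC offset."""
    if cutoff_hz >= fs / 2:
        raise ValueError("cutoff must be below Nyquist")
    x = np.asarray(x, dtype=float)
    sos = sps.butter(4, cutoff_hz, btype="highpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    return y - y.mean()


def normalize_signal(x) -> np.ndarray:
    """Affine map onto [0, 1]; order-preserving."""
    x = np.asarray(x, dtype=float)
    rng = np.ptp(x)
    if rng == 0:
        raise DegenerateSignalError("cannot normalize a constant signal")
    return (x - x.min()) / rng


# ---------------------------------------------------------------------------
# QRS detection (Pan-Tompkins)


def detect_r_peaks(ecg, fs: float) -> np.ndarray:
    """Pan-Tompkins QRS detector returning one index per beat.

    The returned indices point at the local ECG maximum of each QRS.
    A flat or empty signal yields an empty array.
    """
    x = np.asarray(ecg, dtype=float)
    if x.size < int(fs) or np.ptp(x) == 0 or np.std(x) < 1e-12:
        return np.array([], dtype=int)

    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    kern = np.array([2, 1, 0, -1, -2], dtype=float) * (fs / 8.0)
    deriv = np.convolve(bp, kern[::-1], mode="same")
    squared = deriv * deriv
    win = max(1, int(round(0.150 * fs)))
    integ = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(0.200 * fs))
    cand, _ = sps.find_peaks(integ, distance=refractory)
    if cand.size == 0:
        return np.array([], dtype=int)

    # adaptive dual thresholds with search-back
    spki = float(np.max(integ[: int(2 * fs)])) * 0.5 if integ.size else 0.0
    npki = float(np.mean(integ[: int(2 * fs)])) * 0.5
    accepted: list[int] = []
    rr_hist: list[float] = []
    missed_pool: list[int] = []
    for c in cand:
        thr1 = npki + 0.25 * (spki - npki)
        if integ[c] > thr1:
            if accepted and rr_hist:
                rr_avg = float(np.mean(rr_hist[-8:]))
                if (c - accepted[-1]) > 1.66 * rr_avg and missed_pool:
                    thr2 = 0.5 * thr1
                    back = [m for m in missed_pool if m > accepted[-1] + refractory
                            and integ[m] > thr2]
                    if back:
                        m = max(back, key=lambda i: integ[i])
                        rr_hist.append(m - accepted[-1])
                        accepted.append(m)
            if accepted:
                rr_hist.append(c - accepted[-1])
            accepted.append(c)
            spki = 0.125 * integ[c] + 0.875 * spki
            missed_pool = []
        else:
            npki = 0.125 * integ[c] + 0.875 * npki
            missed_pool.append(c)

    if not accepted:
        return np.array([], dtype=int)

    # refine to the raw-ECG local maximum near each integrated peak
    half = int(round(0.200 * fs))
    refined = []
    for c in accepted:
        lo = max(0, c - half)
        hi = min(x.size, c + int(round(0.05 * fs)) + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.array(sorted(set(refined)), dtype=int)

    # enforce the refractory period on the refined indices
    keep: list[int] = []
    for idx in refined:
        if keep and idx - keep[-1] < refractory:
            if x[idx] > x[keep[-1]]:
                keep[-1] = int(idx)
        else:
            keep.append(int(idx))
    return np.array(keep, dtype=int)


# ---------------------------------------------------------------------------
# PPG fiducials


def wavelet_denoise(x, wavelet: str = "db3", level: int | None = None) -> np.ndarray:
    """Daubechies-3 soft-threshold denoising (universal threshold, MAD scale)."""
    x = np.asarray(x, dtype=float)
    max_level = pywt.dwt_max_level(x.size, pywt.Wavelet(wavelet).dec_len)
    level = min(4, max_level) if level is None else min(level, max_level)
    if level < 1:
        return x.copy()
    coeffs = pywt.wavedec(x, wavelet, level=level)
    sigma = np.median(np.abs(coeffs[-1])) / 0.6745 if coeffs[-1].size else 0.0
    thr = sigma * np.sqrt(2.0 * np.log(max(2, x.size)))
    coeffs = [coeffs[0]] + [pywt.threshold(c, thr, mode="soft") for c in coeffs[1:]]
    y = pywt.waverec(coeffs, wavelet)
    return y[: x.size]


def _refine_extremum(y: np.ndarray, i: int, half: int = 3) -> float:
    """Sub-sample refinement of a discrete extremum.

    Fits a least-squares parabola over ``2*half + 1`` samples; the wider
    window averages out small high-frequency ripple (e.g. from wavelet
    denoising) that would bias a 3-point fit in shallow valleys.
    """
    lo, hi = max(0, i - half), min(y.size, i + half + 1)
    if hi - lo >= 5:
        t = np.arange(lo, hi, dtype=float) - i
        a, b, _ = np.polyfit(t, y[lo:hi], 2)
        if abs(a) > 1e-18:
            delta = -b / (2 * a)
            if -1.5 < delta < 1.5:
                return i + delta
    if 0 < i < y.size - 1:
        denom = y[i - 1] - 2 * y[i] + y[i + 1]
        if abs(denom) > 1e-18:
            delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
            if -1.0 < delta < 1.0:
                return i + delta
    return float(i)


def _local_extrema(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "max":
        idx, _ = sps.find_peaks(x)
    else:
        idx, _ = sps.find_peaks(-x)
    return idx


def _sdppg_points(d2: np.ndarray, start: int, stop: int) -> dict:
    """First alternating extrema max/min/max/min/max of the second derivative."""
    seg = d2[start:stop]
    out = {k: (np.nan, np.nan) for k in "abcde"}
    if seg.size < 5:
        return out
    maxima = set(_local_extrema(seg, "max"))
    minima = set(_local_extrema(seg, "min"))
    order = sorted(maxima | minima)
    want = ["max", "min", "max", "min", "max"]
    names = "abcde"
    pos = 0
    for ext in order:
        if pos >= 5:
            break
        is_max = ext in maxima
        if (want[pos] == "max") == is_max:
            out[names[pos]] = (float(start + ext), float(seg[ext]))
            pos += 1
    return out


def detect_ppg_fiducials(ppg, fs: float, r_peaks) -> FiducialSet:
    """Locate the PPG landmarks for every beat bracketed by two R peaks.

    Beats whose dicrotic notch has no local minimum fall back to the
    second-derivative maximum between the systolic and diastolic
    phases; the beat is flagged.  Beats with inconsistent ordering are
    marked invalid rather than repaired.
    """
    x = np.asarray(ppg, dtype=float)
    r = np.asarray(r_peaks, dtype=int)
    den = wavelet_denoise(x)
    d1 = np.gradient(den) * fs
    d2 = np.gradient(d1) * fs

    n_beats = max(0, r.size - 1)
    nan = np.full(n_beats, np.nan)
    foot, syst, notch, dias, slope = nan.copy(), nan.copy(), nan.copy(), nan.copy(), nan.copy()
    beat_end, delta_t, crest = nan.copy(), nan.copy(), nan.copy()
    sd = {k: (nan.copy(), nan.copy()) for k in "abcde"}
    fallback = np.zeros(n_beats, dtype=bool)
    valid = np.zeros(n_beats, dtype=bool)

    # provisional systolic peaks and feet for all beats (feet define beat ends)
    for i in range(n_beats):
        lo = r[i] + int(round(0.05 * fs))
        hi = r[i + 1]
        if hi - lo < 3:
            continue
        s_int = lo + int(np.argmax(den[lo:hi]))
        syst[i] = _refine_extremum(den, s_int)
        # the foot may precede the R peak (onset lags R by the PTT while the
        # valley minimum sits before the onset), so search back from the peak
        f_lo = max(0, s_int - int(round(0.55 * (r[i + 1] - r[i]))))
        f_int = f_lo + int(np.argmin(den[f_lo:s_int + 1]))
        foot[i] = _refine_extremum(den, f_int)

    for i in range(n_beats):
        if not np.isfinite(syst[i]) or not np.isfinite(foot[i]):
            continue
        s, f = int(syst[i]), int(foot[i])
        end = int(foot[i + 1]) if i + 1 < n_beats and np.isfinite(foot[i + 1]) else min(
            x.size - 1, r[i + 1] + int(round(0.3 * fs)))
        beat_end[i] = end
        if end <= s + 2 or s <= f:
            continue
        slope[i] = _refine_extremum(d1, f + int(np.argmax(d1[f:s + 1])))
        crest[i] = (syst[i] - foot[i]) / fs

        mins = _local_extrema(den[s:end], "min")
        maxs = _local_extrema(den[s:end], "max")
        if mins.size:
            notch[i] = _refine_extremum(den, s + int(mins[0]))
            after = maxs[maxs > mins[0]]
            if after.size:
                dias[i] = _refine_extremum(den, s + int(after[0]))
        else:
            # weakly pulsatile beat: use the second-derivative maximum
            inner_lo = s + max(1, int(round(0.05 * (end - s))))
            inner_hi = end - max(1, int(round(0.10 * (end - s))))
            if inner_hi > inner_lo + 2:
                notch[i] = inner_lo + int(np.argmax(d2[inner_lo:inner_hi]))
                fallback[i] = True

        # dT: interval between the first two +/- zero crossings of d1
        seg = d1[f:end]
        sign = np.signbit(seg)
        down = np.flatnonzero((~sign[:-1]) & sign[1:])
        if down.size >= 2:
            delta_t[i] = (down[1] - down[0]) / fs

        sdp = _sdppg_points(d2, f, end)
        for k in "abcde":
            sd[k][0][i], sd[k][1][i] = sdp[k]

        seq = [v for v in (foot[i], syst[i], notch[i], dias[i]) if np.isfinite(v)]
        valid[i] = all(b > a for a, b in zip(seq, seq[1:])) and len(seq) >= 2

    return FiducialSet(
        fs=fs, r_peaks=r, foot=foot, systolic_peak=syst,
        dicrotic_notch=notch, diastolic_peak=dias, max_slope=slope,
        beat_end=beat_end, delta_t=delta_t, crest_time=crest,
        sdppg=sd, ecg_waves={}, notch_fallback=fallback, valid=valid)


def _half_amp_width(x: np.ndarray, peak: int, lo: int, hi: int, fs: float) -> float:
    """Width of a wave at half its amplitude over a local baseline."""
    base = 0.5 * (np.median(x[lo:lo + 3]) + np.median(x[hi - 3:hi]))
    amp = x[peak] - base
    if abs(amp) < 1e-12:
        return np.nan
    half = base + 0.5 * amp
    left = peak
    while left > lo and (x[left] - half) * np.sign(amp) > 0:
        left -= 1
    right = peak
    while right < hi - 1 and (x[right] - half) * np.sign(amp) > 0:
        right += 1
    return (right - left) / fs


def detect_ecg_waves(ecg, fs: float, r_peaks) -> dict:
    """P/Q/S/T landmarks with amplitudes and P/QRS/T durations per beat."""
    x = np.asarray(ecg, dtype=float)
    r = np.asarray(r_peaks, dtype=int)
    n = r.size
    nan = np.full(n, np.nan)
    out = {k: (nan.copy(), nan.copy()) for k in "PQST"}
    durations = {"p_dur": nan.copy(), "qrs_dur": nan.copy(), "t_dur": nan.copy()}

    def win(c, a, b):
        return max(0, c + int(round(a * fs))), min(x.size, c + int(round(b * fs)))

    for i, c in enumerate(r):
        qlo, qhi = win(c, -0.06, -0.005)
        slo, shi = win(c, 0.005, 0.06)
        plo, phi = win(c, -0.28, -0.07)
        tlo, thi = win(c, 0.10, 0.45)
        if i + 1 < n:
            thi = min(thi, r[i + 1] - int(round(0.10 * fs)))
        if qhi > qlo:
            q = qlo + int(np.argmin(x[qlo:qhi]))
            out["Q"][0][i], out["Q"][1][i] = q, x[q]
        if shi > slo:
            s = slo + int(np.argmin(x[slo:shi]))
            out["S"][0][i], out["S"][1][i] = s, x[s]
        if phi > plo + 6:
            p = plo + int(np.argmax(x[plo:phi]))
            out["P"][0][i], out["P"][1][i] = p, x[p]
            durations["p_dur"][i] = _half_amp_width(x, p, plo, phi, fs)
        if thi > tlo + 6:
            t = tlo + int(np.argmax(x[tlo:thi]))
            out["T"][0][i], out["T"][1][i] = t, x[t]
            durations["t_dur"][i] = _half_amp_width(x, t, tlo, thi, fs)
        if np.isfinite(out["Q"][0][i]) and np.isfinite(out["S"][0][i]):
            durations["qrs_dur"][i] = (out["S"][0][i] - out["Q"][0][i]) / fs
    out.update(durations)
    return out


def extract_fiducials(record: WaveformRecord, r_peaks=None) -> FiducialSet:
    """Full fiducial extraction on a cleaned record (PPG + ECG waves)."""
    if r_peaks is None:
        r_peaks = detect_r_peaks(record.ecg, record.fs)
    fid = detect_ppg_fiducials(record.ppg, record.fs, r_peaks)
    waves = detect_ecg_waves(record.ecg, record.fs, fid.r_peaks)
    fid.ecg_waves = {k: waves[k] for k in "PQST"}
    fid.ecg_durations = {k: waves[k] for k in ("p_dur", "qrs_dur", "t_dur")}
    return fid


# ---------------------------------------------------------------------------
# quality screening


def screen_quality(record: WaveformRecord,
                   max_missing_fraction: float = 0.05,
                   max_flatline_s: float = 2.0,
                   hr_range: tuple = (30.0, 200.0),
                   abp_range: tuple = (30.0, 250.0)) -> dict:
    """Automated stand-in for manual record screening.

    Flags: excessive missing samples, flat segments longer than
    ``max_flatline_s``, heart rate outside a physiologic band, ABP
    values outside a plausible band.  ``accepted`` is True when no
    flag fires.
    """
    flags: dict = {}
    n = record.n_samples
    fs = record.fs
    total_missing = sum(int(np.isnan(ch).sum()) for ch in
                        (record.ecg, record.ppg, record.abp))
    flags["missing"] = total_missing / max(1, 3 * n) > max_missing_fraction

    win = int(max_flatline_s * fs)
    flags["flatline"] = False
    for ch in (record.ecg, record.ppg, record.abp):
        c = np.nan_to_num(np.asarray(ch, float))
        if c.size >= win:
            step = max(1, win // 4)
            for start in range(0, c.size - win + 1, step):
                seg = c[start:start + win]
                if np.ptp(seg) < 1e-9 * max(1.0, np.ptp(c)):
                    flags["flatline"] = True
                    break
        if flags["flatline"]:
            break

    ecg = np.nan_to_num(record.ecg)
    r = detect_r_peaks(ecg, fs)
    if r.size >= 2:
        hr = 60.0 * fs / np.median(np.diff(r))
        flags["hr_out_of_range"] = not (hr_range[0] <= hr <= hr_range[1])
    else:
        flags["hr_out_of_range"] = True

    abp = record.abp[np.isfinite(record.abp)]
    flags["abp_out_of_range"] = bool(abp.size == 0 or abp.min() < abp_range[0]
                                     or abp.max() > abp_range[1])

    flags["accepted"] = not any(v for k, v in flags.items() if k != "accepted")
    record.quality_flags.update(flags)
    return flags
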