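"""Per-beat feature extraction and window aggregation.

The feature set is morphological: heart rate, pulse transit time,
PPG amplitudes and amplitude ratio, systolic/diastolic times,
fractional pulse widths (diastolic, total, and their ratio at 1/10,
1/4, 1/3, 1/2 of the pulse maximum plus total widths at 2/3 and 3/4),
first-derivative interval dT and crest time, second-derivative ratios
b/a, c/a, e/a, (b-e)/a, and ECG P/QRS/T durations and amplitudes.
Targets (SBP/DBP) are read off the synchronized arterial-pressure
channel as per-beat maxima/minima.

Beats aggregate to analysis windows by the per-feature median
(robust to occasional detection failures); a feature missing in more
than half of a window's beats is masked in the row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import FiducialSet

__all__ = [
    "FeatureTable",
    "FEATURE_NAMES",
    "WIDTH_FRACTIONS",
    "width_at_fraction",
    "extract_beat_features",
    "extract_record_beats",
    "extract_targets_from_abp",
    "aggregate_window",
]

WIDTH_FRACTIONS = {"1_10": 1 / 10, "1_4": 1 / 4, "1_3": 1 / 3, "1_2": 1 / 2,
                   "2_3": 2 / 3, "3_4": 3 / 4}
#: fractions for which diastolic-only widths and D/S ratios are reported
_RATIO_FRACTIONS = ("1_10", "1_4", "1_3", "1_2")

FEATURE_NAMES = (
    ["HR", "PPGMX", "PPGMN", "AC_amp", "PPGIR", "PTT", "S_T", "DT"]
    + [f"Dias_{k}" for k in _RATIO_FRACTIONS]
    + [f"D_S_{k}" for k in WIDTH_FRACTIONS]
    + [f"DS_ratio_{k}" for k in _RATIO_FRACTIONS]
    + ["P_dur", "QRS_dur", "T_dur", "P_amp", "R_amp", "T_amp"]
    + ["delta_T", "crest_time", "b_a", "c_a", "e_a", "be_a"]
)


@dataclass
class FeatureTable:
    """Windows x named features, with explicit missingness and targets."""

    features: pd.DataFrame
    targets: pd.DataFrame
    mask: pd.DataFrame = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = self.features.notna()
        if len(set(self.features.columns)) != len(self.features.columns):
            raise ValueError("duplicate feature column names")

    @property
    def n_rows(self) -> int:
        return len(self.features)

    def complete_rows(self, columns=None) -> "FeatureTable":
        """Drop rows with any masked cell among ``columns`` (default: all)."""
        cols = list(columns) if columns is not None else list(self.features.columns)
        ok = self.mask[cols].all(axis=1) & self.targets.notna().all(axis=1)
        return FeatureTable(self.features.loc[ok, cols].reset_index(drop=True),
                            self.targets.loc[ok].reset_index(drop=True),
                            self.mask.loc[ok, cols].reset_index(drop=True),
                            dict(self.metadata))

    def to_csv(self, path) -> None:
        path = Path(path)
        frame = pd.concat([self.features, self.targets.add_prefix("target_")], axis=1)
        frame.to_csv(path, index=False)
        sidecar = {
            "feature_columns": list(self.features.columns),
            "target_columns": list(self.targets.columns),
            "mask": self.mask.astype(int).values.tolist(),
            "metadata": _jsonable(self.metadata),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        path = Path(path)
        frame = pd.read_csv(path, float_precision="round_trip")
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        feats = frame[sidecar["feature_columns"]]
        targets = frame[[f"target_{c}" for c in sidecar["target_columns"]]]
        targets.columns = sidecar["target_columns"]
        mask = pd.DataFrame(np.asarray(sidecar["mask"], dtype=bool),
                            columns=sidecar["feature_columns"])
        return cls(feats, targets, mask, sidecar["metadata"])


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------


def _cross_time(x: np.ndarray, i: int, j: int, thr: float) -> float:
    """Linear-interpolated crossing position between samples i and j."""
    if x[j] == x[i]:
        return float(i)
    return i + (thr - x[i]) / (x[j] - x[i]) * (j - i)


def width_at_fraction(pulse, foot_idx: int, peak_idx: int, end_idx: int,
                      fraction: float, fs: float):
    """Systolic/diastolic/total pulse width at a fraction of the maximum.

    The threshold is ``fraction`` of the peak amplitude measured above
    the foot baseline; crossings are linearly interpolated between
    samples for sub-sample accuracy.  Returns
    ``(systolic_s, diastolic_s, total_s, diastolic/systolic)``;
    NaNs when the threshold is never crossed (degenerate pulse).
    """
    x = np.asarray(pulse, dtype=float)
    f, p, e = int(foot_idx), int(peak_idx), int(end_idx)
    if not (f < p < e <= x.size - 1 or f < p <= e < x.size):
        return (np.nan,) * 4
    base = x[f]
    amp = x[p] - base
    if amp <= 0:
        return (np.nan,) * 4
    thr = base + fraction * amp

    up = np.nan
    for k in range(p, f, -1):          # last upward crossing before the peak
        if x[k - 1] < thr <= x[k]:
            up = _cross_time(x, k - 1, k, thr)
            break
    down = np.nan
    for k in range(p, min(e, x.size - 1)):  # first downward crossing after
        if x[k] >= thr > x[k + 1]:
            down = _cross_time(x, k, k + 1, thr)
            break
    if not (np.isfinite(up) and np.isfinite(down)):
        return (np.nan,) * 4
    sys_s = (p - up) / fs
    dia_s = (down - p) / fs
    ratio = dia_s / sys_s if sys_s > 0 else np.nan
    return sys_s, dia_s, sys_s + dia_s, ratio


def extract_beat_features(fid: FiducialSet, beat: int, ecg, ppg, fs: float,
                          ptt_anchor: str = "max_slope") -> dict:
    """Feature vector for one beat; missing landmarks yield NaN entries."""
    x = np.asarray(ppg, dtype=float)
    e = np.asarray(ecg, dtype=float)
    out = {name: np.nan for name in FEATURE_NAMES}
    i = beat
    r = fid.r_peaks
    if i + 1 < len(r):
        rr = (r[i + 1] - r[i]) / fs
        if rr > 0:
            out["HR"] = 60.0 / rr

    foot, syst = fid.foot[i], fid.systolic_peak[i]
    end = fid.beat_end[i]
    anchors = {"max_slope": fid.max_slope, "foot": fid.foot,
               "systolic_peak": fid.systolic_peak}
    if ptt_anchor not in anchors:
        raise ValueError(f"unknown PTT anchor {ptt_anchor!r}")
    anc = anchors[ptt_anchor][i]
    if np.isfinite(anc):
        out["PTT"] = (anc - r[i]) / fs

    if np.isfinite(foot) and np.isfinite(syst):
        f, s = int(foot), int(syst)
        out["PPGMX"] = x[s]
        out["PPGMN"] = x[f]
        out["AC_amp"] = x[s] - x[f]
        if x[f] > 0:
            out["PPGIR"] = x[s] / x[f]
        out["S_T"] = (s - f) / fs
        if np.isfinite(end):
            out["DT"] = (end - s) / fs
            for key, frac in WIDTH_FRACTIONS.items():
                sys_s, dia_s, total, ratio = width_at_fraction(x, f, s, int(end), frac, fs)
                out[f"D_S_{key}"] = total
                if key in _RATIO_FRACTIONS:
                    out[f"Dias_{key}"] = dia_s
                    out[f"DS_ratio_{key}"] = ratio

    out["delta_T"] = fid.delta_t[i]
    out["crest_time"] = fid.crest_time[i]

    a_amp = fid.sdppg["a"][1][i]
    if np.isfinite(a_amp) and abs(a_amp) > 1e-12:
        b, c, eamp = (fid.sdppg[k][1][i] for k in "bce")
        out["b_a"] = b / a_amp
        out["c_a"] = c / a_amp
        out["e_a"] = eamp / a_amp
        if np.isfinite(b) and np.isfinite(eamp):
            out["be_a"] = (b - eamp) / a_amp

    if fid.ecg_durations:
        out["P_dur"] = fid.ecg_durations["p_dur"][i]
        out["QRS_dur"] = fid.ecg_durations["qrs_dur"][i]
        out["T_dur"] = fid.ecg_durations["t_dur"][i]
    if fid.ecg_waves:
        out["P_amp"] = fid.ecg_waves["P"][1][i]
        out["T_amp"] = fid.ecg_waves["T"][1][i]
    out["R_amp"] = e[int(r[i])] if i < len(r) else np.nan
    return out


def extract_targets_from_abp(abp, beat_bounds, fs: float) -> pd.DataFrame:
    """Per-beat SBP (max) and DBP (min) from calibrated arterial pressure."""
    a = np.asarray(abp, dtype=float)
    rows = []
    for lo, hi in beat_bounds:
        if not (np.isfinite(lo) and np.isfinite(hi)) or int(hi) <= int(lo):
            rows.append((np.nan, np.nan))
            continue
        seg = a[int(lo):int(hi) + 1]
        rows.append((float(np.nanmax(seg)), float(np.nanmin(seg))))
    return pd.DataFrame(rows, columns=["sbp", "dbp"])


def extract_record_beats(record, fid: FiducialSet,
                         ptt_anchor: str = "max_slope") -> pd.DataFrame:
    """Per-beat feature + target frame for a cleaned record."""
    rows = []
    for i in range(fid.n_beats):
        feats = extract_beat_features(fid, i, record.ecg, record.ppg,
                                      record.fs, ptt_anchor)
        feats["time_s"] = fid.r_peaks[i] / record.fs
        rows.append(feats)
    beats = pd.DataFrame(rows)
    bounds = list(zip(fid.foot, fid.beat_end))
    targets = extract_targets_from_abp(record.abp, bounds, record.fs)
    return pd.concat([beats, targets], axis=1)


def aggregate_window(beats: pd.DataFrame, window_s: float = 60.0,
                     min_beats: int = 5, record_id: str = "") -> FeatureTable:
    """Median-aggregate per-beat rows into analysis windows.

    Windows with fewer than ``min_beats`` usable beats are dropped; a
    feature present in fewer than half the window's beats is masked.
    """
    if "time_s" not in beats:
        raise ValueError("beats frame must carry a time_s column")
    feature_cols = [c for c in beats.columns if c not in ("time_s", "sbp", "dbp")]
    win_idx = (beats["time_s"] // window_s).astype(int)
    feat_rows, targ_rows, mask_rows, meta_rows = [], [], [], []
    for w, grp in beats.groupby(win_idx):
        if len(grp) < min_beats:
            continue
        med = grp[feature_cols].median()
        present = grp[feature_cols].notna().mean() > 0.5
        med[~present] = np.nan
        feat_rows.append(med)
        targ_rows.append(grp[["sbp", "dbp"]].median())
        mask_rows.append(present)
        meta_rows.append({"record_id": record_id, "window": int(w),
                          "n_beats": int(len(grp))})
    if not feat_rows:
        return FeatureTable(pd.DataFrame(columns=feature_cols),
                            pd.DataFrame(columns=["sbp", "dbp"]),
                            pd.DataFrame(columns=feature_cols).astype(bool),
                            {"windows": []})
    features = pd.DataFrame(feat_rows).reset_index(drop=True)
    targets = pd.DataFrame(targ_rows).reset_index(drop=True)
    mask = pd.DataFrame(mask_rows).reset_index(drop=True) & features.notna()
    return FeatureTable(features, targets, mask, {"windows": meta_rows})


def concat_tables(tables) -> FeatureTable:
    """Stack per-record FeatureTables into one cohort table."""
    tables = [t for t in tables if t.n_rows > 0]
    if not tables:
        raise ValueError("no non-empty tables to concatenate")
    features = pd.concat([t.features for t in tables], ignore_index=True)
    targets = pd.concat([t.targets for t in tables], ignore_index=True)
    mask = pd.concat([t.mask for t in tables], ignore_index=True)
    meta = {"windows": sum((t.metadata.get("windows", []) for t in tables), [])}
    return FeatureTable(features, targets, mask, meta)
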