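"""Readers and writers for waveform records and sidecar metadata.

Records are stored as a 3-row matrix (one channel per row) in
delimited text or, optionally, a MATLAB container.  The default row
order follows the re-hosted waveform-dump convention (PPG, ABP, ECG);
two alternative layouts are accepted.  Ground truth and fiducial sets
travel as JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .preprocess import WaveformRecord

__all__ = ["LAYOUTS", "write_record_matrix", "read_record_matrix"]

LAYOUTS = {
    "rows-ppg-abp-ecg": ("ppg", "abp", "ecg"),
    "rows-ecg-ppg-abp": ("ecg", "ppg", "abp"),
    "columns": ("ppg", "abp", "ecg"),  # columns in the dump order
}


def write_record_matrix(record: WaveformRecord, path,
                        layout: str = "rows-ppg-abp-ecg") -> None:
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}")
    order = LAYOUTS[layout]
    mat = np.vstack([getattr(record, ch) for ch in order])
    if layout == "columns":
        mat = mat.T
    path = Path(path)
    if path.suffix == ".mat":
        from scipy.io import savemat
        savemat(path, {"data": mat, "fs": record.fs})
    else:
        np.savetxt(path, mat, delimiter=",", fmt="%.17g")


def read_record_matrix(path, layout: str = "rows-ppg-abp-ecg",
                       fs: float = 125.0, record_id: str | None = None,
                       max_nan_fraction: float = 0.05) -> WaveformRecord:
    """Load a 3-channel record; channel roles follow ``layout``.

    Raises on a wrong channel count or when more than
    ``max_nan_fraction`` of the samples are missing.
    """
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".mat":
        from scipy.io import loadmat
        d = loadmat(path)
        mat = np.asarray(d["data"], dtype=float)
        if "fs" in d:
            fs = float(np.ravel(d["fs"])[0])
    else:
        mat = np.loadtxt(path, delimiter=",", dtype=float)
    if layout == "columns":
        mat = mat.T
    if mat.ndim != 2 or mat.shape[0] != 3:
        raise ValueError(f"expected 3 channels, found shape {mat.shape}")
    nan_frac = float(np.isnan(mat).mean())
    if nan_frac > max_nan_fraction:
        raise ValueError(f"NaN density {nan_frac:.1%} exceeds {max_nan_fraction:.0%}")
    channels = dict(zip(LAYOUTS[layout], mat))
    return WaveformRecord(ecg=channels["ecg"], ppg=channels["ppg"],
                          abp=channels["abp"], fs=fs,
                          record_id=record_id or path.stem)


def write_truth(truth, path) -> None:
    d = {
        "r_peak_times": np.asarray(truth.r_peak_times, float).tolist(),
        "ppg_fiducial_times": {k: np.asarray(v, float).tolist()
                               for k, v in truth.ppg_fiducial_times.items()},
        "sbp_true": truth.sbp_true, "dbp_true": truth.dbp_true,
        "covariates": truth.covariates,
        "generating_coefficients": truth.generating_coefficients,
    }
    Path(path).write_text(json.dumps(d, indent=1))
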