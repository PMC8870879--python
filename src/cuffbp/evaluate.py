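"""Error metrics and standards-based grading of BP predictions.

Errors are defined as predicted minus reference (mmHg).  BHS grading
uses the cumulative percentage of absolute errors within 5, 10 and
15 mmHg against the published threshold grid (A: 60/85/95, B:
50/75/90, C: 40/65/85, else D).  The AAMI check (|mean error| <= 5
and sd <= 8 mmHg) uses thresholds from that standard, not from the
grading grid, and is reported as advisory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["EvaluationReport", "rmse_mae", "bhs_grade", "aami_check", "evaluate"]

BHS_THRESHOLDS = {
    "A": (60.0, 85.0, 95.0),
    "B": (50.0, 75.0, 90.0),
    "C": (40.0, 65.0, 85.0),
}


@dataclass
class EvaluationReport:
    target: str
    n: int
    rmse: float
    mae: float
    mean_error: float
    sd_error: float
    bhs_cum: dict
    bhs_grade: str
    aami_pass: bool

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def summary(self) -> str:
        c = self.bhs_cum
        return (f"{self.target}: RMSE {self.rmse:.2f} mmHg, MAE {self.mae:.2f} mmHg, "
                f"ME {self.mean_error:+.2f} +/- {self.sd_error:.2f} mmHg | "
                f"BHS {self.bhs_grade} "
                f"({c['within5']:.1f}/{c['within10']:.1f}/{c['within15']:.1f}% "
                f"within 5/10/15) | AAMI {'pass' if self.aami_pass else 'fail'} "
                f"(n={self.n})")


def _errors(pred, true) -> np.ndarray:
    p = np.asarray(pred, dtype=float).ravel()
    t = np.asarray(true, dtype=float).ravel()
    if p.size != t.size or p.size == 0:
        raise ValueError("pred and true must have equal, non-zero length")
    return p - t


def rmse_mae(pred, true):
    """(rmse, mae, mean_error, sd_error) in mmHg."""
    e = _errors(pred, true)
    rmse = float(np.sqrt(np.mean(e ** 2)))
    mae = float(np.mean(np.abs(e)))
    return rmse, mae, float(np.mean(e)), float(np.std(e, ddof=1)) if e.size > 1 else 0.0


def bhs_grade(errors):
    """Cumulative within-5/10/15 percentages and the best grade met."""
    a = np.abs(np.asarray(errors, dtype=float).ravel())
    if a.size == 0:
        raise ValueError("empty error vector")
    cum = {f"within{t}": float(100.0 * np.mean(a <= t)) for t in (5, 10, 15)}
    grade = "D"
    for g in ("C", "B", "A"):  # ascending strictness; keep the best satisfied
        t5, t10, t15 = BHS_THRESHOLDS[g]
        if cum["within5"] >= t5 and cum["within10"] >= t10 and cum["within15"] >= t15:
            grade = g
    return cum, grade


def aami_check(errors, mean_limit: float = 5.0, sd_limit: float = 8.0):
    """(mean_error, sd_error, pass) per the device-accuracy convention."""
    e = np.asarray(errors, dtype=float).ravel()
    if e.size < 2:
        raise ValueError("need at least two errors")
    me, sd = float(np.mean(e)), float(np.std(e, ddof=1))
    return me, sd, bool(abs(me) <= mean_limit and sd <= sd_limit)


def evaluate(pred, true, target: str = "sbp") -> EvaluationReport:
    e = _errors(pred, true)
    rmse, mae, me, sd = rmse_mae(pred, true)
    cum, grade = bhs_grade(e)
    _, _, ok = aami_check(e) if e.size >= 2 else (me, 0.0, False)
    return EvaluationReport(target=target, n=int(e.size), rmse=rmse, mae=mae,
                            mean_error=me, sd_error=sd, bhs_cum=cum,
                            bhs_grade=grade, aami_pass=ok)
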