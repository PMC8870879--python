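"""Synthetic cohorts with known fiducials and a known BP-generating model.

Two generators live here:

* waveform cohorts — per subject, an ECG built from Gaussian bumps for
  the P/Q/R/S/T waves, a PPG whose pulse is the sum of a systolic and
  a delayed diastolic bump (guaranteeing a dicrotic notch between
  them), and an ABP channel that is the same pulse rescaled so its
  per-beat maximum/minimum equal the record's true SBP/DBP.  SBP and
  DBP follow a known model with one deliberately nonlinear term:

      SBP = c0 + c1*(1/PTT) + c2*HR + c3*W50 + c4*exp(-W10/tau) + eps

  (DBP analogous with its own weights), where W50/W10 are the pulse's
  true fractional-amplitude widths.  Every landmark time is recorded
  from the analytic pulse template, so detector accuracy can be scored
  exactly.

* planted-structure feature tables — a target built from linear
  components, symmetric nonlinear components (square / sine / absolute
  value, each with ~zero linear correlation to its source), optional
  product interactions, noisy duplicate columns, and pure-noise
  columns, with every column's role recorded in metadata.  Each
  planted component is standardized to unit variance before weighting
  so equal effect sizes mean equal contribution shares.

All randomness flows from one seed via ``numpy.random.SeedSequence``;
identical configurations are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import FeatureTable
from .preprocess import WaveformRecord

__all__ = [
    "BPModel",
    "SynthCohortConfig",
    "GroundTruth",
    "generate_ecg",
    "generate_ppg_abp",
    "generate_record",
    "generate_cohort",
    "generate_feature_table",
]


@dataclass(frozen=True)
class BPModel:
    """Coefficients of the BP-generating function (per target)."""

    intercept: float
    inv_ptt: float
    hr: float
    w50: float
    w10_exp: float
    tau: float = 0.3

    def value(self, ptt: float, hr: float, w50: float, w10: float) -> float:
        return (self.intercept + self.inv_ptt / ptt + self.hr * hr
                + self.w50 * w50 + self.w10_exp * np.exp(-w10 / self.tau))


DEFAULT_SBP_MODEL = BPModel(intercept=55.0, inv_ptt=9.0, hr=0.35, w50=25.0, w10_exp=15.0)
DEFAULT_DBP_MODEL = BPModel(intercept=40.0, inv_ptt=4.0, hr=0.15, w50=10.0, w10_exp=8.0)


@dataclass
class SynthCohortConfig:
    n_subjects: int = 10
    duration_s: float = 60.0
    fs: float = 125.0
    hr_range: tuple = (60.0, 100.0)
    ptt_range: tuple = (0.15, 0.35)
    noise_sd: float = 0.02
    bp_noise_sd: float = 3.0
    abp_noise_sd: float = 0.0
    sbp_model: BPModel = DEFAULT_SBP_MODEL
    dbp_model: BPModel = DEFAULT_DBP_MODEL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("fs and duration_s must be positive")
        lo, hi = self.hr_range
        if not (30.0 <= lo <= hi <= 200.0):
            raise ValueError("hr_range must lie within [30, 200] bpm")
        lo, hi = self.ptt_range
        if not (0 < lo <= hi):
            raise ValueError("ptt_range must be positive")
        if self.noise_sd < 0 or self.bp_noise_sd < 0:
            raise ValueError("noise levels must be non-negative")


@dataclass
class GroundTruth:
    """Everything the generator knows exactly about one record."""

    r_peak_times: np.ndarray = None
    ppg_fiducial_times: dict = field(default_factory=dict)
    sbp_true: float = np.nan
    dbp_true: float = np.nan
    covariates: dict = field(default_factory=dict)
    generating_coefficients: dict = field(default_factory=dict)


# ECG bump template: (amplitude, offset from R in s, width in s)
_ECG_WAVES = {
    "P": (0.12, -0.16, 0.022),
    "Q": (-0.12, -0.035, 0.008),
    "R": (1.00, 0.0, 0.012),
    "S": (-0.18, 0.035, 0.008),
    "T": (0.28, 0.28, 0.045),
}


def _add_bumps(signal: np.ndarray, fs: float, centers_s: np.ndarray,
               amp: float, sigma_s: float) -> None:
    half = int(np.ceil(4 * sigma_s * fs))
    n = signal.size
    for c in centers_s:
        ci = int(round(c * fs))
        lo, hi = max(0, ci - half), min(n, ci + half + 1)
        if hi <= lo:
            continue
        t = np.arange(lo, hi) / fs
        signal[lo:hi] += amp * np.exp(-0.5 * ((t - c) / sigma_s) ** 2)


def generate_ecg(config: SynthCohortConfig, rng: np.random.Generator | None = None,
                 hr: float | None = None):
    """One record's ECG and its exact R-peak schedule.

    The beat schedule is deterministic given the heart rate: the first
    R peak sits at 0.4 s and subsequent peaks follow at exactly one RR
    interval.  Optional contamination: white noise (sd = ``noise_sd``
    of the unit R amplitude), <0.5 Hz baseline drift, and a powerline
    sinusoid.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if hr is None:
        hr = float(rng.uniform(*config.hr_range))
    if not (config.hr_range[0] <= hr <= config.hr_range[1]):
        raise ValueError("hr outside configured hr_range")
    rr = 60.0 / hr
    r_times = np.arange(0.4, config.duration_s, rr)
    n = int(round(config.duration_s * config.fs))
    ecg = np.zeros(n)
    for amp, off, sig in _ECG_WAVES.values():
        _add_bumps(ecg, config.fs, r_times + off, amp, sig)
    if config.noise_sd > 0:
        t = np.arange(n) / config.fs
        ecg = ecg + rng.normal(0.0, config.noise_sd, n)
        ecg = ecg + 3 * config.noise_sd * np.sin(
            2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
        ecg = ecg + config.noise_sd * np.sin(
            2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
    truth = GroundTruth(r_peak_times=r_times, covariates={"hr": hr, "rr": rr})
    return ecg, truth


def _pulse_template(rr: float, rng: np.random.Generator):
    """Per-subject two-bump pulse parameters (seconds, relative to onset)."""
    u = rng.uniform(0.9, 1.1, size=4)
    params = {
        "sigma_sys": 0.085 * rr * u[0],
        "t_sys": 0.20 * rr * u[1],
        "t_dia": 0.58 * rr * u[2],
        "sigma_dia": 0.11 * rr * u[3],
        "amp_dia": float(rng.uniform(0.30, 0.45)),
        # broad base component: keeps the inter-pulse valley curved so the
        # pulse foot is a unique, well-defined minimum
        "amp_base": 0.25,
        "t_base": 0.32 * rr,
        "sigma_base": 0.30 * rr,
    }
    return params


def _template_value(tau: np.ndarray, p: dict) -> np.ndarray:
    g1 = np.exp(-0.5 * ((tau - p["t_sys"]) / p["sigma_sys"]) ** 2)
    g2 = p["amp_dia"] * np.exp(-0.5 * ((tau - p["t_dia"]) / p["sigma_dia"]) ** 2)
    g0 = p["amp_base"] * np.exp(-0.5 * ((tau - p["t_base"]) / p["sigma_base"]) ** 2)
    return g0 + g1 + g2


def _periodic_value(tau: np.ndarray, p: dict, rr: float) -> np.ndarray:
    out = np.zeros_like(tau, dtype=float)
    for k in (-2, -1, 0, 1, 2):
        out += _template_value(tau - k * rr, p)
    return out


def _template_landmarks(p: dict, rr: float, oversample: int = 40):
    """Analytic landmark times (relative to pulse onset) on a fine grid."""
    dt = rr / (4000 * max(1, oversample // 40))
    tt = np.arange(-0.5 * rr, 1.2 * rr, dt)
    g = _periodic_value(tt, p, rr)

    sys_zone = (tt >= 0) & (tt <= 0.5 * rr)
    t_sys = tt[sys_zone][np.argmax(g[sys_zone])]
    foot_zone = (tt >= t_sys - 0.9 * rr) & (tt <= t_sys)
    t_foot = tt[foot_zone][np.argmin(g[foot_zone])]
    mid_zone = (tt > t_sys) & (tt < p["t_dia"] + 0.05 * rr)
    t_notch = tt[mid_zone][np.argmin(g[mid_zone])]
    dia_zone = (tt > t_notch) & (tt < t_notch + 0.45 * rr)
    t_dia = tt[dia_zone][np.argmax(g[dia_zone])]
    up_zone = (tt > t_foot) & (tt < t_sys)
    grad = np.gradient(g, dt)
    t_slope = tt[up_zone][np.argmax(grad[up_zone])]

    # fractional widths of one full beat (foot to foot+RR)
    beat = (tt >= t_foot) & (tt < t_foot + rr)
    tb, gb = tt[beat], g[beat]
    base = gb[0]
    amp = g[np.searchsorted(tt, t_sys)] - base
    widths = {}
    for name, frac in (("w10", 0.10), ("w50", 0.50)):
        thr = base + frac * amp
        above = gb >= thr
        if above.any():
            widths[name] = float(tb[above][-1] - tb[above][0])
        else:
            widths[name] = np.nan
    marks = {"foot": float(t_foot), "systolic_peak": float(t_sys),
             "dicrotic_notch": float(t_notch), "diastolic_peak": float(t_dia),
             "max_slope": float(t_slope)}
    return marks, widths


def generate_ppg_abp(config: SynthCohortConfig, r_peak_times,
                     rng: np.random.Generator | None = None,
                     ptt: float | None = None):
    """PPG + ABP for a given R-peak schedule, with exact landmark truth."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    r_times = np.asarray(r_peak_times, dtype=float)
    if r_times.size < 2 or np.any(np.diff(r_times) <= 0):
        raise ValueError("r_peak_times must be increasing with >= 2 beats")
    if ptt is None:
        ptt = float(rng.uniform(*config.ptt_range))
    if ptt <= 0:
        raise ValueError("sampled PTT must be positive")
    rr = float(np.median(np.diff(r_times)))
    hr = 60.0 / rr
    params = _pulse_template(rr, rng)
    marks, widths = _template_landmarks(params, rr)

    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs
    onsets = r_times + ptt
    ppg_clean = np.zeros(n)
    span = int(np.ceil(1.6 * rr * config.fs))
    # lead-in and tail pulses keep the train periodic at the record edges,
    # so the first/last beats' valleys match the analytic template
    synth_onsets = np.concatenate([[onsets[0] - rr], onsets, [onsets[-1] + rr]])
    for o in synth_onsets:
        ci = int(round(o * config.fs))
        lo, hi = max(0, ci - span // 3), min(n, ci + span)
        if hi <= lo:
            continue
        ppg_clean[lo:hi] += _template_value(t[lo:hi] - o, params)

    sbp_model, dbp_model = config.sbp_model, config.dbp_model
    eps_s = rng.normal(0.0, config.bp_noise_sd) if config.bp_noise_sd > 0 else 0.0
    eps_d = rng.normal(0.0, config.bp_noise_sd) if config.bp_noise_sd > 0 else 0.0
    sbp = sbp_model.value(ptt, hr, widths["w50"], widths["w10"]) + eps_s
    dbp = dbp_model.value(ptt, hr, widths["w50"], widths["w10"]) + eps_d

    # ABP is the clean pulse rescaled to [DBP, SBP]; the rescaling is done
    # per beat (foot to foot) so every beat's sampled extremes equal the
    # true SBP/DBP exactly despite sampling-phase drift across beats
    interior = (t > onsets[0]) & (t < onsets[-1])
    ref = ppg_clean[interior] if interior.any() else ppg_clean
    pmin, pmax = float(ref.min()), float(ref.max())
    p_norm = np.clip((ppg_clean - pmin) / max(pmax - pmin, 1e-12), 0.0, 1.0)
    foot_rel = marks["foot"]
    foot_idx = np.round((onsets + foot_rel) * config.fs).astype(int)
    foot_idx = foot_idx[(foot_idx > 0) & (foot_idx < n)]
    bounds = np.concatenate([[0], foot_idx, [n]])
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        seg = p_norm[lo:hi]
        if seg.size and seg.max() > seg.min():
            p_norm[lo:hi] = (seg - seg.min()) / (seg.max() - seg.min())
    abp = dbp + (sbp - dbp) * p_norm
    if config.abp_noise_sd > 0:
        abp = abp + rng.normal(0.0, config.abp_noise_sd, n)

    ppg = ppg_clean
    if config.noise_sd > 0:
        ppg = ppg + rng.normal(0.0, config.noise_sd, n)
        ppg = ppg + 2 * config.noise_sd * np.sin(
            2 * np.pi * 0.3 * t + rng.uniform(0, 2 * np.pi))

    fid_times = {name: onsets + rel for name, rel in marks.items()}
    fid_times["onset"] = onsets.copy()
    truth = GroundTruth(
        r_peak_times=r_times,
        ppg_fiducial_times=fid_times,
        sbp_true=float(sbp), dbp_true=float(dbp),
        covariates={"hr": hr, "rr": rr, "ptt": ptt,
                    "w50": widths["w50"], "w10": widths["w10"],
                    "w10_exp_sbp": float(np.exp(-widths["w10"] / sbp_model.tau)),
                    "inv_ptt": 1.0 / ptt},
        generating_coefficients={"sbp": sbp_model.__dict__, "dbp": dbp_model.__dict__},
    )
    return ppg, abp, truth


def generate_record(config: SynthCohortConfig, rng: np.random.Generator,
                    record_id: str = ""):
    ecg, ecg_truth = generate_ecg(config, rng)
    ppg, abp, truth = generate_ppg_abp(config, ecg_truth.r_peak_times, rng)
    truth.covariates.update(ecg_truth.covariates)
    record = WaveformRecord(ecg=ecg, ppg=ppg, abp=abp, fs=config.fs,
                            record_id=record_id)
    return record, truth


def generate_cohort(config: SynthCohortConfig):
    """All records of a cohort; one child seed stream per subject."""
    streams = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    out = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        out.append(generate_record(config, rng, record_id=f"synth-{config.seed}-{i:04d}"))
    return out


# ---------------------------------------------------------------------------
# planted-structure feature tables

# analytic standardization for components of U(-1, 1) inputs
_NONLINEAR = {
    "square": (lambda x: x ** 2, 1.0 / 3.0, np.sqrt(4.0 / 45.0)),
    "sine": (lambda x: np.sin(np.pi * x), 0.0, np.sqrt(0.5)),
    "abs": (lambda x: np.abs(x), 0.5, np.sqrt(1.0 / 12.0)),
}
_LINEAR_SD = np.sqrt(1.0 / 3.0)


def generate_feature_table(n_rows: int = 2000,
                           n_relevant_linear: int = 3,
                           n_relevant_nonlinear: int = 2,
                           n_redundant: int = 5,
                           n_noise: int = 10,
                           effect_sizes=None,
                           noise_sd: float = 0.3,
                           copy_noise_sd: float = 1.0,
                           n_interacting: int = 0,
                           seed: int = 0) -> FeatureTable:
    """Feature table with planted relevant / redundant / noise columns.

    The target is ``y = sum_i a_i * std(comp_i) + eps`` where each
    component (a raw column, a symmetric nonlinear transform of one,
    or a product of an interacting pair) is standardized to unit
    variance analytically, so effect sizes are contribution shares.
    Nonlinear transforms cycle through square, sine and absolute
    value; each has zero population correlation with its source
    column.  Redundant columns are noisy copies of relevant ones
    (``copy_noise_sd`` is relative to the source column's sd).
    """
    if n_rows < 50:
        raise ValueError("n_rows must be >= 50")
    counts = (n_relevant_linear, n_relevant_nonlinear, n_redundant, n_noise, n_interacting)
    if any(c < 0 for c in counts):
        raise ValueError("column counts must be non-negative")
    rng = np.random.default_rng(seed)
    n_relevant = n_relevant_linear + n_relevant_nonlinear + n_interacting
    if effect_sizes is None:
        effect_sizes = np.ones(n_relevant_linear + n_relevant_nonlinear
                               + (1 if n_interacting else 0))
    effect_sizes = np.asarray(effect_sizes, dtype=float)

    cols, roles, components = {}, {}, []
    kinds = list(_NONLINEAR)
    e = 0
    for i in range(n_relevant_linear):
        name = f"lin_{i}"
        x = rng.uniform(-1, 1, n_rows)
        cols[name] = x
        roles[name] = "relevant_linear"
        components.append((effect_sizes[e], x / _LINEAR_SD))
        e += 1
    for j in range(n_relevant_nonlinear):
        kind = kinds[j % len(kinds)]
        name = f"nl_{kind}_{j}"
        x = rng.uniform(-1, 1, n_rows)
        fn, mu, sd = _NONLINEAR[kind]
        cols[name] = x
        roles[name] = "relevant_nonlinear"
        components.append((effect_sizes[e], (fn(x) - mu) / sd))
        e += 1
    if n_interacting:
        if n_interacting != 2:
            raise ValueError("interacting features are planted as one pair")
        xa = rng.uniform(-1, 1, n_rows)
        xb = rng.uniform(-1, 1, n_rows)
        cols["int_a"], cols["int_b"] = xa, xb
        roles["int_a"] = roles["int_b"] = "relevant_interacting"
        components.append((effect_sizes[e], (xa * xb) * 3.0))  # sd of product = 1/3
        e += 1

    relevant_names = [n for n, r in roles.items() if r.startswith("relevant")]
    redundant_of = {}
    for k in range(n_redundant):
        src = relevant_names[k % max(1, len(relevant_names))]
        name = f"red_{k}"
        noise = rng.normal(0.0, copy_noise_sd * np.std(cols[src]), n_rows) \
            if copy_noise_sd > 0 else 0.0
        cols[name] = cols[src] + noise
        roles[name] = "redundant"
        redundant_of[name] = src
    for k in range(n_noise):
        name = f"noise_{k}"
        cols[name] = rng.uniform(-1, 1, n_rows)
        roles[name] = "noise"

    y = sum(a * comp for a, comp in components) if components else np.zeros(n_rows)
    y = y + rng.normal(0.0, noise_sd, n_rows)

    features = pd.DataFrame(cols)
    targets = pd.DataFrame({"y": y})
    metadata = {
        "roles": roles,
        "redundant_of": redundant_of,
        "effect_sizes": effect_sizes.tolist(),
        "noise_sd": noise_sd,
        "copy_noise_sd": copy_noise_sd,
        "seed": seed,
    }
    return FeatureTable(features, targets, metadata=metadata)
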