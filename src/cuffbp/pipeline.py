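"""End-to-end orchestration: simulate/clean/extract/select/train/evaluate.

A :class:`PipelineConfig` fully determines a run: the synthetic-cohort
parameters, the filter and selection settings, the regression grids
and the global seed.  ``run_pipeline`` executes the stages in order,
records per-stage counts, and (optionally) writes every artifact with
the config hash so runs are reproducible and auditable from the
config alone.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as ft
from . import preprocess as pp
from . import regression as rg
from . import selection as sel
from .evaluate import evaluate as _evaluate
from .synth import SynthCohortConfig, generate_cohort

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "preprocess_record"]


@dataclass
class PipelineConfig:
    synth: SynthCohortConfig = field(default_factory=SynthCohortConfig)
    filter_spec: pp.FilterSpec = field(default_factory=pp.FilterSpec)
    selection: sel.SelectionConfig = field(default_factory=sel.SelectionConfig)
    window_s: float = 60.0
    min_beats: int = 5
    ptt_anchor: str = "max_slope"
    method: str = "msu-hybrid"
    targets: tuple = ("sbp", "dbp")
    holdout_fraction: float = 0.3
    lambda_grid: tuple = tuple(float(v) for v in rg.DEFAULT_LAMBDA_GRID)
    alpha_grid: tuple = tuple(rg.DEFAULT_ALPHA_GRID)
    n_folds: int = 10
    seed: int = 0

    _KNOWN = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synth"]["sbp_model"] = asdict(self.synth.sbp_model)
        d["synth"]["dbp_model"] = asdict(self.synth.dbp_model)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        from .synth import BPModel
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "synth" in d:
            s = dict(d["synth"])
            for key in ("sbp_model", "dbp_model"):
                if key in s and isinstance(s[key], dict):
                    s[key] = BPModel(**s[key])
            for key in ("hr_range", "ptt_range"):
                if key in s:
                    s[key] = tuple(s[key])
            d["synth"] = SynthCohortConfig(**s)
        if "filter_spec" in d and isinstance(d["filter_spec"], dict):
            fsd = dict(d["filter_spec"])
            if "band" in fsd:
                fsd["band"] = tuple(fsd["band"])
            d["filter_spec"] = pp.FilterSpec(**fsd)
        if "selection" in d and isinstance(d["selection"], dict):
            d["selection"] = sel.SelectionConfig(**d["selection"])
        for key in ("targets", "lambda_grid", "alpha_grid"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    table: ft.FeatureTable
    selection: dict
    models: dict
    predictions: pd.DataFrame
    reports: dict
    log: dict


def preprocess_record(record: pp.WaveformRecord,
                      spec: pp.FilterSpec | None = None) -> pp.WaveformRecord:
    """Clean the ECG (notch/FIR/delay compensation) and PPG channels."""
    spec = spec or pp.FilterSpec()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        ecg = pp.compensate_group_delay(
            pp.filter_ecg(record.ecg, record.fs, spec), spec.fir_order)
    ppg = pp.remove_baseline(record.ppg, record.fs)
    try:
        ppg = pp.normalize_signal(ppg)
    except pp.DegenerateSignalError:
        record.quality_flags["flatline"] = True
    return pp.WaveformRecord(ecg=ecg, ppg=ppg, abp=record.abp, fs=record.fs,
                             record_id=record.record_id,
                             quality_flags=dict(record.quality_flags))


def _record_table(record: pp.WaveformRecord, cfg: PipelineConfig):
    clean = preprocess_record(record, cfg.filter_spec)
    flags = pp.screen_quality(clean)
    if not flags["accepted"]:
        return None, flags
    r = pp.detect_r_peaks(clean.ecg, clean.fs)
    if r.size < cfg.min_beats + 1:
        flags["too_few_beats"] = True
        return None, flags
    fid = pp.extract_fiducials(clean, r)
    beats = ft.extract_record_beats(clean, fid, cfg.ptt_anchor)
    table = ft.aggregate_window(beats, cfg.window_s, cfg.min_beats,
                                record_id=record.record_id)
    return table, flags


def run_pipeline(config: PipelineConfig | None = None,
                 outdir: str | Path | None = None,
                 records=None) -> PipelineResult:
    """Execute the full measurement pipeline on a (synthetic) cohort.

    ``records`` may carry pre-loaded (record, truth-or-None) pairs to
    bypass simulation; otherwise the configured cohort is generated.
    """
    cfg = config or PipelineConfig()
    log: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed, "stages": {}}

    if records is None:
        synth_cfg = cfg.synth
        if synth_cfg.seed != cfg.seed:
            synth_cfg = SynthCohortConfig(**{**asdict(synth_cfg),
                                             "sbp_model": synth_cfg.sbp_model,
                                             "dbp_model": synth_cfg.dbp_model,
                                             "seed": cfg.seed})
        records = generate_cohort(synth_cfg)
    log["stages"]["records"] = len(records)

    tables, rejected = [], 0
    for rec, _truth in records:
        table, flags = _record_table(rec, cfg)
        if table is None or table.n_rows == 0:
            rejected += 1
            continue
        tables.append(table)
    if not tables:
        log["stages"]["rejected"] = rejected
        raise RuntimeError(f"quality screen rejected all {rejected} records")
    cohort = ft.concat_tables(tables)
    log["stages"]["rejected"] = rejected
    log["stages"]["windows"] = cohort.n_rows

    # split train/test by row (each window is one subject-window)
    rng = np.random.default_rng(cfg.seed)
    n = cohort.n_rows
    n_test = max(1, int(round(cfg.holdout_fraction * n))) if cfg.holdout_fraction > 0 else 0
    perm = rng.permutation(n)
    test_idx, train_idx = np.sort(perm[:n_test]), np.sort(perm[n_test:])

    selections, models, reports = {}, {}, {}
    preds = {}
    for target in cfg.targets:
        usable = cohort.complete_rows()
        # complete_rows reindexes; recompute the split on the usable table
        X_all, y_all = usable.features, usable.targets[target].to_numpy()
        n_u = len(X_all)
        n_test_u = max(1, int(round(cfg.holdout_fraction * n_u))) \
            if cfg.holdout_fraction > 0 else 0
        perm_u = np.random.default_rng(cfg.seed).permutation(n_u)
        te, tr = np.sort(perm_u[:n_test_u]), np.sort(perm_u[n_test_u:])

        result = sel.select_features(X_all.iloc[tr], y_all[tr],
                                     cfg.selection, method=cfg.method)
        chosen = result.fused_rank
        selections[target] = result
        model = rg.ElasticNetRegressorCV(lambdas=cfg.lambda_grid,
                                         alphas=cfg.alpha_grid,
                                         n_folds=cfg.n_folds, seed=cfg.seed)
        model.fit(X_all.iloc[tr][chosen].to_numpy(), y_all[tr])
        models[target] = (model, chosen)
        if te.size:
            yhat = model.predict(X_all.iloc[te][chosen].to_numpy())
            reports[target] = _evaluate(yhat, y_all[te], target=target)
            preds[f"{target}_pred"] = yhat
            preds[f"{target}_true"] = y_all[te]
        log["stages"][f"selected_{target}"] = len(chosen)
        log["stages"][f"train_{target}"] = int(tr.size)
        log["stages"][f"test_{target}"] = int(te.size)

    predictions = pd.DataFrame(preds)
    result = PipelineResult(table=cohort, selection=selections, models=models,
                            predictions=predictions, reports=reports, log=log)
    if outdir is not None:
        _write_artifacts(result, cfg, Path(outdir))
    return result


def _write_artifacts(res: PipelineResult, cfg: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    res.table.to_csv(outdir / "feature_table.csv")
    for target, selection in res.selection.items():
        (outdir / f"selection_{target}.json").write_text(
            json.dumps({"config_hash": cfg.config_hash(),
                        **selection.to_dict()}, indent=1))
    for target, (model, chosen) in res.models.items():
        rg.save_model(model, outdir / f"model_{target}.json",
                      feature_names=chosen, target=target)
    res.predictions.to_csv(outdir / "predictions.csv", index=False)
    for target, report in res.reports.items():
        report.to_json(outdir / f"report_{target}.json")
    (outdir / "run_log.json").write_text(json.dumps(res.log, indent=1))
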