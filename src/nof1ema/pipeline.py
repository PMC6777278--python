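"""End-to-end per-participant analysis orchestration.

Each participant's data are analyzed separately: sessionize the screen-view
log, derive per-window engagement outcomes, multiply impute EMA predictors
when more than 5% of responses are missing, select the ARMA error structure
on the full model, fit univariable models per predictor, build a
parsimonious multivariable model by backward elimination, and report IRRs
with 95% CIs — Rubin-pooled across imputations whenever imputation ran.
The study level is purely descriptive: per-predictor forest tables across
participants, with no pooled inference.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time as time_mod
import warnings
from dataclasses import dataclass, field, replace
from datetime import time, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from . import engagement, impute, models, synth
from .impute import ImputationSpec
from .models import ModelSpec

__all__ = [
    "ParticipantConfig",
    "StudyConfig",
    "ParticipantReport",
    "run_participant",
    "run_study",
    "run_synthetic_study",
]

logger = logging.getLogger(__name__)

OUTCOMES = ("frequency", "amount")


def _parse_time(t) -> time:
    if isinstance(t, time):
        return t
    h, m = str(t).split(":")
    return time(int(h), int(m))


@dataclass
class ParticipantConfig:
    participant_id: str
    morning_time: str = "10:00"  # EMA anchor; evening is 12 h later
    reminder_enabled: bool = True

    def __post_init__(self) -> None:
        t = _parse_time(self.morning_time)
        if not time(6, 0) <= t <= time(10, 0):
            raise ValueError(
                f"{self.participant_id}: morning EMA time must lie in "
                "[06:00, 10:00]")


@dataclass
class StudyConfig:
    participants: list = field(default_factory=lambda: [ParticipantConfig("P1")])
    component_set_size: int = 7
    gap_minutes: float = 30.0
    imputation: ImputationSpec = field(default_factory=ImputationSpec)
    model: ModelSpec = field(default_factory=ModelSpec)
    structure_grid: tuple = models.DEFAULT_STRUCTURE_GRID
    n_days: int = 28
    seed: int = 0
    out_dir: str | None = None

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            return str(o)
        payload = json.dumps(dataclasses.asdict(self), default=default,
                             sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ParticipantReport:
    participant_id: str
    descriptives: dict
    univariable: pd.DataFrame
    multivariable: pd.DataFrame
    diagnostics: dict
    provenance: dict
    errors: list

    def to_json(self) -> str:
        def conv(o):
            if isinstance(o, pd.DataFrame):
                return o.to_dict(orient="records")
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)
        return json.dumps({
            "participant_id": self.participant_id,
            "descriptives": self.descriptives,
            "univariable": self.univariable.to_dict(orient="records"),
            "multivariable": self.multivariable.to_dict(orient="records"),
            "diagnostics": self.diagnostics,
            "provenance": self.provenance,
            "errors": self.errors,
        }, default=conv, indent=2)


def _pooled_row(fits: list, predictor: str, z: float = 1.96) -> dict:
    """IRR row from one fit or Rubin-pooled across m imputation fits."""
    spec = fits[0].spec
    if len(fits) == 1:
        f = fits[0]
        b, se = float(f.params[predictor]), float(f.se[predictor])
        p = float(f.wald_p()[predictor])
        lo, hi = b - z * se, b + z * se
    else:
        pooled = impute.rubin_pool(
            [float(f.params[predictor]) for f in fits],
            [float(f.se[predictor]) ** 2 for f in fits])
        b = pooled.point
        lo, hi = pooled.ci()
        p = pooled.p_value()
    return {
        "predictor": predictor,
        "irr": math.exp(b), "ci_low": math.exp(lo), "ci_high": math.exp(hi),
        "p_value": p, "ar": spec.ar_order, "ma": spec.ma_order,
        "label": models.percent_change_label(math.exp(b)),
        "retained": True,
    }


def _dash_row(predictor: str, reason: str) -> dict:
    return {"predictor": predictor, "irr": np.nan, "ci_low": np.nan,
            "ci_high": np.nan, "p_value": np.nan, "ar": np.nan, "ma": np.nan,
            "label": reason, "retained": False}


def _analysis_table(ema: pd.DataFrame, events: pd.DataFrame | None,
                    pcfg: ParticipantConfig, cfg: StudyConfig) -> pd.DataFrame:
    """Merge EMA predictors with outcomes derived from the raw event log."""
    df = ema.copy().reset_index(drop=True)
    if events is not None:
        if "window_start" in df.columns:
            starts = pd.to_datetime(df["window_start"])
            windows = [engagement.MeasurementWindow(
                s, s + pd.Timedelta(hours=12),
                "morning" if i % 2 == 0 else "evening", i + 1)
                for i, s in enumerate(starts)]
        else:
            first = pd.to_datetime(events["timestamp"]).min()
            windows = engagement.build_windows(
                first, cfg.n_days, _parse_time(pcfg.morning_time))
        sessions = engagement.sessionize(
            events, timedelta(minutes=cfg.gap_minutes))
        summary = engagement.windowed_summary(sessions, windows,
                                              cfg.component_set_size)
        df["frequency"] = summary["frequency"].to_numpy()
        df["amount"] = summary["amount"].to_numpy()
        df["depth"] = summary["depth"].to_numpy()
    return df


def run_participant(ema: pd.DataFrame, events: pd.DataFrame | None,
                    pcfg: ParticipantConfig, cfg: StudyConfig
                    ) -> ParticipantReport:
    """Full single-participant analysis; stage failures yield a partial report."""
    t0 = time_mod.time()
    errors: list[dict] = []
    provenance: dict = {"seed": cfg.seed, "config_hash": cfg.config_hash(),
                        "stages": []}
    data = _analysis_table(ema, events, pcfg, cfg)
    item_cols = [c for c in impute.DEFAULT_KINDS if c in data.columns]
    n = len(data)
    missing_mask = data[item_cols].isna().any(axis=1).to_numpy()
    n_responses = int((~missing_mask).sum())
    compliance_pct = engagement.round_half_away(100.0 * n_responses / n)
    descriptives: dict = {
        "n_periods": n,
        "n_responses": n_responses,
        "compliance_pct": compliance_pct,
        "total_log_ins": float(np.nansum(data.get("frequency"))),
        "total_amount_seconds": float(np.nansum(data.get("amount"))),
    }
    if "depth" in data.columns:
        all_comp = data["depth"].max()
        descriptives["max_window_depth_pct"] = float(
            engagement.round_half_away(100 * all_comp))

    # --- imputation stage -------------------------------------------------
    ispec = replace(cfg.imputation, seed=cfg.seed)
    predictors = [p for p in cfg.model.predictors if p in data.columns]
    if not pcfg.reminder_enabled and "reminder" in predictors:
        predictors.remove("reminder")
        provenance["reminder"] = "did not apply (daily reminder opted out)"
    predictors = [p for p in predictors
                  if np.nanstd(data[p].to_numpy(float)) > 0]
    datasets = [data]
    imputed = False
    if impute.should_impute(data):
        try:
            trend = ispec.trend
            if trend == "auto":
                trend, widths = impute.select_trend(data, ispec)
                provenance["trend_ci_widths"] = widths
            imp = impute.em_bootstrap_impute(data, ispec, trend=trend)
            datasets = imp.datasets
            imputed = True
            provenance["stages"].append(
                {"stage": "impute", "m": imp.m, "trend": imp.trend,
                 "n_imputed_cells": len(imp.imputed_cells)})
        except Exception as exc:  # noqa: BLE001 - partial report contract
            errors.append({"stage": "impute", "error": str(exc)})
            datasets = [data.dropna(subset=item_cols).reset_index(drop=True)]
    elif missing_mask.any():
        datasets = [data.dropna(subset=item_cols).reset_index(drop=True)]
        provenance["stages"].append(
            {"stage": "impute",
             "skipped": "missingness at or below the 5% threshold; "
                        "complete-case analysis"})
    else:
        provenance["stages"].append({"stage": "impute",
                                     "skipped": "no missing responses"})

    # descriptives for predictors, Rubin-style across imputations
    for p in predictors:
        means = [float(np.mean(d[p])) for d in datasets]
        sds = [float(np.std(d[p], ddof=1)) for d in datasets]
        descriptives[p] = {
            "mean": float(np.mean(means)), "sd": float(np.mean(sds)),
            "range": (float(np.min([d[p].min() for d in datasets])),
                      float(np.max([d[p].max() for d in datasets]))),
        }

    uni_rows: dict[str, list] = {o: [] for o in OUTCOMES}
    multi_rows: dict[str, list] = {o: [] for o in OUTCOMES}
    diagnostics: dict = {"imputed": imputed, "m": len(datasets)}

    for outcome in OUTCOMES:
        base = replace(cfg.model, outcome=outcome,
                       predictors=tuple(predictors))
        try:
            structure, aic_table = models.select_structure(
                datasets[0], base, cfg.structure_grid)
            diagnostics[f"{outcome}_structure"] = (structure.ar_order,
                                                   structure.ma_order)
            diagnostics[f"{outcome}_aic_table"] = aic_table.to_dict("records")
        except Exception as exc:  # noqa: BLE001
            errors.append({"stage": f"select_structure[{outcome}]",
                           "error": str(exc)})
            continue
        # univariable fits, pooled across imputations
        for p in predictors:
            try:
                fits = [models.fit_univariable(d, p, structure)
                        for d in datasets]
                uni_rows[outcome].append(_pooled_row(fits, p))
            except Exception as exc:  # noqa: BLE001
                errors.append({"stage": f"univariable[{outcome}:{p}]",
                               "error": str(exc)})
                uni_rows[outcome].append(_dash_row(p, "fit failed"))
        # multivariable backward selection; majority vote on retained sets
        try:
            retained_sets = []
            for d in datasets:
                fit, trace = models.backward_select(d, structure)
                retained_sets.append(set(fit.spec.predictors))
            keep = tuple(p for p in predictors
                         if sum(p in s for s in retained_sets)
                         >= math.ceil(len(retained_sets) / 2))
            diagnostics[f"{outcome}_retained"] = list(keep)
            if keep:
                final_spec = replace(structure, predictors=keep)
                fits = [models.fit_count_gam(final_spec, d) for d in datasets]
                for p in predictors:
                    if p in keep:
                        multi_rows[outcome].append(_pooled_row(fits, p))
                    else:
                        multi_rows[outcome].append(_dash_row(
                            p, "not included in the best-fitting model"))
            else:
                for p in predictors:
                    multi_rows[outcome].append(_dash_row(
                        p, "not included in the best-fitting model"))
        except Exception as exc:  # noqa: BLE001
            errors.append({"stage": f"backward_select[{outcome}]",
                           "error": str(exc)})

    def _table(rows_by_outcome: dict) -> pd.DataFrame:
        frames = []
        for outcome, rows in rows_by_outcome.items():
            f = pd.DataFrame(rows)
            if not f.empty:
                f.insert(0, "outcome", outcome)
            frames.append(f)
        return (pd.concat(frames, ignore_index=True) if frames
                else pd.DataFrame())

    provenance["runtime_s"] = round(time_mod.time() - t0, 3)
    report = ParticipantReport(
        participant_id=pcfg.participant_id,
        descriptives=descriptives,
        univariable=_table(uni_rows),
        multivariable=_table(multi_rows),
        diagnostics=diagnostics,
        provenance=provenance,
        errors=errors,
    )
    if cfg.out_dir:
        out = Path(cfg.out_dir) / pcfg.participant_id
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        report.univariable.to_csv(out / "univariable.csv", index=False)
        report.multivariable.to_csv(out / "multivariable.csv", index=False)
    return report


def run_study(cfg: StudyConfig, data: dict) -> dict:
    """Analyze every participant and emit descriptive forest tables.

    ``data`` maps participant id to an (ema, events) pair. Per-participant
    failures are isolated; no cross-participant inference is performed.
    """
    reports: dict[str, ParticipantReport] = {}
    for pcfg in cfg.participants:
        pid = pcfg.participant_id
        try:
            ema, events = data[pid]
            reports[pid] = run_participant(ema, events, pcfg, cfg)
        except Exception as exc:  # noqa: BLE001
            logger.error("participant %s failed: %s", pid, exc)
            reports[pid] = ParticipantReport(
                pid, {}, pd.DataFrame(), pd.DataFrame(), {},
                {"config_hash": cfg.config_hash()},
                [{"stage": "run_participant", "error": str(exc)}])
    forest: dict[str, pd.DataFrame] = {}
    predictors = cfg.model.predictors
    for outcome in OUTCOMES:
        for p in predictors:
            rows = []
            for pid, rep in reports.items():
                t = rep.univariable
                if t.empty:
                    continue
                sel = t[(t["outcome"] == outcome) & (t["predictor"] == p)]
                for _, r in sel.iterrows():
                    rows.append({"participant": pid, **r.to_dict()})
            forest[f"{outcome}_{p}"] = pd.DataFrame(rows)
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for key, tab in forest.items():
            tab.to_csv(out / f"forest_{key}.csv", index=False)
    return {"reports": reports, "forest": forest,
            "config_hash": cfg.config_hash()}


def run_synthetic_study(cfg: StudyConfig,
                        sim_config: synth.SimulationConfig | None = None,
                        effects_by_pid: dict | None = None) -> dict:
    """Generate synthetic participants under ``sim_config`` and analyze them."""
    base = sim_config or synth.SimulationConfig()
    data = {}
    for i, pcfg in enumerate(cfg.participants):
        pid = pcfg.participant_id
        sim_cfg = dataclasses.replace(
            base,
            reminder=synth.ReminderSchedule(enabled=pcfg.reminder_enabled),
            seed=cfg.seed + i)
        if effects_by_pid and pid in effects_by_pid:
            sim_cfg = dataclasses.replace(sim_cfg,
                                          effects=effects_by_pid[pid])
        sim = synth.simulate_participant(sim_cfg, participant_id=pid)
        data[pid] = (sim.ema, sim.events)
    return run_study(cfg, data)
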