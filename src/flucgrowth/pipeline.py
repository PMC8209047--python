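"""Config-driven runs tying the stages into reproducible pipelines.

A run is described by a single YAML config with explicit unit suffixes
(`_s`, `_per_h`, `_um`) and a seed; re-executing a persisted config with
the same seed reproduces outputs byte-identically.  Three stages exist:

* ``run_simulate``  — signals + synthetic tracks (+ sidecar signal specs),
* ``run_analyze``   — QC, growth points, curves, steady-state rates, shift
  and stabilization summaries,
* ``run_nullmodel`` — kernel-based G_fluc predictions, Jensen references,
  biomass projections, paired comparisons.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .growth import (assign_phase, bin_mean, growth_points, phase_fold,
                     phase_period_stats, steady_state_rate,
                     DEFAULT_WINDOW_START_S)
from .kernels import make_shift_kernels
from .nullmodel import (biomass_projection, fold_difference, jensen_rate,
                        paired_comparison, predict_gfluc)
from .qc import QCCriteria, apply_qc, read_tracks, write_tracks
from .shifts import (StabilizationParams, align_to_shifts,
                     detect_stabilization, initial_response, onset_analysis)
from .signals import NutrientSignal, make_signal
from .simulate import SimConfig, simulate_experiment
from .steadymap import SteadyStateMap

__all__ = ["RunConfig", "run_simulate", "run_analyze", "run_nullmodel",
           "ConfigError", "DataError"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


class DataError(ValueError):
    """Schema or content problem in input data."""


@dataclass
class RunConfig:
    """Serializable description of a full run."""

    seed: int = 0
    n_days: int = 1
    signals: Dict[str, dict] = field(default_factory=dict)
    physiologies: Dict[str, str] = field(default_factory=dict)
    sim: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    anchors: Optional[list] = None
    kernels: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    # -- constructed objects -------------------------------------------

    def build_signals(self) -> Dict[str, NutrientSignal]:
        if not self.signals:
            raise ConfigError("config defines no signals")
        out = {}
        for name, spec in self.signals.items():
            try:
                out[name] = make_signal(
                    kind=spec["kind"],
                    c_low=spec.get("c_low_pct", 0.1),
                    c_high=spec.get("c_high_pct", 2.0),
                    duration=spec["duration_s"],
                    period_T=spec.get("period_T_s"),
                    shift_time=spec.get("shift_time_s"),
                    first_phase=spec.get("first_phase"),
                    steady_level=spec.get("steady_level", "average"),
                )
            except (KeyError, ValueError) as exc:
                raise ConfigError(f"signal {name!r}: {exc}") from exc
        return out

    def build_sim_config(self, physiology: str) -> SimConfig:
        try:
            return SimConfig(seed=self.seed, physiology=physiology,
                             **self.sim)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"sim config: {exc}") from exc

    def build_map(self) -> SteadyStateMap:
        return SteadyStateMap(self.anchors) if self.anchors \
            else SteadyStateMap()

    def build_kernels(self):
        return make_shift_kernels(**self.kernels)

    def build_qc(self) -> QCCriteria:
        try:
            return QCCriteria(**self.qc)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"qc criteria: {exc}") from exc


def _provenance(config: RunConfig, stage: str) -> str:
    return (f"flucgrowth {__version__} | stage={stage} "
            f"| seed={config.seed} | config={config.digest()}")


def _log(outdir: Path, stage: str, payload: dict) -> None:
    path = outdir / f"{stage}_log.json"
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)


def run_simulate(config: RunConfig, outdir) -> Dict[str, Path]:
    """Simulate every configured condition; write tracks + signal sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    signals = config.build_signals()
    steady_map = config.build_map()
    kernels = config.build_kernels()
    conditions = {}
    for name, sig in signals.items():
        phys = config.physiologies.get(name, "instantaneous")
        conditions[name] = (sig, phys)
    sim_cfg = config.build_sim_config("instantaneous")
    results = simulate_experiment(conditions, sim_cfg,
                                  steady_map=steady_map, kernels=kernels,
                                  n_days=config.n_days)
    paths = {}
    counts = {}
    for name, runs in results.items():
        table = pd.concat([r.table for r in runs], ignore_index=True)
        path = outdir / f"tracks_{name}.csv"
        write_tracks(table, path, provenance=_provenance(config, "simulate"))
        with open(outdir / f"signal_{name}.yaml", "w") as fh:
            yaml.safe_dump(signals[name].to_dict(), fh, sort_keys=True)
        paths[name] = path
        counts[name] = {"rows": int(len(table)),
                        "tracks": int(table["track_id"].nunique())}
    config.to_yaml(outdir / "config.yaml")
    _log(outdir, "simulate", {"seed": config.seed,
                              "config_digest": config.digest(),
                              "conditions": counts})
    return paths


def _curve_summary(curve, stab, resp):
    return {
        "direction": curve.direction,
        "n_shifts": int(curve.n_shifts),
        "stabilized": bool(stab.stabilized),
        "stabilization_time_min": stab.stabilization_time_min,
        "stabilized_value_per_h": stab.stabilized_value,
        "initial_response_pct": resp,
    }


def run_analyze(config: RunConfig, tracks_dir, outdir) -> dict:
    """QC -> growth rates -> binned/steady/phase/shift statistics."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tracks_dir = Path(tracks_dir)
    signals = config.build_signals()
    crit = config.build_qc()
    ana = config.analysis
    bin_width = float(ana.get("bin_width_s", 117.0))
    coarse = float(ana.get("coarse_bin_width_s", 1800.0))
    window_start = float(ana.get("window_start_s", DEFAULT_WINDOW_START_S))
    stab_params = StabilizationParams(
        min_window_points=int(ana.get("min_window_points", 4)),
        rule=ana.get("stabilization_rule", "ci"),
        slope_tol=float(ana.get("slope_tol_per_h_per_h", 0.5)),
    )
    summary = {"seed": config.seed, "config_digest": config.digest(),
               "conditions": {}}
    qc_reports = {}
    for name, sig in signals.items():
        path = tracks_dir / f"tracks_{name}.csv"
        if not path.exists():
            raise DataError(f"missing track table {path}")
        table = read_tracks(path)
        kept, report = apply_qc(table, crit)
        qc_reports[name] = report.per_condition
        if len(kept) == 0:
            raise DataError(f"no frames survive QC for condition {name!r}")
        points = growth_points(kept)
        points = assign_phase(points, sig)
        points.to_csv(outdir / f"growth_points_{name}.csv", index=False)
        curve = bin_mean(points, bin_width)
        curve.to_frame().to_csv(outdir / f"growth_curve_{name}.csv",
                                index=False)
        bin_mean(points, coarse).to_frame().to_csv(
            outdir / f"growth_curve_coarse_{name}.csv", index=False)
        cond = {"n_points": int(points["valid"].sum())}
        per_day = []
        for day, dpts in points.groupby("replicate_day"):
            try:
                ss = steady_state_rate(dpts, window_start, condition=name,
                                       replicate_day=str(day))
            except ValueError:
                continue
            per_day.append({"replicate_day": str(day), "G_per_h": ss.G,
                            "sem_per_h": ss.sem, "n_points": ss.n_points,
                            "n_cells": ss.n_cells})
        if not per_day:
            raise DataError(
                f"no growth points after {window_start/3600:.1f} h for "
                f"condition {name!r}")
        cond["steady_state"] = per_day
        if sig.kind in ("fluctuating", "onset"):
            fold = phase_fold(points, sig)
            fold.to_frame().to_csv(outdir / f"phase_fold_{name}.csv",
                                   index=False)
            cond["phase_under_resolved"] = bool(fold.under_resolved)
            cond["period_stats"] = phase_period_stats(points, sig).to_dict(
                "records")
        if sig.kind in ("fluctuating", "single_shift"):
            shift_summaries = {}
            for direction in ("up", "down"):
                try:
                    curve = align_to_shifts(points, sig, direction,
                                            bin_width=bin_width)
                except ValueError:
                    continue
                curve.to_frame().to_csv(
                    outdir / f"aligned_{direction}_{name}.csv", index=False)
                try:
                    stab = detect_stabilization(curve, stab_params)
                except ValueError:
                    continue
                try:
                    resp = initial_response(curve)
                except ValueError:
                    resp = None
                shift_summaries[direction] = _curve_summary(curve, stab,
                                                            resp)
            if shift_summaries:
                cond["shift_response"] = shift_summaries
        if sig.kind == "onset":
            onset = onset_analysis(points, sig)
            cond["onset_convergence_period"] = onset.convergence_period
        summary["conditions"][name] = cond
    with open(outdir / "qc_report.json", "w") as fh:
        json.dump(qc_reports, fh, indent=2, sort_keys=True)
    with open(outdir / "analysis_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    _log(outdir, "analyze", {"seed": config.seed,
                             "conditions": list(signals)})
    return summary


def run_nullmodel(config: RunConfig, outdir,
                  analysis_summary: Optional[dict] = None) -> dict:
    """Kernel-based predictions, Jensen reference, biomass, comparisons."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    kernels = config.build_kernels()
    ana = config.analysis
    T_grid = ana.get("T_grid_s", [30.0, 300.0, 900.0, 3600.0,
                                  12 * 3600.0, 96 * 3600.0])
    variants = ana.get("variants", ["A_value_matching", "B_clock_reset"])
    frames = []
    for variant in variants:
        pred = predict_gfluc(kernels, variant, T_grid_s=T_grid)
        frames.append(pred.to_frame())
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(outdir / "null_predictions.csv", index=False)
    g_j = jensen_rate(kernels.g_low, kernels.g_high)
    report = {"G_J_per_h": g_j,
              "G_low_per_h": kernels.g_low, "G_high_per_h": kernels.g_high}
    t_h = float(ana.get("biomass_horizon_h", 24.0))
    report["biomass"] = {}
    for label, g in (("G_low", kernels.g_low), ("G_J", g_j),
                     ("G_high", kernels.g_high)):
        report["biomass"][label] = biomass_projection(1.0, g, t_h).M
    if analysis_summary is not None:
        rows = {}
        for name, cond in analysis_summary.get("conditions", {}).items():
            for rec in cond.get("steady_state", []):
                rows.setdefault(rec["replicate_day"], {})[name] = \
                    rec["G_per_h"]
        recs = []
        for day, vals in sorted(rows.items()):
            rec = {"replicate_day": day}
            for cond_name, col in (("fluctuating", "G_fluc"),
                                   ("steady_low", "G_low"),
                                   ("steady_ave", "G_ave"),
                                   ("steady_high", "G_high")):
                if cond_name in vals:
                    rec[col] = vals[cond_name]
            recs.append(rec)
        per_day = pd.DataFrame(recs)
        if "G_fluc" in per_day.columns:
            comps = {}
            for ref in ("G_ave", "G_J", "G_low"):
                need = {"G_low", "G_high"} if ref == "G_J" else {ref}
                if need.issubset(per_day.columns):
                    try:
                        cs = paired_comparison(per_day, ref)
                    except ValueError:
                        continue
                    comps[ref] = {"mean_pct_diff": cs.mean_pct_diff,
                                  "sd_pct_diff": cs.sd_pct_diff,
                                  "n_days": int(len(cs.per_day))}
            report["paired_comparisons"] = comps
            per_day.to_csv(outdir / "per_day_rates.csv", index=False)
    with open(outdir / "nullmodel_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    _log(outdir, "nullmodel", {"seed": config.seed, "variants": variants})
    return report
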