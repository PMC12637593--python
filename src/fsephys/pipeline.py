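"""End-to-end seeded studies: simulate (or load) a cohort, extract
features, and run the group statistics, emitting tidy CSV tables, a JSON
stats report, a reproducibility manifest and a plain-text log.

Two designs mirror the physiology experiments:

* the *intrinsic* study (three genotypes, current steps): per-cell
  selection of the first trace with >= 10 APs, AP_2/AP_10 metrics and
  first-10 means, one-way ANOVA + Tukey-Kramer per metric, bootstrap of
  group means, rate-binned tables and spike-train adaptation;
* the *synaptic* study (two genotypes, paired recordings): passive QC,
  unitary IPSC amplitudes, decay-corrected PPR (current and conductance)
  per interstimulus interval, five-pulse train curves, per-interval
  t-tests and a genotype x interval mixed RM-ANOVA.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .simulate.cohort import (
    PPR_INTERVALS_MS,
    CohortSpec,
    generate_cohort,
)
from .simulate.neuron import FSNeuronParams
from .simulate.synapse import SynapseParams
from .spikes import (
    METRICS,
    FeatureConfig,
    SelectionError,
    adaptation,
    bin_by_rate,
    select_trace,
    summarize_trace,
)
from .stats import bootstrap_means, mixed_rm_anova, summarize, tukey_kramer, unpaired_t
from .sweeps import CellRecording, StepProtocol, StimTrain, load_cell, qc_cell, save_cell
from .synaptic import (
    ConductanceParams,
    MeasurementError,
    measure_passive,
    ppr,
    train_response,
    unitary_amplitude,
)

__all__ = ["PipelineConfig", "run_intrinsic_study", "run_synaptic_study"]

log = logging.getLogger("fsephys")


@dataclass
class PipelineConfig:
    seed: int = 0
    design: str = "intrinsic"
    out_dir: str = "study_out"
    bundle_dir: Optional[str] = None  # load cohort from disk instead
    save_bundles: bool = False
    n_cells: Dict[str, int] = field(
        default_factory=lambda: {"WT/WT": 18, "Cre/WT": 16, "Cre/Cre": 20}
    )
    cohort_overrides: dict = field(default_factory=dict)
    n_rate_bins: int = 4
    n_bootstrap: int = 1000
    test_pulse_mV: float = -5.0
    conductance: ConductanceParams = field(default_factory=ConductanceParams)

    def cohort_spec(self) -> CohortSpec:
        over = dict(self.cohort_overrides)
        if "neuron" in over and isinstance(over["neuron"], dict):
            over["neuron"] = FSNeuronParams(**over["neuron"])
        if "synapse_by_genotype" in over:
            over["synapse_by_genotype"] = {
                k: (SynapseParams(**v) if isinstance(v, dict) else v)
                for k, v in over["synapse_by_genotype"].items()
            }
        return CohortSpec(
            n_cells=dict(self.n_cells),
            design=self.design,
            seed=self.seed,
            **over,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "conductance" in raw and isinstance(raw["conductance"], dict):
            raw["conductance"] = ConductanceParams(**raw["conductance"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _prepare(config: PipelineConfig):
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "study.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    if config.bundle_dir:
        cells = [
            load_cell(p)
            for p in sorted(Path(config.bundle_dir).iterdir())
            if (p / "metadata.json").exists()
        ]
        log.info("loaded %d bundles from %s", len(cells), config.bundle_dir)
    else:
        cells = generate_cohort(config.cohort_spec())
        log.info("generated %d cells (design=%s, seed=%d)",
                 len(cells), config.design, config.seed)
        if config.save_bundles:
            for c in cells:
                save_cell(c, out / "bundles" / c.cell_id)
    return out, handler, cells


def _manifest(config: PipelineConfig, out: Path, extra: dict) -> None:
    cfg = json.dumps(config.to_dict(), sort_keys=True, default=str)
    manifest = {
        "fsephys_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg.encode()).hexdigest(),
        "config": json.loads(cfg),
        **extra,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)


def run_intrinsic_study(config: PipelineConfig) -> dict:
    """Three-genotype intrinsic-property analysis; returns the report dict
    and writes CSV/JSON artifacts under ``config.out_dir``."""
    out, handler, cells = _prepare(config)
    try:
        cfg = FeatureConfig()
        rows = []
        excluded = []
        summaries_by_cell = {}
        genotypes = {}
        adapt_rows = []
        for cell in cells:
            genotypes[cell.cell_id] = cell.genotype
            try:
                sel = select_trace(cell, cfg)
            except SelectionError as exc:
                excluded.append({"cell_id": cell.cell_id, "reason": str(exc)})
                log.warning("excluded %s: %s", cell.cell_id, exc)
                continue
            row = {"cell_id": cell.cell_id, "genotype": cell.genotype,
                   "sweep_id": sel.sweep_id, "n_APs": sel.n_APs,
                   "rate_Hz": sel.firing_rate_Hz}
            for metric in METRICS:
                row[f"{metric}_AP2"] = sel.metric_at(metric, 2)
                row[f"{metric}_AP10"] = sel.metric_at(metric, 10)
                row[f"{metric}_mean10"] = sel.metric_mean_first(metric, 10)
            rows.append(row)
            summaries_by_cell[cell.cell_id] = [
                summarize_trace(s, cfg)
                for s in cell.sweeps_of("current_clamp")
                if isinstance(s.stimulus, StepProtocol)
                and s.stimulus.amplitude_pA > 0
            ]
            am = adaptation(cell, cfg)
            if am.eligible:
                adapt_rows.append({"cell_id": cell.cell_id,
                                   "genotype": cell.genotype,
                                   "n_APs": am.n_APs,
                                   "delta_isi_ms": am.delta_isi_ms,
                                   "delta_half_width_ms": am.delta_half_width_ms,
                                   "delta_interspike_mV": am.delta_interspike_mV})
        table = pd.DataFrame(rows)
        table.to_csv(out / "intrinsic_features.csv", index=False)
        pd.DataFrame(adapt_rows).to_csv(out / "adaptation.csv", index=False)

        stats_report = {}
        boot = {}
        rng = np.random.default_rng(config.seed)
        for metric in METRICS if not table.empty else []:
            for where in ("AP2", "AP10", "mean10"):
                col = f"{metric}_{where}"
                groups = {
                    g: sub[col].dropna().to_numpy()
                    for g, sub in table.groupby("genotype")
                }
                groups = {g: v for g, v in groups.items() if len(v) >= 2}
                if len(groups) < 2:
                    continue
                res = tukey_kramer(groups)
                stats_report[col] = {
                    "test": "one-way ANOVA + Tukey-Kramer",
                    "F": res.statistic,
                    "df": list(res.df),
                    "p_value": res.p_value,
                    "pairwise": res.pairwise.to_dict("records"),
                    "groups": summarize(groups).to_dict("records"),
                }
                boot[col] = {
                    g: bootstrap_means(
                        v, config.n_bootstrap,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    ).tolist()
                    for g, v in groups.items()
                }
        with open(out / "intrinsic_stats.json", "w") as fh:
            json.dump(stats_report, fh, indent=1, sort_keys=True)
        with open(out / "bootstrap_means.json", "w") as fh:
            json.dump(boot, fh)

        if any(s.n_APs for ss in summaries_by_cell.values() for s in ss):
            binned = bin_by_rate(summaries_by_cell, config.n_rate_bins,
                                 genotypes)
        else:
            binned = pd.DataFrame()
        binned.to_csv(out / "rate_binned.csv", index=False)

        _manifest(config, out, {"n_cells": len(cells),
                                "n_excluded": len(excluded),
                                "excluded": excluded})
        log.info("intrinsic study complete: %d cells analyzed, %d excluded",
                 len(rows), len(excluded))
        return {"features": table, "stats": stats_report,
                "binned": binned, "excluded": excluded,
                "adaptation": pd.DataFrame(adapt_rows), "bootstrap": boot}
    finally:
        log.removeHandler(handler)
        handler.close()


def _classify_sweeps(cell: CellRecording) -> dict:
    """Sort a pair's sweeps by protocol type from stimulus metadata."""
    out = {"testpulse": [], "single": [], "pp": {}, "train5": {}}
    for sw in cell.sweeps:
        if sw.modality != "voltage_clamp":
            continue
        stim = sw.stimulus
        if isinstance(stim, StepProtocol):
            out["testpulse"].append(sw)
        elif isinstance(stim, StimTrain):
            times = stim.pulse_times_ms
            if len(times) == 1:
                out["single"].append(sw)
            elif len(times) == 2:
                out["pp"].setdefault(times[1] - times[0], []).append(sw)
            elif len(times) == 5:
                out["train5"].setdefault(times[1] - times[0], []).append(sw)
    return out


def run_synaptic_study(config: PipelineConfig) -> dict:
    """Two-genotype paired-recording analysis; returns the report dict and
    writes artifacts under ``config.out_dir``."""
    if not config.bundle_dir and "WT/WT" in config.n_cells and len(
        config.n_cells
    ) > 2:
        raise ValueError("synaptic design compares two genotypes")
    cfg = dataclasses.replace(config, design="synaptic")
    out, handler, cells = _prepare(cfg)
    try:
        ppr_rows, train_rows, unit_rows, excluded = [], [], [], []
        for cell in cells:
            kinds = _classify_sweeps(cell)
            params = config.conductance
            if kinds["testpulse"]:
                tp = kinds["testpulse"][0]
                stim = tp.stimulus
                try:
                    passive = measure_passive(
                        tp,
                        delta_V_mV=config.test_pulse_mV,
                        onset_ms=stim.onset_ms,
                        duration_ms=stim.duration_ms,
                    )
                    cell.passive = passive
                    params = dataclasses.replace(
                        config.conductance,
                        R_series_MOhm=passive.R_series_MOhm,
                        R_membrane_MOhm=passive.R_membrane_MOhm,
                    )
                except MeasurementError as exc:
                    log.warning("%s: passive measurement failed: %s",
                                cell.cell_id, exc)
            flags = qc_cell(cell)
            if any(f.status == "fail" for f in flags):
                excluded.append({"cell_id": cell.cell_id,
                                 "reason": "QC fail: " + ", ".join(
                                     f.rule for f in flags
                                     if f.status == "fail")})
                log.warning("excluded %s (QC)", cell.cell_id)
                continue
            if kinds["single"]:
                t0 = kinds["single"][0].stimulus.pulse_times_ms[0]
                unit = unitary_amplitude(kinds["single"], t0, params)
                unit_rows.append({"pair_id": cell.cell_id,
                                  "genotype": cell.genotype,
                                  "amplitude_nA": unit["amplitude_nA"],
                                  "conductance_nS": unit.get("conductance_nS")})
            for dt_ms, sweeps in sorted(kinds["pp"].items()):
                stim = sweeps[0].stimulus
                for units in ("current", "conductance"):
                    try:
                        res = ppr(sweeps, stim, params, units=units)
                    except MeasurementError as exc:
                        log.warning("%s PPR dt=%s %s failed: %s",
                                    cell.cell_id, dt_ms, units, exc)
                        continue
                    ppr_rows.append({"pair_id": cell.cell_id,
                                     "genotype": cell.genotype,
                                     "delta_t_ms": dt_ms, "units": units,
                                     "ppr": res.ppr,
                                     "ppr_uncorrected": res.ppr_uncorrected,
                                     "A1": res.A1,
                                     "n_repeats": res.n_repeats})
            for dt_ms, sweeps in sorted(kinds["train5"].items()):
                stim = sweeps[0].stimulus
                for units in ("current", "conductance"):
                    res = train_response(sweeps, stim, params, units=units)
                    for k, val in enumerate(res.normalized):
                        train_rows.append({"pair_id": cell.cell_id,
                                           "genotype": cell.genotype,
                                           "delta_t_ms": dt_ms,
                                           "units": units,
                                           "pulse": k + 1,
                                           "normalized": float(val)})
        ppr_table = pd.DataFrame(ppr_rows)
        train_table = pd.DataFrame(train_rows)
        unit_table = pd.DataFrame(unit_rows)
        ppr_table.to_csv(out / "ppr.csv", index=False)
        train_table.to_csv(out / "train5.csv", index=False)
        unit_table.to_csv(out / "unitary.csv", index=False)

        stats_report = {}
        for units in ("current", "conductance"):
            sub = ppr_table[ppr_table.units == units]
            if sub.empty:
                continue
            per_dt = {}
            for dt_ms, d in sub.groupby("delta_t_ms"):
                gs = {g: v["ppr"].to_numpy() for g, v in d.groupby("genotype")}
                if len(gs) == 2 and all(len(v) >= 2 for v in gs.values()):
                    a, b = (gs[k] for k in sorted(gs))
                    t = unpaired_t(a, b)
                    per_dt[dt_ms] = {
                        "t": t.statistic, "df": list(t.df),
                        "p_value": t.p_value,
                        "groups": summarize(gs).to_dict("records"),
                    }
            entry = {"per_interval_t": per_dt}
            if sub.genotype.nunique() == 2 and sub.delta_t_ms.nunique() >= 2:
                rm = mixed_rm_anova(sub, dv="ppr", within="delta_t_ms",
                                    between="genotype", subject="pair_id")
                entry["mixed_rm_anova"] = {
                    "F": rm.statistic, "df": list(rm.df),
                    "p_value": rm.p_value, "epsilon": rm.epsilon,
                    "effects": rm.effects.to_dict("records"),
                }
            stats_report[units] = entry
        with open(out / "synaptic_stats.json", "w") as fh:
            json.dump(stats_report, fh, indent=1, sort_keys=True)
        _manifest(config, out, {"n_pairs": len(cells),
                                "n_excluded": len(excluded),
                                "excluded": excluded})
        log.info("synaptic study complete: %d pairs, %d excluded",
                 len(cells), len(excluded))
        return {"ppr": ppr_table, "train": train_table,
                "unitary": unit_table, "stats": stats_report,
                "excluded": excluded}
    finally:
        log.removeHandler(handler)
        handler.close()
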