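"""End-to-end orchestration: simulate -> volumes -> metrics -> atlas -> models.

A PipelineConfig (plain YAML/JSON) fixes every numeric choice of the
analysis (grid size, spline upsampling, diastasis threshold, PCA
variance threshold, CV parameters) and names the candidate feature
blocks that compose each prognostic model (e.g. "cmr + vt_ai"). A run
produces a deterministic artifact set — transients.csv, metrics.csv,
atlas.json, weights.csv, per-model JSONs and a text report — each
stamped with the config hash and seed, plus a patient-flow log of the
counts surviving each exclusion.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import atlas as atlas_mod
from . import metrics as metrics_mod
from . import models as models_mod
from . import synthetic
from .volumes import write_transients_csv

logging.basicConfig(format="%(levelname)s %(name)s: %(message)s")
logger = logging.getLogger(__name__)

VT_BLOCK_DEFAULT = [
    "rr_ms", "rr_variability_pct_rr", "systolic_time_ms",
    "diastolic_time_ms", "diastasis_ms", "time_to_diastasis_ms",
    "passive_filling_ml", "active_filling_ml",
]
CMR_BLOCK_DEFAULT = ["esv_ml", "edv_ml", "ef_pct"]


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Everything a run needs; all analysis constants in one place."""

    n_patients: int = 1000
    mace_rate: float = synthetic.MACE_RATE_DEFAULT
    seed: int = 0
    grid_points: int = atlas_mod.GRID_POINTS_DEFAULT
    upsample_factor: int = 10
    diastasis_threshold_frac: float = metrics_mod.DIASTASIS_THRESHOLD_FRAC
    variance_threshold: float = atlas_mod.VARIANCE_THRESHOLD_DEFAULT
    cv_k: int = models_mod.K_FOLDS_DEFAULT
    cv_n_splits: int = models_mod.N_SPLITS_DEFAULT
    blocks: dict = field(default_factory=lambda: {
        "cmr": list(CMR_BLOCK_DEFAULT),
        "vt": list(VT_BLOCK_DEFAULT),
        "vt_ai": "retained atlas modes",  # expanded after the atlas fit
    })
    models: list = field(default_factory=lambda: [
        {"name": "ef", "blocks": [], "extra": ["ef_pct"]},
        {"name": "cmr", "blocks": ["cmr"]},
        {"name": "cmr_vt", "blocks": ["cmr", "vt"]},
        {"name": "cmr_vt_ai", "blocks": ["cmr", "vt_ai"]},
    ])

    def __post_init__(self) -> None:
        if not 0 < self.diastasis_threshold_frac < 1:
            raise ConfigError("diastasis threshold must lie in (0, 1)")
        if not 0 < self.variance_threshold <= 1:
            raise ConfigError("variance threshold must lie in (0, 1]")
        if self.cv_k < 2 or self.cv_n_splits < 1:
            raise ConfigError("need k >= 2 and n_splits >= 1")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def hash(self) -> str:
        text = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _candidate_columns(cfg: PipelineConfig, model_spec: dict,
                       vt_ai_cols: list[str]) -> list[str]:
    cols: list[str] = []
    for block in model_spec.get("blocks", []):
        if block == "vt_ai":
            cols.extend(vt_ai_cols)
        else:
            cols.extend(cfg.blocks[block])
    cols.extend(model_spec.get("extra", []))
    seen, out = set(), []
    for c in cols:
        if c not in seen:
            seen.add(c)
            out.append(c)
    return out


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Execute the full synthetic-cohort analysis; returns the report dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": cfg.hash(), "seed": cfg.seed}
    flow: dict[str, int] = {}

    # 1. cohort simulation
    spec = synthetic.CohortSpec(
        n_patients=cfg.n_patients, mace_rate=cfg.mace_rate, seed=cfg.seed,
        diastasis_threshold_frac=cfg.diastasis_threshold_frac)
    patients, features = synthetic.generate_cohort(spec)
    flow["simulated"] = len(patients)
    write_transients_csv([p.transient for p in patients],
                         outdir / "transients.csv")
    with open(outdir / "planted_truth.json", "w") as fh:
        json.dump({"stamp": stamp,
                   "patients": synthetic.planted_truth_records(patients)}, fh)

    # 2-3. landmark detection + conventional metrics
    rows = []
    for p in patients:
        m = metrics_mod.transient_metrics(
            p.transient, rr_list_ms=p.rr_list_ms,
            threshold_frac=cfg.diastasis_threshold_frac,
            upsample_factor=cfg.upsample_factor)
        rows.append(m.to_row())
    metrics_df = pd.DataFrame(rows)
    metrics_df.to_csv(outdir / "metrics.csv", index=False)
    flow["no_diastasis"] = int((~metrics_df["diastasis_found"]).sum())
    logger.info("diastasis not found in %d/%d patients",
                flow["no_diastasis"], len(patients))

    # 4. transient atlas + mode weights
    normalized = [atlas_mod.normalize_transient(p.transient, cfg.grid_points)
                  for p in patients]
    atl = atlas_mod.fit_atlas(normalized, cfg.variance_threshold,
                              metadata=stamp)
    atl.to_json(outdir / "atlas.json")
    weights = atlas_mod.project_cohort(atl, normalized)
    weights.to_csv(outdir / "weights.csv", index=False)
    vt_ai_cols = [c for c in weights.columns if c.startswith("vt_ai_")]

    # merged feature table
    drop = ["sv_ml", "esv_ml", "edv_ml", "ef_pct"]  # already covariates
    table = (features
             .merge(metrics_df.drop(columns=drop), on="patient_id")
             .merge(weights, on="patient_id"))
    table.to_csv(outdir / "features.csv", index=False)

    # 5. stepwise models + repeated CV
    report_models = {}
    for model_spec in cfg.models:
        name = model_spec["name"]
        candidates = _candidate_columns(cfg, model_spec, vt_ai_cols)
        complete = int(table.dropna(subset=candidates).shape[0])
        flow[f"complete_cases_{name}"] = complete
        entry = {"candidates": candidates, "complete_cases": complete}
        for family in ("lda", "cox"):
            sel = models_mod.backward_stepwise(table, candidates, family)
            fam_entry = {
                "selected": sel.selected_variables,
                "coefficients": sel.coefficients,
                "p_values": sel.p_values,
                "n_used": sel.n_used,
                "trace": sel.elimination_trace,
            }
            variables = sel.selected_variables or candidates
            fam_entry["selection_empty"] = not sel.selected_variables
            try:
                perf = models_mod.evaluate_cv(
                    table, variables, family=family, k=cfg.cv_k,
                    n_splits=cfg.cv_n_splits, seed=cfg.seed)
                fam_entry["performance"] = {
                    "metric": perf.metric,
                    "resubstitution": perf.resubstitution,
                    "cv_median": perf.median,
                    "cv_iqr": perf.iqr,
                    "cv_values": perf.values.tolist(),
                }
            except Exception as err:  # e.g. singular Cox fit at small n
                logger.warning("CV for model %s (%s) failed: %s",
                               name, family, err)
                fam_entry["performance"] = {"error": f"{type(err).__name__}: {err}"}
            entry[family] = fam_entry
        report_models[name] = entry
        with open(outdir / f"model_{name}.json", "w") as fh:
            json.dump({"stamp": stamp, **entry}, fh, indent=1)

    report = {
        "stamp": stamp,
        "n_patients": len(patients),
        "n_events": int(features["mace"].sum()),
        "patient_flow": flow,
        "atlas": {"n_modes": atl.n_modes,
                  "cumulative_variance": atl.cumulative_variance.tolist()},
        "models": report_models,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    (outdir / "report.txt").write_text(format_report(report))
    return report


def format_report(report: dict) -> str:
    """Model-table text summary (selection + AUC_k/AUC_RS, C_k/C_RS)."""
    lines = [
        f"run {report['stamp']['config_hash']} seed {report['stamp']['seed']}",
        f"patients {report['n_patients']}  events {report['n_events']}",
        f"atlas modes {report['atlas']['n_modes']}",
        "",
        f"{'model':<12}{'LDA selection':<42}{'AUC_k':>8}{'AUC_RS':>8}"
        f"{'C_k':>8}{'C_RS':>8}",
    ]
    def _fmt(perf, key):
        return f"{perf[key]:>8.3f}" if key in perf else f"{'n/a':>8}"

    for name, entry in report["models"].items():
        lda, cox = entry["lda"], entry["cox"]
        sel = ", ".join(lda["selected"]) or "(none)"
        lines.append(
            f"{name:<12}{sel[:40]:<42}"
            + _fmt(lda["performance"], "cv_median")
            + _fmt(lda["performance"], "resubstitution")
            + _fmt(cox["performance"], "cv_median")
            + _fmt(cox["performance"], "resubstitution"))
    return "\n".join(lines) + "\n"
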