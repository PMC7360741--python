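"""End-to-end orchestration: QC -> dissection -> features -> models ->
evaluation -> networks, with all artifacts written under one output
directory and every stochastic step driven by the run seed."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import dissection, evaluation, features, io, model, networks, qc
from .config import RunConfig
from .tables import CellTable, ReconciliationError, validate_survival

log = logging.getLogger(__name__)

DOMAIN_KEYS = ("epithelial", "stromal", "epi_stromal")


@dataclass
class PipelineResult:
    config: RunConfig
    qc_counts: dict
    feature_tables: dict  # domain -> DataFrame (patients x features), plus "spot"
    spatial_model: model.SpatialModel
    null_model: model.DomainModel
    clinical_model: model.ClinicalModel | None
    risk_scores: pd.Series
    evaluation: dict
    networks: dict
    out_dir: Path | None = None


def extract_features(
    cells: CellTable, config: RunConfig
) -> tuple[dict, dict]:
    """Per-patient domain dissection + feature tables.

    Returns ``(feature_tables, domain_cells)``: feature tables for the three
    spatial domains plus the undissected ``spot``, and the per-patient
    per-domain cell tables (needed later for network inference).
    """
    domain_tables: dict[str, dict] = {k: {} for k in (*DOMAIN_KEYS, "spot")}
    thresholds: dict = {}
    for spot_id in cells.spots():
        spot = cells.subset_spot(spot_id)
        thresholds[spot_id] = features.spot_thresholds(spot, config.percentile_threshold)
        domains, _ = dissection.dissect_spot(
            spot, config.circle_diameter_um, config.center_spacing_um
        )
        for key in DOMAIN_KEYS:
            domain_tables[key][spot_id] = domains[key]
        domain_tables["spot"][spot_id] = spot
    tables = {
        key: features.cohort_feature_table(tabs, thresholds, config.percentile_threshold)
        for key, tabs in domain_tables.items()
    }
    return tables, {"cells": domain_tables, "thresholds": thresholds}


def run_pipeline(
    cells: CellTable,
    surv: pd.DataFrame,
    config: RunConfig,
    models_to_compare=("spatial", "null"),
) -> PipelineResult:
    """Execute the full analysis on an in-memory cohort.

    Raises :class:`ReconciliationError` when cell spots and survival patients
    disagree.  Re-running with the same config/seed reproduces every
    stochastic output exactly.
    """
    surv = validate_survival(surv.reset_index(drop=True))
    spot_ids = {str(s) for s in cells.spots()}
    patient_ids = set(surv.index)
    if spot_ids != patient_ids:
        orphans = sorted(spot_ids ^ patient_ids)
        raise ReconciliationError(f"cell/survival patient mismatch; orphans: {orphans}")

    table = cells.validate()
    if config.intensities_raw:
        table = qc.log2_transform(
            CellTable(df=table.df, panel=table.panel, log2_applied=False)
        )
    table, counts = qc.filter_cells(table, config.min_cell_size_px, config.min_quality)
    table = qc.median_normalize(table)

    raw_tables, domain_info = extract_features(table, config)
    feature_tables = {}
    for key, tab in raw_tables.items():
        tab.index = tab.index.map(str)
        complete, _ = features.complete_features(tab.loc[surv.index], config.max_missing_fraction)
        feature_tables[key] = complete
    intensity_table = feature_tables["spot"][
        [c for c in feature_tables["spot"].columns if c.startswith("mean__")]
    ]

    fit_kw = dict(
        n_boot=config.n_bootstraps,
        threshold=config.stability_threshold,
        seed=config.seed,
        horizon_years=config.horizon_years,
    )
    spatial = model.fit_spatial_model(
        {k: feature_tables[k] for k in DOMAIN_KEYS}, surv, **fit_kw
    )
    null = model.fit_null_model(feature_tables["spot"], surv, domain="null", **fit_kw)
    clinical = None
    if {"stage", "age", "gender"} <= set(surv.columns):
        clinical = model.fit_clinical_model(surv)

    risk = spatial.combined_risk({k: feature_tables[k] for k in DOMAIN_KEYS})

    report = _evaluate(feature_tables, intensity_table, surv, config, models_to_compare)
    nets = _infer_networks(spatial, domain_info, surv, config)
    return PipelineResult(
        config=config,
        qc_counts=counts,
        feature_tables=feature_tables,
        spatial_model=spatial,
        null_model=null,
        clinical_model=clinical,
        risk_scores=risk,
        evaluation=report,
        networks=nets,
    )


def _evaluate(feature_tables, intensity_table, surv, config: RunConfig, models_to_compare):
    domain_features = {k: feature_tables[k] for k in DOMAIN_KEYS}
    comparison = evaluation.compare_models(
        domain_features,
        feature_tables["spot"],
        intensity_table,
        surv,
        n_boot=config.n_eval_splits,
        seed=config.seed,
        horizon_years=config.horizon_years,
        stability_boots=config.n_bootstraps,
        stability_threshold=config.stability_threshold,
        models=models_to_compare,
    )
    report = {"model_comparison": comparison}
    # single full-data operating characteristics for the spatial score
    sm = model.fit_spatial_model(
        domain_features, surv,
        n_boot=config.n_bootstraps, threshold=config.stability_threshold,
        seed=config.seed, horizon_years=config.horizon_years,
    )
    scores = sm.log_risk(domain_features)
    labels, usable = evaluation.binary_outcome_at_horizon(surv, config.horizon_years)
    if labels[usable].nunique() == 2:
        roc = evaluation.roc_curve(scores[usable], labels[usable])
        thr, sens, spec = evaluation.youden_operating_point(roc)
        lr_plus, lr_minus = evaluation.likelihood_ratios(sens, spec)
        report.update(
            auc=roc.auc, sensitivity=sens, specificity=spec,
            lr_plus=lr_plus, lr_minus=lr_minus, youden_threshold=thr,
        )
        report["km"] = evaluation.km_curves(scores, surv, thr)
        grid = np.arange(1.0, config.horizon_years + 0.5)
        report["auc_t"] = evaluation.time_dependent_auc(scores, surv, grid)
    return report


def _infer_networks(spatial, domain_info, surv, config: RunConfig):
    out = {}
    outcomes = surv["event"]
    for domain in DOMAIN_KEYS:
        markers = spatial.selected_biomarkers(domain)
        if len(markers) < 2:
            log.warning("domain %s: <2 selected biomarkers; skipping network", domain)
            continue
        partials = {}
        for pid, tab in domain_info["cells"][domain].items():
            pid = str(pid)
            if pid not in outcomes.index or tab.n_cells < 3:
                continue
            try:
                C, _ = networks.build_correlation_matrix(
                    tab, markers, config.percentile_threshold, domain_info["thresholds"].get(pid)
                )
                partials[pid] = networks.partial_correlations(C)
            except (ValueError, np.linalg.LinAlgError) as exc:
                log.warning("patient %s domain %s: correlation matrix failed (%s)", pid, domain, exc)
        try:
            D = networks.distance_matrix(partials, outcomes, config.network_bins)
            out[domain] = {
                "distance_matrix": D,
                "network": networks.threshold_network(D, config.network_percentile),
            }
        except ValueError as exc:
            log.warning("domain %s: network inference skipped (%s)", domain, exc)
    return out


def write_results(result: PipelineResult, out_dir) -> Path:
    """Persist feature tables, models, evaluation CSVs, and networks, each
    with a JSON sidecar carrying the config hash and seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    for key, tab in result.feature_tables.items():
        path = out / f"features_{key}.csv"
        tab.to_csv(path)
        io.write_sidecar(path, cfg)
    io.write_json(
        {
            "domains": {k: m.to_dict() for k, m in result.spatial_model.models.items()},
            "null": result.null_model.to_dict(),
            "clinical": (
                result.clinical_model.beta.to_dict() if result.clinical_model else None
            ),
            "config_hash": cfg.hash(),
            "seed": cfg.seed,
        },
        out / "model.json",
    )
    result.risk_scores.rename("risk").to_csv(out / "risk_scores.csv")
    io.write_sidecar(out / "risk_scores.csv", cfg)
    stab = []
    for name, m in result.spatial_model.models.items():
        for kind, rep in (("selection", m.selection_report), ("sign", m.sign_report)):
            if rep is None:
                continue
            frame = rep.frequency.rename("frequency").rename_axis("feature").reset_index()
            frame.insert(0, "screen", kind)
            frame.insert(0, "domain", name)
            frame["n_bootstraps"] = rep.n_bootstraps
            frame["threshold"] = rep.threshold
            stab.append(frame)
    if stab:
        pd.concat(stab, ignore_index=True).to_csv(out / "stability_report.csv", index=False)
        io.write_sidecar(out / "stability_report.csv", cfg)
    ev = result.evaluation
    ev["model_comparison"].to_csv(out / "model_comparison.csv", index_label="split")
    scalars = {k: v for k, v in ev.items() if isinstance(v, (int, float))}
    if scalars:
        io.write_json(scalars, out / "operating_point.json")
    if "auc_t" in ev:
        ev["auc_t"].rename("auc").to_csv(out / "auc_t.csv", index_label="time")
    if "km" in ev:
        for grp, curve in ev["km"].items():
            curve.to_csv(out / f"km_{grp}.csv", index=False)
    for domain, net in result.networks.items():
        net["distance_matrix"].to_csv(out / f"distance_{domain}.csv")
        networks.export_network(net["network"], out / f"network_{domain}")
    result.out_dir = out
    return out
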