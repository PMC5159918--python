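"""End-to-end orchestration: simulate -> QC -> bulk-density model ->
accounting -> classification -> disturbance screening -> estimation.

Stages communicate through plain CSV/JSON files in a run directory so a
run is inspectable and re-runnable; every stage is a pure function of
(inputs, config, seed).  ``run_pipeline`` is the library entry point;
the command-line interface wraps it thinly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, accounting, bdmodel, io, qc
from .classify import carbon_type, classify_soil
from .disturbance import calibrate_most_thresholds, gradient_summary, screen_sites
from .estimation import estimate_subpopulation, scale_to_target
from .model import SiteRecord, SoilHorizon
from .simulate import DEPTH_RANGES, SimulationConfig, generate_population, sample_survey

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "default_config", "build_per_site_table",
           "estimate_all", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage received an inconsistent configuration or inputs."""


def default_config() -> dict:
    """A self-contained synthetic-run configuration."""
    return {
        "seed": 0,
        "simulation": {},  # SimulationConfig overrides; present => simulate
        "bd_model": {"enabled": True, "n_trees": 500, "shrinkage": 0.05,
                     "max_tree_depth": 3, "bag_fraction": 0.5,
                     "train_fraction": 0.70},
        "depth_ranges": [list(r) for r in DEPTH_RANGES],
        "disturbance": {"target_fraction": 0.25, "least_target_fraction": 0.25},
        "target_area_Mha": None,  # optional inference->target scaling
    }


def _merged_config(config: dict | str | Path | None) -> dict:
    cfg = default_config()
    if config is None:
        return cfg
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    for k, v in config.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _impenetrable_depth(horizons: list[SoilHorizon]) -> float | None:
    bottom = max(h.bottom_depth_cm for h in horizons)
    return bottom if bottom < accounting.MAX_DEPTH_CM else None


def build_per_site_table(sites: list[SiteRecord],
                         profiles: dict[str, list[SoilHorizon]],
                         assignments: dict[str, str | None],
                         depth_ranges: list[tuple[int, int]],
                         ) -> pd.DataFrame:
    """Per-site summary: labels, classes and depth-range densities."""
    rows = []
    for s in sites:
        horizons = profiles.get(s.site_id)
        if not horizons:
            continue
        sliced = accounting.slice_profile(horizons)
        row = {
            "site_id": s.site_id,
            "reporting_group": s.reporting_group,
            "region": s.region,
            "carbon_type": carbon_type(s),
            "soil_class": classify_soil(horizons, _impenetrable_depth(horizons)),
            "disturbance_class": assignments.get(s.site_id),
            "probability_site": s.probability_site,
            "weight_ha": s.weight_ha,
        }
        for lo, hi in depth_ranges:
            row[f"density_{lo}_{hi}_tC_ha"] = accounting.depth_range_density(
                sliced, lo, hi)
        rows.append(row)
    return pd.DataFrame(rows)


def _groupings(df: pd.DataFrame) -> list[tuple[str, pd.Series]]:
    subs: list[tuple[str, pd.Series]] = [("national", pd.Series(True, index=df.index))]
    for col, prefix in (("region", "region"), ("carbon_type", "carbon"),
                        ("disturbance_class", "disturbance"),
                        ("soil_class", "soil"), ("reporting_group", "group")):
        for val in sorted(df[col].dropna().unique()):
            subs.append((f"{prefix}:{val}", df[col] == val))
    return subs


def estimate_all(per_site: pd.DataFrame,
                 depth_ranges: list[tuple[int, int]],
                 target_area_Mha: float | None = None) -> list:
    """Design-based estimates for every subpopulation x depth range.

    Only probability sites contribute.  With ``target_area_Mha`` set,
    national-row totals are additionally scaled by the common ratio of
    the target area to the full realized inference area (the summed
    weight of all probability sites) and appended with subpopulation
    suffix ``"|target"`` — every depth row scales by the same factor,
    mirroring the assumption that the unsampled area follows the same
    trends.
    """
    prob = per_site[per_site["probability_site"]]
    estimates = []
    for sub, mask in _groupings(prob):
        sel = prob[mask]
        for lo, hi in depth_ranges:
            est = estimate_subpopulation(
                sel[f"density_{lo}_{hi}_tC_ha"].to_numpy(),
                sel["weight_ha"].to_numpy(), sub, lo, hi)
            estimates.append(est)
    if target_area_Mha is not None:
        inference_area_Mha = float(prob["weight_ha"].sum()) / 1e6
        national = [e for e in estimates if e.subpopulation == "national"
                    and e.n_sites > 0]
        for e in national:
            scaled = scale_to_target(e, inference_area_Mha,
                                     float(target_area_Mha))
            scaled.subpopulation = "national|target"
            estimates.append(scaled)
    return estimates


def run_pipeline(config: dict | str | Path | None, out_dir: str | Path,
                 seed: int | None = None) -> dict:
    """Run every stage and write artifacts under ``out_dir``.

    Returns a dict with the in-memory products (sites, profiles,
    per-site table, estimates, QC report, model metrics, manifest).
    ``seed`` overrides the config seed.
    """
    cfg = _merged_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = {}

    # --- inputs: simulate or load -------------------------------------
    if "inputs" in cfg and cfg["inputs"]:
        sites = io.read_sites(cfg["inputs"]["sites"])
        profiles = io.read_horizons(cfg["inputs"]["horizons"])
        nonprob = [s for s in sites if not s.probability_site]
        sites = [s for s in sites if s.probability_site]
        truth = None
    else:
        sim = SimulationConfig(**{"seed": cfg["seed"], **cfg["simulation"]})
        population, pop_profiles, truth = generate_population(sim)
        sampled, nonprob = sample_survey(population, sim)
        sites = sampled
        profiles = {s.site_id: pop_profiles[s.site_id]
                    for s in sampled + nonprob}
        io.write_sites(sampled + nonprob, out / "sites.csv")
        io.write_horizons(profiles, out / "horizons.csv")
        with open(out / "truth.json", "w") as fh:
            json.dump({"true_total_PgC": {f"{k[0]}|{k[1]}": v for k, v in
                                          truth.true_total_PgC.items()},
                       "true_mean_tC_ha": {f"{k[0]}|{k[1]}": v for k, v in
                                           truth.true_mean_tC_ha.items()}},
                      fh, indent=1)
    counts["sites_probability"] = len(sites)
    counts["sites_nonprobability"] = len(nonprob)
    counts["horizons"] = sum(len(v) for v in profiles.values())

    # --- QC: carbon imputation ----------------------------------------
    report = qc.QCReport()
    usable: dict[str, list[SoilHorizon]] = {}
    for sid, horizons in profiles.items():
        try:
            usable[sid] = qc.impute_missing_carbon(horizons, report)
        except qc.UnusableSiteError:
            log.warning("%s: excluded (no SOC data in any horizon)", sid)
    counts["sites_unusable"] = len(profiles) - len(usable)

    # --- bulk-density model -------------------------------------------
    site_lookup = {s.site_id: s for s in list(sites) + list(nonprob)}
    frame = bdmodel.horizons_to_frame(usable, site_lookup)
    any_missing_bd = frame["bd_g_cm3"].isna().any()
    bd_cfg = dict(cfg["bd_model"])
    enabled = bd_cfg.pop("enabled", True)
    metrics = None
    if not enabled:
        if any_missing_bd:
            raise PipelineError(
                "bd_model.enabled is false but the horizon table has missing "
                "bulk density; enable the model or supply complete data")
        modelled_by_site = {sid: {} for sid in usable}
    else:
        spec = bdmodel.BDModelSpec(seed=cfg["seed"], **bd_cfg)
        train = frame[(frame["bd_source"] == "measured")
                      & frame["bd_g_cm3"].notna()
                      & (frame["bd_g_cm3"] <= qc.BD_UPPER_LIMIT)
                      & frame["soc_pct"].notna()]
        fit = bdmodel.fit_bd_model(train, spec)
        metrics = {"holdout_r2": fit.holdout_r2, "importance": fit.importance,
                   "n_train": int(len(train))}
        with open(out / "bd_metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=1)
        pred = bdmodel.predict_bd(fit, frame)
        frame = frame.assign(bd_modelled=pred)
        modelled_by_site = {
            sid: dict(zip(g["horizon_order"], g["bd_modelled"]))
            for sid, g in frame.groupby("site_id")}

    # --- bulk-density screening ---------------------------------------
    for sid, horizons in usable.items():
        qc.screen_bulk_density(horizons, modelled_by_site.get(sid, {}), report)
    with open(out / "qc_report.json", "w") as fh:
        json.dump({"totals": report.totals(),
                   "sites": {k: v.as_dict() for k, v in report.sites.items()}},
                  fh, indent=1)

    # --- disturbance screening ----------------------------------------
    screened = list(sites) + list(nonprob)
    thresholds = calibrate_most_thresholds(
        screened, target_fraction=cfg["disturbance"]["target_fraction"],
        least_target_fraction=cfg["disturbance"]["least_target_fraction"],
        least_quantile=cfg["disturbance"].get("least_quantile"),
        min_group_size=cfg["disturbance"].get("min_group_size", 20))
    assignments = screen_sites(screened, thresholds)
    gradient = gradient_summary(assignments)
    counts["disturbance_gradient"] = gradient

    # --- accounting + classification + estimation ---------------------
    ranges = [tuple(r) for r in cfg["depth_ranges"]]
    per_site = build_per_site_table(
        [s for s in sites if s.site_id in usable], usable, assignments, ranges)
    per_site.to_csv(out / "per_site.csv", index=False)
    estimates = estimate_all(per_site, ranges, cfg.get("target_area_Mha"))
    io.write_estimates(estimates, out / "estimates.csv")
    counts["estimates"] = len(estimates)

    manifest = {
        "version": __version__,
        "seed": cfg["seed"],
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest(),
        "row_counts": counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return {"sites": sites, "nonprobability_sites": nonprob,
            "profiles": usable, "truth": truth, "per_site": per_site,
            "estimates": estimates, "qc_report": report,
            "bd_metrics": metrics, "gradient": gradient,
            "thresholds": thresholds, "manifest": manifest}
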