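"""End-to-end orchestration: ingest -> covariates -> summaries -> models.

Every stage logs its row counts; outputs are deterministic given the config
(the only randomness in a pipeline run lives in the synthetic generator,
which takes its own seed).  Existing outputs are never overwritten unless
`config.force` is set.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import __version__
from .config import RunConfig
from .covariates import compute_camera_covariates, read_ascii_grid
from .errors import ValidationError
from .ingest import (
    build_events,
    events_to_frame,
    read_deployments_csv,
    read_photos_csv,
    write_events_csv,
)
from .models import (
    DesignSpec,
    build_model_frame,
    fit_binomial_glmm,
    fit_timing_lm,
    save_fit_json,
)
from .summaries import monthly_diurnal_proportion, site_nocturnality_flags, summarize_sites

log = logging.getLogger("armadiel")

__all__ = ["run_pipeline", "setup_logging"]


def setup_logging(log_file: Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if log_file is not None:
        handlers.append(logging.FileHandler(log_file, mode="w"))
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


def _check_overwrite(paths: list[Path], force: bool) -> None:
    existing = [str(p) for p in paths if p.exists()]
    if existing and not force:
        raise ValidationError(
            f"outputs exist (use --force to overwrite): {existing[:3]}"
        )


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage and return the output bundle paths."""
    config.require_inputs()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    setup_logging(out / "run.log")
    log.info("armadiel %s starting; output -> %s", __version__, out)
    log.info(
        "parameters: species=%r gap=%.1f min buffer=%.0f m offset=%d min seed=%d",
        config.species_filter, config.gap_minutes, config.buffer_radius_m,
        config.utc_offset_minutes, config.seed,
    )

    paths = {
        "events": out / "events.csv",
        "covariates": out / "covariates.csv",
        "site_summaries": out / "site_summaries.csv",
        "site_summaries_json": out / "site_summaries.json",
        "monthly": out / "monthly_diurnal.csv",
        "glmm": out / "glmm_diurnality.json",
        "glmm_txt": out / "glmm_diurnality.txt",
        "timing": out / "timing_lm.json",
        "fig_diurnal_by_site": out / "fig_diurnal_by_site.png",
        "fig_timing_by_site": out / "fig_timing_by_site.png",
    }
    _check_overwrite(list(paths.values()), config.force)

    # --- ingest ---------------------------------------------------------
    photos = read_photos_csv(config.photos)
    deployments = read_deployments_csv(config.deployments)
    log.info("ingest: %d photo rows, %d cameras", len(photos), len(deployments))
    events = build_events(
        photos,
        deployments,
        species=config.species_filter,
        gap_minutes=config.gap_minutes,
        utc_offset_minutes=config.utc_offset_minutes,
        per_date_classification=config.per_date_classification,
    )
    write_events_csv(events, paths["events"])
    events_df = events_to_frame(events)
    n_night = int((events_df["diel_class"] == "NIGHT").sum()) if len(events_df) else 0
    log.info("ingest: %d detection events (%d nocturnal)", len(events_df), n_night)

    # --- covariates -----------------------------------------------------
    landcover = read_ascii_grid(config.landcover_raster)
    sound = read_ascii_grid(config.sound_raster)
    covariates = compute_camera_covariates(
        deployments,
        landcover,
        sound,
        forest_codes=config.forest_codes,
        developed_codes=config.developed_codes,
        buffer_radius_m=config.buffer_radius_m,
        anchor=config.anchor,
        raster_origin=config.anchor,
    )
    covariates.to_csv(paths["covariates"], index=False, float_format="%.6f")
    log.info("covariates: %d camera rows", len(covariates))

    # --- summaries ------------------------------------------------------
    site_table = summarize_sites(events_df, deployments, covariates)
    site_table.to_csv(paths["site_summaries"], index=False, float_format="%.6f")
    paths["site_summaries_json"].write_text(
        json.dumps(site_table.to_dict(orient="records"), indent=2, default=float) + "\n"
    )
    monthly = monthly_diurnal_proportion(events_df)
    monthly.to_csv(paths["monthly"], index=False, float_format="%.6f")
    n_flagged = site_nocturnality_flags(site_table, config.nocturnality_threshold_pct)
    log.info(
        "summaries: %d sites, %d detections, %d sites >%g%% nocturnal",
        len(site_table) - 1,
        int(site_table.iloc[-1]["n_detections"]),
        n_flagged,
        config.nocturnality_threshold_pct,
    )
    _report_figures(site_table, covariates, paths)

    # --- models ---------------------------------------------------------
    if events_df.empty:
        log.warning("no detection events: model fitting skipped")
        for key in ("glmm", "glmm_txt", "timing"):
            paths.pop(key)
        return paths
    frame = build_model_frame(events_df, covariates)
    glmm = fit_binomial_glmm(
        frame,
        DesignSpec(fixed_terms=config.fixed_terms),
        quad_points=config.quad_points,
    )
    save_fit_json(glmm, paths["glmm"])
    paths["glmm_txt"].write_text(glmm.summary_text() + "\n")
    log.info(
        "glmm: logLik=%.2f sigma_site=%.3f converged=%s",
        glmm.loglik, glmm.sigma_site, glmm.converged,
    )
    timing = fit_timing_lm(frame, config.timing_terms)
    save_fit_json(timing, paths["timing"])
    log.info(
        "timing lm: n=%d F=%.2f (df %d, %d)",
        timing.n_obs, timing.f_overall.statistic,
        timing.f_overall.df_num, timing.f_overall.df_den,
    )
    log.info("pipeline complete")
    return paths


def _report_figures(site_table: pd.DataFrame, covariates: pd.DataFrame, paths: dict) -> None:
    """Bar charts of per-site diurnal share and mean nocturnal timing,
    sites ordered nearest-to-farthest from the population center."""
    sites = site_table[site_table["site_id"] != "Total"].copy()
    if "mean_dist_downtown_km" in sites.columns:
        sites = sites.sort_values("mean_dist_downtown_km")
    for col, ylabel, key in (
        ("pct_diurnal", "Detections during the day (%)", "fig_diurnal_by_site"),
        ("mean_minutes_after_sunset", "Mean minutes after sunset", "fig_timing_by_site"),
    ):
        fig, ax = plt.subplots(figsize=(8, 4))
        ax.bar(sites["site_id"], sites[col], color="#4878a8")
        for x, (v, n) in enumerate(zip(sites[col], sites["n_detections"])):
            if pd.notna(v):
                ax.annotate(str(int(n)), (x, v), ha="center", va="bottom", fontsize=8)
        ax.set_ylabel(ylabel)
        ax.set_xticks(range(len(sites)))
        ax.set_xticklabels(sites["site_id"], rotation=45, ha="right", fontsize=8)
        fig.tight_layout()
        fig.savefig(paths[key], dpi=120)
        plt.close(fig)
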