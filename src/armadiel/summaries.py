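"""Descriptive site- and month-level summaries of detection events.

The central product is the per-site summary table: effort (trap nights,
cameras), detection counts, diurnal share, mean nocturnal timing, and mean
landscape covariates — plus a study-total row whose means are detection-
weighted combinations of the site means (nocturnal-count weights for timing),
which is the weighting under which the per-site rows and the total row are
mutually consistent.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .ingest import CameraDeployment

TOTAL_ROW_ID = "Total"

__all__ = ["summarize_sites", "monthly_diurnal_proportion", "site_nocturnality_flags"]


def summarize_sites(
    events: pd.DataFrame,
    deployments: Mapping[str, CameraDeployment],
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-site summary rows plus a study-total row.

    Parameters
    ----------
    events
        Classified events table (site_id, camera_id, diel_class,
        minutes_after_sunset).  Sites present in `deployments` but without
        events are retained with zero counts and empty means.
    deployments
        Camera deployments; effort (trap nights, camera count) comes from
        here, so sites are summarized even when a camera recorded nothing.
    covariates
        Optional per-camera covariates; site means of distance and sound are
        unweighted camera averages.

    The total row sums effort and counts; mean minutes-after-sunset is the
    nocturnal-count-weighted mean of site means, and mean distance/sound are
    detection-weighted means of site means.
    """
    unknown = set(events["camera_id"]) - set(deployments)
    if unknown:
        raise ValidationError(f"events reference unknown cameras {sorted(unknown)[:5]}")

    dep_df = pd.DataFrame(
        {
            "camera_id": [d.camera_id for d in deployments.values()],
            "site_id": [d.site_id for d in deployments.values()],
            "trap_nights": [d.trap_nights for d in deployments.values()],
        }
    )
    effort = dep_df.groupby("site_id").agg(
        trap_nights=("trap_nights", "sum"), n_cameras=("camera_id", "nunique")
    )

    rows = []
    for site_id in effort.index:
        ev = events[events["site_id"] == site_id]
        n_det = len(ev)
        n_diu = int((ev["diel_class"] == "DAY").sum())
        mas = ev["minutes_after_sunset"].dropna().astype(float)
        row = {
            "site_id": site_id,
            "trap_nights": int(effort.loc[site_id, "trap_nights"]),
            "n_cameras": int(effort.loc[site_id, "n_cameras"]),
            "n_detections": n_det,
            "n_diurnal": n_diu,
            "pct_diurnal": 100.0 * n_diu / n_det if n_det else np.nan,
            "mean_minutes_after_sunset": mas.mean() if len(mas) else np.nan,
            "sd_minutes_after_sunset": mas.std(ddof=1) if len(mas) > 1 else np.nan,
        }
        if covariates is not None:
            cams = covariates[covariates["site_id"] == site_id]
            row["mean_dist_downtown_km"] = cams["dist_downtown_km"].mean()
            row["mean_sound_db"] = cams["sound_L50_db"].mean()
        rows.append(row)
    table = pd.DataFrame(rows)

    n_noct = table["n_detections"] - table["n_diurnal"]
    total = {
        "site_id": TOTAL_ROW_ID,
        "trap_nights": int(table["trap_nights"].sum()),
        "n_cameras": int(table["n_cameras"].sum()),
        "n_detections": int(table["n_detections"].sum()),
        "n_diurnal": int(table["n_diurnal"].sum()),
    }
    total["pct_diurnal"] = (
        100.0 * total["n_diurnal"] / total["n_detections"] if total["n_detections"] else np.nan
    )
    total["mean_minutes_after_sunset"] = _weighted_mean(
        table["mean_minutes_after_sunset"], n_noct
    )
    total["sd_minutes_after_sunset"] = np.nan
    if covariates is not None:
        total["mean_dist_downtown_km"] = _weighted_mean(
            table["mean_dist_downtown_km"], table["n_detections"]
        )
        total["mean_sound_db"] = _weighted_mean(
            table["mean_sound_db"], table["n_detections"]
        )
    return pd.concat([table, pd.DataFrame([total])], ignore_index=True)


def _weighted_mean(values: pd.Series, weights: pd.Series) -> float:
    v = values.to_numpy(dtype=float)
    w = weights.to_numpy(dtype=float)
    ok = np.isfinite(v) & (w > 0)
    if not ok.any():
        return float("nan")
    return float(np.average(v[ok], weights=w[ok]))


def monthly_diurnal_proportion(events: pd.DataFrame) -> pd.DataFrame:
    """Per-month detection count, diurnal count and diurnal proportion.

    Months are 'YYYY-MM' stamps from the events table, reported in calendar
    order; the `no_events` flag marks months present in the span but empty.
    """
    if events.empty:
        return pd.DataFrame(
            columns=["month", "n", "n_diurnal", "proportion_diurnal", "no_events"]
        )
    grouped = events.groupby("month").agg(
        n=("diel_class", "size"),
        n_diurnal=("diel_class", lambda s: int((s == "DAY").sum())),
    )
    months = sorted(grouped.index)
    full_range = pd.period_range(months[0], months[-1], freq="M").strftime("%Y-%m")
    out = grouped.reindex(full_range)
    out["no_events"] = out["n"].isna()
    out["n"] = out["n"].fillna(0).astype(int)
    out["n_diurnal"] = out["n_diurnal"].fillna(0).astype(int)
    out["proportion_diurnal"] = np.where(
        out["n"] > 0, out["n_diurnal"] / out["n"].replace(0, 1), np.nan
    )
    return out.reset_index(names="month")[
        ["month", "n", "n_diurnal", "proportion_diurnal", "no_events"]
    ]


def site_nocturnality_flags(summaries: pd.DataFrame, threshold_pct: float = 95.0) -> int:
    """Number of sites whose nocturnal share exceeds `threshold_pct` percent.

    Operates on the :func:`summarize_sites` output; the total row and sites
    without detections are excluded.  The comparison is strict, except that a
    threshold of 100 counts the exactly-fully-nocturnal sites (nocturnality
    cannot exceed 100, so a strict comparison would be vacuous there).
    """
    sites = summaries[summaries["site_id"] != TOTAL_ROW_ID]
    sites = sites[sites["n_detections"] > 0]
    nocturnality = 100.0 - sites["pct_diurnal"]
    if threshold_pct >= 100.0:
        return int((sites["n_diurnal"] == 0).sum())
    return int((nocturnality > threshold_pct).sum())
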