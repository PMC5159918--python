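"""Readers and writers for the site, horizon and estimate tables.

All files are UTF-8 comma-delimited text with a header row.  Missing
values are empty fields, never numeric sentinels.  Column names are
documented in ``docs/data_dictionary.md``.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from pathlib import Path

import pandas as pd

from .model import (
    DISTURBANCE_MEASURES,
    PopulationEstimate,
    ProfileError,
    SchemaError,
    SiteRecord,
    SoilHorizon,
)

log = logging.getLogger(__name__)

SITE_COLUMNS = [
    "site_id", "reporting_group", "region", "wetland_type", "hgm_class",
    "tidal_saline", "weight_ha", "probability_site",
] + [f"dist_{m}" for m in DISTURBANCE_MEASURES]

HORIZON_COLUMNS = [
    "site_id", "horizon_order", "top_depth_cm", "bottom_depth_cm",
    "organic_flag", "total_c_pct", "inorg_c_pct", "soc_pct", "bd_g_cm3",
    "bd_source", "ec", "cec", "sand_pct", "silt_pct", "clay_pct", "thin_flag",
]

ESTIMATE_COLUMNS = [
    "subpopulation", "depth_lo_cm", "depth_hi_cm", "mean_tC_ha", "se_mean",
    "total_PgC", "se_total", "n_sites", "area_Mha",
]

_BOOL = {"true": True, "false": False, "1": True, "0": False}


def _check_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _as_bool(v, path, col) -> bool:
    if isinstance(v, bool):
        return v
    try:
        return _BOOL[str(v).strip().lower()]
    except KeyError:
        raise SchemaError(f"{path}: cannot parse {col}={v!r} as boolean") from None


def _opt(v) -> float | None:
    """NaN (empty CSV field) -> None."""
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def read_sites(path: str | Path) -> list[SiteRecord]:
    """Read and validate the site table.

    Raises :class:`SchemaError` for a malformed header and
    :class:`ValidationError` (naming the site) for invariant violations
    such as a non-positive weight on a probability site.
    """
    df = pd.read_csv(path, dtype={"site_id": str}, float_precision="round_trip")
    _check_columns(df, SITE_COLUMNS, path)
    records = []
    for row in df.itertuples(index=False):
        rec = SiteRecord(
            site_id=row.site_id,
            reporting_group=row.reporting_group,
            region=row.region,
            wetland_type=row.wetland_type,
            hgm_class=str(row.hgm_class),
            tidal_saline=_as_bool(row.tidal_saline, path, "tidal_saline"),
            weight_ha=float(row.weight_ha),
            probability_site=_as_bool(row.probability_site, path, "probability_site"),
            disturbance_indices={
                m: v for m in DISTURBANCE_MEASURES
                if (v := _opt(getattr(row, f"dist_{m}"))) is not None
            },
        )
        rec.validate()
        records.append(rec)
    return records


def read_horizons(path: str | Path) -> dict[str, list[SoilHorizon]]:
    """Read the horizon table, grouped by site and sorted by horizon order.

    Contiguity is enforced: within a site each horizon's top depth must
    equal the previous bottom.  When both total and inorganic carbon are
    present, SOC is recomputed as their difference clipped at zero (a
    recorded soc_pct field is overridden; carbonate-rich samples can
    yield small negatives, which are clipped with a warning).
    """
    df = pd.read_csv(path, dtype={"site_id": str}, float_precision="round_trip")
    _check_columns(df, HORIZON_COLUMNS, path)
    profiles: dict[str, list[SoilHorizon]] = defaultdict(list)
    for row in df.itertuples(index=False):
        h = SoilHorizon(
            site_id=row.site_id,
            horizon_order=int(row.horizon_order),
            top_depth_cm=float(row.top_depth_cm),
            bottom_depth_cm=float(row.bottom_depth_cm),
            organic_flag=_as_bool(row.organic_flag, path, "organic_flag"),
            total_c_pct=_opt(row.total_c_pct),
            inorg_c_pct=_opt(row.inorg_c_pct),
            soc_pct=_opt(row.soc_pct),
            bd_g_cm3=_opt(row.bd_g_cm3),
            bd_source=row.bd_source if isinstance(row.bd_source, str) else "measured",
            ec=_opt(row.ec),
            cec=_opt(row.cec),
            sand_pct=_opt(row.sand_pct),
            silt_pct=_opt(row.silt_pct),
            clay_pct=_opt(row.clay_pct),
            thin_flag=_as_bool(row.thin_flag, path, "thin_flag"),
        )
        recompute_soc(h)
        h.validate()
        profiles[h.site_id].append(h)
    out = {}
    for site_id, horizons in profiles.items():
        horizons.sort(key=lambda h: h.horizon_order)
        check_contiguity(horizons)
        out[site_id] = horizons
    return out


def recompute_soc(h: SoilHorizon) -> None:
    """soc = max(0, total - inorganic) when both components are present."""
    if h.total_c_pct is not None and h.inorg_c_pct is not None:
        soc = h.total_c_pct - h.inorg_c_pct
        if soc < 0:
            log.warning("%s horizon %d: SOC %.4f%% < 0 after carbonate "
                        "subtraction; clipped to 0", h.site_id, h.horizon_order, soc)
            soc = 0.0
        h.soc_pct = soc


def check_contiguity(horizons: list[SoilHorizon]) -> None:
    """Horizons sorted by order must tile [surface, bottom) without gaps."""
    for prev, nxt in zip(horizons, horizons[1:]):
        if abs(nxt.top_depth_cm - prev.bottom_depth_cm) > 1e-9:
            raise ProfileError(
                f"{nxt.site_id}: horizon {nxt.horizon_order} top "
                f"{nxt.top_depth_cm} cm does not meet previous bottom "
                f"{prev.bottom_depth_cm} cm")


def write_sites(records: list[SiteRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {
            "site_id": r.site_id,
            "reporting_group": r.reporting_group,
            "region": r.region,
            "wetland_type": r.wetland_type,
            "hgm_class": r.hgm_class,
            "tidal_saline": r.tidal_saline,
            "weight_ha": r.weight_ha,
            "probability_site": r.probability_site,
        }
        for m in DISTURBANCE_MEASURES:
            row[f"dist_{m}"] = r.disturbance_indices.get(m)
        rows.append(row)
    pd.DataFrame(rows, columns=SITE_COLUMNS).to_csv(path, index=False)


def write_horizons(profiles: dict[str, list[SoilHorizon]], path: str | Path) -> None:
    rows = []
    for horizons in profiles.values():
        for h in horizons:
            rows.append({c: getattr(h, c) for c in HORIZON_COLUMNS})
    pd.DataFrame(rows, columns=HORIZON_COLUMNS).to_csv(path, index=False)


def write_estimates(estimates: list[PopulationEstimate], path: str | Path) -> None:
    """Write estimates as one CSV row per subpopulation x depth range."""
    rows = [{c: getattr(e, c) for c in ESTIMATE_COLUMNS} for e in estimates]
    pd.DataFrame(rows, columns=ESTIMATE_COLUMNS).to_csv(
        path, index=False, float_format="%.10g")


def read_estimates(path: str | Path) -> list[PopulationEstimate]:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, ESTIMATE_COLUMNS, path)
    out = []
    for row in df.itertuples(index=False):
        out.append(PopulationEstimate(
            subpopulation=row.subpopulation,
            depth_lo_cm=float(row.depth_lo_cm),
            depth_hi_cm=float(row.depth_hi_cm),
            mean_tC_ha=float(row.mean_tC_ha),
            se_mean=float(row.se_mean),
            total_PgC=float(row.total_PgC),
            se_total=float(row.se_total),
            n_sites=int(row.n_sites),
            area_Mha=float(row.area_Mha),
        ))
    return out
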