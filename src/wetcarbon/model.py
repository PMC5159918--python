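"""Domain types for wetland soil-carbon accounting.

The vocabulary follows the 2011 National Wetland Condition Assessment
(NWCA): wetland points ("sites") carry design weights in hectares and
categorical reporting labels; each site has an ordered, contiguous stack
of described soil horizons with laboratory chemistry and bulk density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

__all__ = [
    "REPORTING_GROUPS",
    "REGIONS",
    "REGION_BY_GROUP",
    "WETLAND_TYPES",
    "DISTURBANCE_MEASURES",
    "BD_SOURCES",
    "SoilHorizon",
    "SiteRecord",
    "PopulationEstimate",
    "SchemaError",
    "ValidationError",
    "ProfileError",
]

#: The ten NWCA Reporting Groups: tidal saline estuarine wetlands are pooled
#: nationally (ALL-EW woody, ALL-EH herbaceous); inland palustrine/riverine/
#: lacustrine (PRL) wetlands are split by ecoregion (EMU, CPL, IPL, W) and
#: vegetation (W woody, H herbaceous).
REPORTING_GROUPS = (
    "ALL-EW", "ALL-EH",
    "EMU-PRLW", "EMU-PRLH",
    "CPL-PRLW", "CPL-PRLH",
    "IPL-PRLW", "IPL-PRLH",
    "W-PRLW", "W-PRLH",
)

REGIONS = ("Tidal Saline", "EMU", "Coastal Plains", "Interior Plains", "West")

_REGION_PREFIX = {
    "ALL": "Tidal Saline",
    "EMU": "EMU",
    "CPL": "Coastal Plains",
    "IPL": "Interior Plains",
    "W": "West",
}

#: Region implied by each reporting group (ALL-* groups are tidal saline).
REGION_BY_GROUP = {g: _REGION_PREFIX[g.split("-")[0]] for g in REPORTING_GROUPS}

#: The seven NWCA Wetland Types.
WETLAND_TYPES = (
    "EH", "EW", "PRL-EM", "PRL-SS", "PRL-FO", "PRL-f", "PRL-UBAB",
)

#: The ten disturbance measures used for condition screening: five
#: proximity-weighted buffer stressor counts, their summary, two in-site
#: hydrologic stressor counts, a soil heavy-metal exceedance count and the
#: relative cover of alien plants.
DISTURBANCE_MEASURES = (
    "agriculture",
    "residential_urban",
    "hydrologic_buffer",
    "industrial",
    "habitat_modification",
    "buffer_summary",
    "hydro_high_impact",
    "hydro_moderate_impact",
    "soil_heavy_metal",
    "alien_plant_cover",
)

BD_SOURCES = ("measured", "modelled", "imputed_adjacent")


class SchemaError(ValueError):
    """An input table is missing or misnaming a required column."""


class ValidationError(ValueError):
    """A record violates a field-level invariant."""


class ProfileError(ValueError):
    """A site's horizon stack is not contiguous / non-overlapping."""


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass
class SoilHorizon:
    """One field-described soil layer.

    Depths are cm below the soil surface with half-open extent
    ``[top_depth_cm, bottom_depth_cm)``.  ``soc_pct`` is soil organic
    carbon as a percent of fine-earth mass (total minus inorganic carbon,
    clipped at zero).  ``thin_flag`` marks layers under 8 cm thick that
    were described but not sampled for laboratory analysis.
    """

    site_id: str
    horizon_order: int
    top_depth_cm: float
    bottom_depth_cm: float
    organic_flag: bool = False
    total_c_pct: float | None = None
    inorg_c_pct: float | None = None
    soc_pct: float | None = None
    bd_g_cm3: float | None = None
    bd_source: str = "measured"
    ec: float | None = None
    cec: float | None = None
    sand_pct: float | None = None
    silt_pct: float | None = None
    clay_pct: float | None = None
    thin_flag: bool = False

    @property
    def thickness_cm(self) -> float:
        return self.bottom_depth_cm - self.top_depth_cm

    @property
    def mid_depth_cm(self) -> float:
        return 0.5 * (self.top_depth_cm + self.bottom_depth_cm)

    def validate(self) -> None:
        if self.horizon_order < 1:
            raise ValidationError(
                f"{self.site_id}: horizon_order must be >=1, got {self.horizon_order}")
        if not self.bottom_depth_cm > self.top_depth_cm:
            raise ValidationError(
                f"{self.site_id}: bottom depth {self.bottom_depth_cm} must exceed "
                f"top depth {self.top_depth_cm}")
        if self.top_depth_cm < 0:
            raise ValidationError(f"{self.site_id}: negative top depth")
        for name in ("total_c_pct", "inorg_c_pct", "soc_pct",
                     "sand_pct", "silt_pct", "clay_pct"):
            v = getattr(self, name)
            if not _is_missing(v) and not (0.0 <= v <= 100.0):
                raise ValidationError(
                    f"{self.site_id}: {name}={v} outside [0, 100]")
        if not _is_missing(self.bd_g_cm3) and self.bd_g_cm3 <= 0:
            raise ValidationError(
                f"{self.site_id}: bulk density must be positive, got {self.bd_g_cm3}")
        if self.bd_source not in BD_SOURCES:
            raise ValidationError(
                f"{self.site_id}: unknown bd_source {self.bd_source!r}")
        for name in ("ec", "cec"):
            v = getattr(self, name)
            if not _is_missing(v) and v < 0:
                raise ValidationError(f"{self.site_id}: {name} must be >=0")
        tex = [self.sand_pct, self.silt_pct, self.clay_pct]
        if not any(_is_missing(v) for v in tex) and sum(tex) > 100.0 + 1e-6:
            raise ValidationError(
                f"{self.site_id}: sand+silt+clay = {sum(tex):.3f} exceeds 100")


@dataclass
class SiteRecord:
    """One wetland survey point with its design weight and labels.

    ``weight_ha`` is the area the site represents: the inverse of its
    inclusion probability expressed in hectares.  Non-probability
    (hand-picked) sites carry no weight and never enter population
    estimates, but do enter disturbance-threshold calibration.
    """

    site_id: str
    reporting_group: str
    region: str
    wetland_type: str
    hgm_class: str
    tidal_saline: bool
    weight_ha: float
    disturbance_indices: dict[str, float] = field(default_factory=dict)
    probability_site: bool = True

    def validate(self) -> None:
        if self.reporting_group not in REPORTING_GROUPS:
            raise ValidationError(
                f"{self.site_id}: unknown reporting group {self.reporting_group!r}")
        expected_region = REGION_BY_GROUP[self.reporting_group]
        if self.region != expected_region:
            raise ValidationError(
                f"{self.site_id}: region {self.region!r} inconsistent with "
                f"reporting group {self.reporting_group} (expected {expected_region!r})")
        if self.tidal_saline != self.reporting_group.startswith("ALL-"):
            raise ValidationError(
                f"{self.site_id}: tidal_saline flag inconsistent with "
                f"reporting group {self.reporting_group}")
        if self.wetland_type not in WETLAND_TYPES:
            raise ValidationError(
                f"{self.site_id}: unknown wetland type {self.wetland_type!r}")
        if self.probability_site and not self.weight_ha > 0:
            raise ValidationError(
                f"{self.site_id}: probability site must have weight_ha > 0, "
                f"got {self.weight_ha}")
        for k, v in self.disturbance_indices.items():
            if k not in DISTURBANCE_MEASURES:
                raise ValidationError(
                    f"{self.site_id}: unknown disturbance measure {k!r}")
            if not _is_missing(v) and v < 0:
                raise ValidationError(
                    f"{self.site_id}: disturbance index {k} must be >=0, got {v}")


@dataclass
class PopulationEstimate:
    """A design-based estimate for one subpopulation and depth range.

    ``mean_tC_ha`` is the area-weighted mean carbon density, ``total_PgC``
    the estimated stock; both come with standard errors except after
    scaling to a target population (scaled standard errors are not
    defined and are reported as NaN).
    """

    subpopulation: str
    depth_lo_cm: float
    depth_hi_cm: float
    mean_tC_ha: float
    se_mean: float
    total_PgC: float
    se_total: float
    n_sites: int
    area_Mha: float

    def validate(self) -> None:
        if self.n_sites == 0:
            return
        if self.depth_hi_cm <= self.depth_lo_cm:
            raise ValidationError(
                f"{self.subpopulation}: empty depth range "
                f"[{self.depth_lo_cm}, {self.depth_hi_cm})")
        # identity: PgC = (tC/ha) x (Mha -> ha) x (t -> g) / (g -> Pg)
        implied = self.mean_tC_ha * self.area_Mha * 1e6 * 1e6 / 1e15
        if self.total_PgC > 0 and abs(implied - self.total_PgC) > 1e-9 * max(
                1.0, abs(self.total_PgC)):
            raise ValidationError(
                f"{self.subpopulation}: total {self.total_PgC} PgC inconsistent "
                f"with mean x area ({implied} PgC)")


def horizon_fields() -> list[str]:
    return [f.name for f in fields(SoilHorizon)]
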