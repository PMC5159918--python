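"""Profile-level quality control: carbon imputation and bulk-density screening.

Roughly a quarter of described horizons are too thin (<8 cm) to sample,
and around 30% of bulk-density measurements fail or are missing in the
field, so accounting cannot proceed without filling rules.  The rules
implemented here are deliberately simple and auditable:

* top horizon missing SOC: copy the concentration of the next lower
  horizon with data (conservative when an organic cap overlies mineral
  soil);
* interior horizon missing SOC: arithmetic mean of the nearest horizons
  with data immediately above and below;
* bottom horizon missing SOC: copy from the nearest horizon above
  (mirrors the top rule; configurable off);
* measured bulk density above 2.0 g cm^-3 (the physical ceiling of
  measurable bulk density) is treated as erroneous and replaced by the
  modelled value;
* measured bulk density differing from the modelled value by more than
  40% (of the modelled value) is replaced by the modelled value;
* missing bulk density is filled with the modelled value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .model import SoilHorizon

log = logging.getLogger(__name__)

__all__ = ["QCReport", "SiteQCCounts", "UnusableSiteError",
           "impute_missing_carbon", "screen_bulk_density",
           "BD_UPPER_LIMIT", "BD_DISCREPANCY_FRACTION"]

#: Upper limit of measurable bulk density, g cm^-3.
BD_UPPER_LIMIT = 2.0

#: Relative discrepancy (vs the modelled value) beyond which a measured
#: bulk density is replaced by the modelled one.
BD_DISCREPANCY_FRACTION = 0.40


class UnusableSiteError(ValueError):
    """Every horizon of the site is missing SOC; it cannot be accounted."""


@dataclass
class SiteQCCounts:
    """Per-site tally of QC dispositions."""

    site_id: str = ""
    soc_imputed_top: int = 0
    soc_imputed_middle: int = 0
    soc_imputed_bottom: int = 0
    bd_over_limit: int = 0
    bd_replaced_40pct: int = 0
    bd_modelled_missing: int = 0

    def as_dict(self) -> dict:
        return dict(vars(self))


@dataclass
class QCReport:
    """Aggregated QC dispositions across sites."""

    sites: dict[str, SiteQCCounts] = field(default_factory=dict)
    unusable_sites: list[str] = field(default_factory=list)

    def counts_for(self, site_id: str) -> SiteQCCounts:
        if site_id not in self.sites:
            self.sites[site_id] = SiteQCCounts(site_id=site_id)
        return self.sites[site_id]

    def totals(self) -> dict:
        tot = SiteQCCounts(site_id="ALL")
        for c in self.sites.values():
            tot.soc_imputed_top += c.soc_imputed_top
            tot.soc_imputed_middle += c.soc_imputed_middle
            tot.soc_imputed_bottom += c.soc_imputed_bottom
            tot.bd_over_limit += c.bd_over_limit
            tot.bd_replaced_40pct += c.bd_replaced_40pct
            tot.bd_modelled_missing += c.bd_modelled_missing
        d = tot.as_dict()
        d["n_unusable_sites"] = len(self.unusable_sites)
        return d


def _missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def impute_missing_carbon(profile: list[SoilHorizon],
                          report: QCReport | None = None,
                          fill_bottom: bool = True) -> list[SoilHorizon]:
    """Fill missing SOC concentrations from vertically adjacent horizons.

    The profile must be sorted and contiguous.  Non-missing values are
    never altered, and the operation is idempotent.  Runs of consecutive
    missing horizons share the same nearest-neighbour donors.  Raises
    :class:`UnusableSiteError` if no horizon has SOC.
    """
    socs = [h.soc_pct for h in profile]
    known = [i for i, v in enumerate(socs) if not _missing(v)]
    if not profile:
        return profile
    counts = report.counts_for(profile[0].site_id) if report is not None else None
    if not known:
        if report is not None:
            report.unusable_sites.append(profile[0].site_id)
        raise UnusableSiteError(
            f"{profile[0].site_id}: no horizon has SOC data")
    for i, h in enumerate(profile):
        if not _missing(h.soc_pct):
            continue
        above = max((j for j in known if j < i), default=None)
        below = min((j for j in known if j > i), default=None)
        if above is None:
            # surface horizon(s): equate to the next lower horizon with data
            h.soc_pct = socs[below]
            if counts:
                counts.soc_imputed_top += 1
        elif below is None:
            if not fill_bottom:
                continue
            h.soc_pct = socs[above]
            if counts:
                counts.soc_imputed_bottom += 1
        else:
            h.soc_pct = 0.5 * (socs[above] + socs[below])
            if counts:
                counts.soc_imputed_middle += 1
        log.debug("%s horizon %d: SOC imputed to %.3f%%",
                  h.site_id, h.horizon_order, h.soc_pct)
    return profile


def screen_bulk_density(profile: list[SoilHorizon],
                        modelled: dict[int, float],
                        report: QCReport | None = None,
                        discrepancy_fraction: float = BD_DISCREPANCY_FRACTION,
                        ) -> list[SoilHorizon]:
    """Replace implausible or missing bulk densities with modelled values.

    ``modelled`` maps horizon_order to the model prediction; a prediction
    is required for every horizon the rules touch, and its absence is an
    error listing the offending horizons.  Idempotent: a horizon already
    carrying a modelled value within tolerance is left alone.
    """
    counts = (report.counts_for(profile[0].site_id)
              if report is not None and profile else None)
    needed = []
    for h in profile:
        needs_model = (_missing(h.bd_g_cm3)
                       or h.bd_g_cm3 > BD_UPPER_LIMIT
                       or (h.horizon_order in modelled
                           and h.bd_source == "measured"
                           and abs(h.bd_g_cm3 - modelled[h.horizon_order])
                           / modelled[h.horizon_order] > discrepancy_fraction))
        if needs_model and h.horizon_order not in modelled:
            needed.append(h.horizon_order)
    if needed:
        raise ValueError(
            f"{profile[0].site_id}: modelled bulk density required but absent "
            f"for horizon(s) {needed}")
    for h in profile:
        m = modelled.get(h.horizon_order)
        if _missing(h.bd_g_cm3):
            h.bd_g_cm3 = m
            h.bd_source = "modelled"
            if counts:
                counts.bd_modelled_missing += 1
        elif h.bd_g_cm3 > BD_UPPER_LIMIT:
            log.info("%s horizon %d: measured bd %.2f > %.1f g cm^-3, replaced "
                     "with modelled %.2f", h.site_id, h.horizon_order,
                     h.bd_g_cm3, BD_UPPER_LIMIT, m)
            h.bd_g_cm3 = m
            h.bd_source = "modelled"
            if counts:
                counts.bd_over_limit += 1
        elif (h.bd_source == "measured" and m is not None
              and abs(h.bd_g_cm3 - m) / m > discrepancy_fraction):
            log.info("%s horizon %d: measured bd %.2f differs from modelled "
                     "%.2f by >%.0f%%, replaced", h.site_id, h.horizon_order,
                     h.bd_g_cm3, m, 100 * discrepancy_fraction)
            h.bd_g_cm3 = m
            h.bd_source = "modelled"
            if counts:
                counts.bd_replaced_40pct += 1
    return profile
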