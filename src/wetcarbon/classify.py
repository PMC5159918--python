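"""Organic vs mineral soil classification and blue/teal carbon typing.

A wetland is organic-soil dominated (histosol-like) if any of the three
field-rule criteria holds:

(a) every horizon from the surface down to at least 40 cm was described
    as organic (peat, muck, mucky peat);
(b) at least 40 cm of the top 80 cm is organic; or
(c) an impenetrable layer lies within the top 40 cm, two-thirds or more
    of the described soil thickness is organic, and total mineral
    thickness is under 10 cm.

Otherwise it is mineral-soil dominated.  Tidal saline sites hold "blue"
carbon; freshwater inland sites hold "teal" carbon.
"""

from __future__ import annotations

from .model import SiteRecord, SoilHorizon

__all__ = ["classify_soil", "carbon_type", "ClassificationError"]


class ClassificationError(ValueError):
    """A profile cannot be classified (e.g. missing organic flags)."""


def _organic_thickness(profile: list[SoilHorizon], lo: float, hi: float,
                       organic: bool) -> float:
    """Total thickness of (non-)organic material within [lo, hi) cm."""
    t = 0.0
    for h in profile:
        if h.organic_flag == organic:
            t += max(0.0, min(h.bottom_depth_cm, hi) - max(h.top_depth_cm, lo))
    return t


def classify_soil(profile: list[SoilHorizon],
                  impenetrable_depth_cm: float | None = None) -> str:
    """Classify a described profile as ``"organic"`` or ``"mineral"``.

    ``impenetrable_depth_cm`` is the depth at which digging stopped on an
    impenetrable layer, if one was recorded; it gates rule (c).
    Horizon ``organic_flag`` must be set for every horizon.
    """
    if not profile:
        raise ClassificationError("empty profile")
    for h in profile:
        if h.organic_flag is None:
            raise ClassificationError(
                f"{h.site_id}: horizon {h.horizon_order} missing organic flag")
    bottom = max(h.bottom_depth_cm for h in profile)

    # (a) organic from the surface through at least 40 cm: no mineral
    # material above 40 cm and the profile is described that deep.
    if bottom >= 40.0 and _organic_thickness(profile, 0.0, 40.0, organic=False) == 0.0:
        return "organic"

    # (b) >=40 cm of organic material within the top 80 cm.
    if _organic_thickness(profile, 0.0, 80.0, organic=True) >= 40.0:
        return "organic"

    # (c) shallow impenetrable layer: mostly-organic thin profile.
    if impenetrable_depth_cm is not None and impenetrable_depth_cm < 40.0:
        total = bottom - min(h.top_depth_cm for h in profile)
        org = _organic_thickness(profile, 0.0, bottom, organic=True)
        mineral = total - org
        if total > 0 and org >= (2.0 / 3.0) * total and mineral < 10.0:
            return "organic"

    return "mineral"


def carbon_type(site: SiteRecord) -> str:
    """``"blue"`` for tidal saline sites, ``"teal"`` for freshwater inland."""
    return "blue" if site.tidal_saline else "teal"
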