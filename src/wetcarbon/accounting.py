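"""Per-horizon carbon density and 1-cm depth slicing.

Carbon density of a soil layer is

    rho_c = A * d_l * rho_d * C

with ``rho_c`` in g m^-2, ``A`` = 10,000 cm^2 m^-2, ``d_l`` the layer
thickness in cm, ``rho_d`` the bulk density in g cm^-3 and ``C`` the SOC
concentration as a mass fraction.  Because horizon depths differ between
profiles, each profile is resolved onto 1-cm increments down to 120 cm so
stocks can be aggregated over any depth range; increments below the
deepest described (and QC-complete) horizon are marked unavailable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import SoilHorizon

__all__ = [
    "MAX_DEPTH_CM",
    "AREA_CM2_PER_M2",
    "G_M2_PER_TC_HA",
    "SlicedProfile",
    "horizon_carbon_density",
    "slice_profile",
    "depth_range_density",
]

#: Reporting depth limit, cm below the surface.
MAX_DEPTH_CM = 120

#: cm^2 in one m^2 (the A term of the density equation).
AREA_CM2_PER_M2 = 10_000.0

#: 1 tC ha^-1 expressed in g m^-2 (1 t = 1e6 g over 1e4 m^2).
G_M2_PER_TC_HA = 100.0


def horizon_carbon_density(d_l_cm: float, bd_g_cm3: float, soc_pct: float) -> float:
    """Carbon density of one layer in g m^-2.

    Parameters are the layer thickness in cm, its bulk density in
    g cm^-3 and its SOC concentration in percent.
    """
    if d_l_cm <= 0:
        raise ValueError(f"layer thickness must be positive, got {d_l_cm}")
    if bd_g_cm3 <= 0:
        raise ValueError(f"bulk density must be positive, got {bd_g_cm3}")
    if not (0.0 <= soc_pct <= 100.0):
        raise ValueError(f"SOC percent outside [0, 100]: {soc_pct}")
    return AREA_CM2_PER_M2 * d_l_cm * bd_g_cm3 * (soc_pct / 100.0)


@dataclass
class SlicedProfile:
    """Per-site carbon density resolved to 1-cm increments.

    ``density_g_m2_per_cm[i]`` is the carbon density of the increment
    [i, i+1) cm; ``available[i]`` says whether that increment lies inside
    a horizon with complete (measured or modelled) bulk density and SOC.
    """

    site_id: str
    density_g_m2_per_cm: np.ndarray = field(
        default_factory=lambda: np.zeros(MAX_DEPTH_CM))
    available: np.ndarray = field(
        default_factory=lambda: np.zeros(MAX_DEPTH_CM, dtype=bool))

    def described_bottom_cm(self) -> int:
        """Deepest contiguous available increment boundary from the surface."""
        run = 0
        for ok in self.available:
            if not ok:
                break
            run += 1
        return run


def _horizon_complete(h: SoilHorizon) -> bool:
    return (h.soc_pct is not None and not (isinstance(h.soc_pct, float) and
                                           math.isnan(h.soc_pct))
            and h.bd_g_cm3 is not None
            and not (isinstance(h.bd_g_cm3, float) and math.isnan(h.bd_g_cm3))
            and 0.0 < h.bd_g_cm3 <= 2.0)


def slice_profile(profile: list[SoilHorizon],
                  max_depth_cm: int = MAX_DEPTH_CM) -> SlicedProfile:
    """Resolve a QC-complete profile onto 1-cm increments.

    Horizons are assumed internally homogeneous.  Non-integer horizon
    boundaries are handled by thickness-weighting the overlapping
    horizons within each 1-cm slice, so per-horizon totals are conserved
    exactly.  A slice is available only if every part of it is covered by
    a horizon with usable bulk density and SOC.
    """
    density = np.zeros(max_depth_cm)
    covered = np.zeros(max_depth_cm)  # cm of usable coverage per slice
    site_id = profile[0].site_id if profile else ""
    for h in profile:
        if not _horizon_complete(h):
            continue
        per_cm = horizon_carbon_density(1.0, h.bd_g_cm3, h.soc_pct)
        lo, hi = h.top_depth_cm, min(h.bottom_depth_cm, float(max_depth_cm))
        if hi <= lo:
            continue
        first, last = int(math.floor(lo)), int(math.ceil(hi))
        for i in range(first, min(last, max_depth_cm)):
            overlap = min(hi, i + 1.0) - max(lo, float(i))
            if overlap > 0:
                density[i] += per_cm * overlap
                covered[i] += overlap
    available = covered > 1.0 - 1e-9
    density[~available] = 0.0
    return SlicedProfile(site_id=site_id, density_g_m2_per_cm=density,
                         available=available)


def depth_range_density(sliced: SlicedProfile, lo_cm: int, hi_cm: int,
                        prorate: bool = False) -> float | None:
    """Carbon density over [lo_cm, hi_cm) in tC ha^-1, or None.

    By default the site contributes only if every 1-cm increment in the
    range is available (incomplete profiles drop out of deeper ranges,
    so the contributing n shrinks with depth).  With ``prorate=True`` the
    mean density of available increments is extrapolated over the range
    instead — a downward-bias-prone convenience, off by default.
    """
    if not (0 <= lo_cm < hi_cm <= len(sliced.density_g_m2_per_cm)):
        raise ValueError(f"malformed depth range [{lo_cm}, {hi_cm})")
    mask = sliced.available[lo_cm:hi_cm]
    dens = sliced.density_g_m2_per_cm[lo_cm:hi_cm]
    if mask.all():
        return float(dens.sum() / G_M2_PER_TC_HA)
    if prorate and mask.any():
        return float(dens[mask].mean() * (hi_cm - lo_cm) / G_M2_PER_TC_HA)
    return None
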