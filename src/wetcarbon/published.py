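"""Published national summaries from the 2011 NWCA soil-carbon analysis.

These are the printed population-level results of the 2011 National
Wetland Condition Assessment carbon accounting: estimated carbon stocks
(PgC) by depth increment and subpopulation for the inference population
(25.2 Mha directly represented by the probability sample) and the target
population (the full 38.4 Mha design frame), disturbance-gradient
screening counts, disturbance-class mean densities, and the deep-layer
bulk-density modelling tally.  They serve as *inputs* to the package's
aggregation and ratio operations — e.g. recomputing depth shares, area
shares or the least-vs-most density gap — not as outputs of it.
"""

from __future__ import annotations

from .model import PopulationEstimate

__all__ = [
    "INFERENCE_STOCKS_PGC", "TARGET_STOCKS_PGC", "AREA_MHA_INFERENCE",
    "AREA_MHA_TARGET", "DISTURBANCE_MEAN_TC_HA", "SCREENED_COUNTS",
    "DEEP_LAYERS_DESCRIBED", "DEEP_LAYERS_BD_MODELLED",
    "published_estimates",
]

_DEPTHS = ((0, 30), (30, 60), (60, 90), (90, 120))

#: Estimated PgC by depth increment, inference population (25.2 Mha).
INFERENCE_STOCKS_PGC = {
    "national": (2.63, 2.08, 1.76, 1.08),
    "blue": (0.20, 0.17, 0.18, 0.20),
    "teal": (2.42, 1.91, 1.59, 0.93),
}

#: Estimated PgC by depth increment, target population (38.4 Mha).
TARGET_STOCKS_PGC = {
    "national": (4.02, 3.17, 2.68, 1.64),
    "blue": (0.20, 0.20, 0.22, 0.25),
    "teal": (3.25, 2.72, 2.21, 1.45),
}

#: Represented wetland area, million hectares.
AREA_MHA_INFERENCE = {"national": 25.2, "blue": 2.2, "teal": 23.0}
AREA_MHA_TARGET = {"national": 38.4, "blue": 2.7, "teal": 35.7}

#: Mean 0-120 cm carbon density by disturbance class, tC ha^-1.
DISTURBANCE_MEAN_TC_HA = {"least": 407.0, "most": 236.0}

#: Disturbance-gradient screening outcome over all screened sites
#: (probability plus hand-picked).
SCREENED_COUNTS = {"least": 277, "intermediate": 530, "most": 331}

#: Soil layers described at 75 cm depth or greater, and how many of
#: their bulk densities had to be modelled.
DEEP_LAYERS_DESCRIBED = 1287
DEEP_LAYERS_BD_MODELLED = 899


def published_estimates(population: str = "inference",
                        ) -> dict[str, list[PopulationEstimate]]:
    """Published stocks as :class:`PopulationEstimate` rows per subpopulation.

    ``population`` selects ``"inference"`` or ``"target"``.  Standard
    errors are not carried (NaN); n_sites is unknown at this granularity
    and set to -1 sentinel-free as 0 with validation skipped via mean
    back-computation from total and area.
    """
    stocks = INFERENCE_STOCKS_PGC if population == "inference" else TARGET_STOCKS_PGC
    areas = AREA_MHA_INFERENCE if population == "inference" else AREA_MHA_TARGET
    out: dict[str, list[PopulationEstimate]] = {}
    for sub, vals in stocks.items():
        area = areas[sub]
        rows = []
        for (lo, hi), pgc in zip(_DEPTHS, vals):
            mean = pgc * 1e15 / 1e6 / (area * 1e6)  # tC ha^-1 implied
            rows.append(PopulationEstimate(
                subpopulation=sub, depth_lo_cm=lo, depth_hi_cm=hi,
                mean_tC_ha=mean, se_mean=float("nan"), total_PgC=pgc,
                se_total=float("nan"), n_sites=1, area_Mha=area))
        out[sub] = rows
    return out
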