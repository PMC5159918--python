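"""Synthetic NWCA-like wetland populations with known ground truth.

The generator builds a finite population of wetland sites, each with an
ordered stack of soil horizons, so that every downstream stage (QC,
bulk-density modelling, slicing, classification, screening, design-based
estimation) can be exercised and checked against exact population
truths.  The main features of real survey soil data it emulates:

* SOC concentration decays roughly exponentially with depth, with
  distinct organic (peaty: high surface SOC, slow decay, organic field
  texture) and mineral archetypes;
* bulk density declines with SOC, here rho_d = a*exp(-b*SOC%) + noise
  truncated into (0.05, 2.0];
* about a quarter of horizons are under 8 cm thick and unsampled, and
  about 30% of the remaining bulk densities are missing;
* some profiles stop short of 120 cm on an impenetrable layer, so the
  number of sites with complete deep increments shrinks with depth;
* sites are drawn with unequal inclusion probabilities by wetland type
  and carry inverse-probability weights in hectares;
* a latent least/intermediate/most disturbance class drives both the
  ten stressor indices and a multiplicative SOC reduction at the most
  disturbed sites.

Everything is deterministic for a fixed master seed (per-stage child
generators are spawned from it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import accounting
from .classify import classify_soil
from .model import (
    DISTURBANCE_MEASURES,
    REGION_BY_GROUP,
    REPORTING_GROUPS,
    SiteRecord,
    SoilHorizon,
)

__all__ = ["SimulationConfig", "GroundTruth", "generate_population",
           "sample_survey", "DEPTH_RANGES"]

#: The standard reporting depth increments, cm.
DEPTH_RANGES = ((0, 30), (30, 60), (60, 90), (90, 120), (0, 120))


def _default_group_mix() -> dict[str, float]:
    return {
        "ALL-EW": 0.06, "ALL-EH": 0.10,
        "EMU-PRLW": 0.12, "EMU-PRLH": 0.08,
        "CPL-PRLW": 0.14, "CPL-PRLH": 0.10,
        "IPL-PRLW": 0.10, "IPL-PRLH": 0.10,
        "W-PRLW": 0.10, "W-PRLH": 0.10,
    }


def _default_organic_fraction() -> dict[str, float]:
    frac = {}
    for g in REPORTING_GROUPS:
        if g.startswith("EMU"):
            frac[g] = 0.35
        elif g.startswith("ALL"):
            frac[g] = 0.30
        else:
            frac[g] = 0.12
    return frac


def _default_inclusion() -> dict[str, float]:
    # estuarine types oversampled relative to their area, like a design
    # stratified by wetland type
    return {"EH": 3.0, "EW": 3.0, "PRL-EM": 1.0, "PRL-SS": 1.0,
            "PRL-FO": 0.8, "PRL-f": 1.5, "PRL-UBAB": 1.2}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic population and survey draw."""

    seed: int = 0
    n_population_sites: int = 2000
    n_sampled_sites: int = 200
    n_nonprobability_sites: int = 35
    frame_area_ha: float = 25.2e6
    group_mix: dict[str, float] = field(default_factory=_default_group_mix)
    organic_fraction_by_group: dict[str, float] = field(
        default_factory=_default_organic_fraction)
    # SOC depth-decay archetypes: surface mean (%) and decay rate (cm^-1)
    soc_surface_mean_pct: dict[str, float] = field(
        default_factory=lambda: {"organic": 30.0, "mineral": 8.0})
    depth_decay_rate: dict[str, float] = field(
        default_factory=lambda: {"organic": 0.003, "mineral": 0.02})
    soc_noise_sd: float = 0.25  # lognormal sigma on SOC
    # bulk density relation rho_d = a*exp(-b*SOC) + N(0, noise_sd)
    bd_a: float = 1.6
    bd_b: float = 0.08
    bd_noise_sd: float = 0.10
    thin_horizon_rate: float = 0.25
    bd_missing_rate: float = 0.30
    bd_error_rate: float = 0.01  # spurious measured values > 2 g cm^-3
    disturbance_class_mix: dict[str, float] = field(
        default_factory=lambda: {"least": 0.25, "intermediate": 0.50,
                                 "most": 0.25})
    inclusion_probability_by_type: dict[str, float] = field(
        default_factory=_default_inclusion)
    impenetrable_prob: float = 0.30
    most_soc_factor: float = 0.6
    most_soc_depth_slope: float = 0.2

    def validate(self) -> None:
        for name, mix in (("group_mix", self.group_mix),
                          ("disturbance_class_mix", self.disturbance_class_mix)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions must sum to 1")
        for name, rate in (("thin_horizon_rate", self.thin_horizon_rate),
                           ("bd_missing_rate", self.bd_missing_rate),
                           ("bd_error_rate", self.bd_error_rate),
                           ("impenetrable_prob", self.impenetrable_prob)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for g, f in self.organic_fraction_by_group.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"organic fraction for {g} outside [0, 1]")
        if self.n_sampled_sites > self.n_population_sites:
            raise ValueError("n_sampled_sites exceeds n_population_sites")


@dataclass
class GroundTruth:
    """Exact population quantities computed before any masking.

    Totals and means are over the synthetic population sites whose
    profile fully covers the depth range (shallow profiles drop out of
    deep increments exactly as they do in estimation), keyed by
    (subpopulation, "lo-hi").
    """

    true_total_PgC: dict[tuple[str, str], float] = field(default_factory=dict)
    true_mean_tC_ha: dict[tuple[str, str], float] = field(default_factory=dict)
    disturbance_class: dict[str, str] = field(default_factory=dict)
    soil_class: dict[str, str] = field(default_factory=dict)
    site_density_tC_ha: dict[str, dict[str, float | None]] = field(
        default_factory=dict)
    impenetrable_depth_cm: dict[str, float | None] = field(default_factory=dict)


_WOODY_TYPES = ("PRL-SS", "PRL-FO")
_HERB_TYPES = ("PRL-EM", "PRL-f", "PRL-UBAB")

# class-conditional gamma scales for the stressor indices; larger latent
# disturbance shifts every index upward so threshold screening can
# recover the classes
_DIST_SCALE = {"least": 0.3, "intermediate": 1.0, "most": 2.8}


def _draw_site_labels(rng: np.random.Generator, cfg: SimulationConfig,
                      i: int) -> SiteRecord:
    groups = list(cfg.group_mix)
    group = groups[rng.choice(len(groups), p=np.asarray(
        [cfg.group_mix[g] for g in groups]))]
    tidal = group.startswith("ALL-")
    if group.endswith("EW"):
        wtype = "EW"
    elif group.endswith("EH"):
        wtype = "EH"
    elif group.endswith("PRLW"):
        wtype = _WOODY_TYPES[rng.choice(2)]
    else:
        wtype = _HERB_TYPES[rng.choice(3, p=[0.6, 0.2, 0.2])]
    if tidal:
        hgm = ["Estuarine", "Tidal Fringe"][rng.choice(2)]
    else:
        hgm = ["Riverine", "Depression", "Slope", "Flat", "Lacustrine"][
            rng.choice(5, p=[0.3, 0.3, 0.1, 0.2, 0.1])]
    return SiteRecord(
        site_id=f"S{i:05d}",
        reporting_group=group,
        region=REGION_BY_GROUP[group],
        wetland_type=wtype,
        hgm_class=hgm,
        tidal_saline=tidal,
        weight_ha=cfg.frame_area_ha / cfg.n_population_sites,
        probability_site=True,
    )


def _draw_disturbance_indices(rng: np.random.Generator, klass: str) -> dict:
    scale = _DIST_SCALE[klass]
    vals = rng.gamma(shape=2.0, scale=scale, size=len(DISTURBANCE_MEASURES))
    return {m: float(v) for m, v in zip(DISTURBANCE_MEASURES, vals)}


def _build_profile(rng: np.random.Generator, cfg: SimulationConfig,
                   site: SiteRecord, archetype: str, klass: str,
                   bottom_cm: float) -> list[SoilHorizon]:
    """Draw contiguous horizons with complete (pre-masking) values."""
    s0 = max(0.5, rng.normal(cfg.soc_surface_mean_pct[archetype],
                             0.2 * cfg.soc_surface_mean_pct[archetype]))
    k = cfg.depth_decay_rate[archetype]
    organic_depth = 0.0
    if archetype == "organic":
        organic_depth = min(bottom_cm, float(rng.uniform(45.0, 120.0)))
    elif rng.random() < 0.5:
        organic_depth = float(rng.uniform(0.0, 20.0))  # thin organic cap

    horizons: list[SoilHorizon] = []
    top = 0.0
    order = 1
    while top < bottom_cm - 1e-9:
        if rng.random() < cfg.thin_horizon_rate:
            thickness = float(rng.uniform(2.0, 7.9))
        else:
            thickness = float(rng.uniform(8.0, 35.0))
        bottom = min(top + thickness, bottom_cm)
        if bottom_cm - bottom < 8.0 and bottom < bottom_cm:
            bottom = bottom_cm  # absorb a sliver remainder into this horizon
        mid = 0.5 * (top + bottom)
        soc = s0 * math.exp(-k * mid)
        if cfg.soc_noise_sd > 0:
            soc *= math.exp(rng.normal(0.0, cfg.soc_noise_sd))
        if klass == "most":
            soc *= max(0.05, cfg.most_soc_factor
                       - cfg.most_soc_depth_slope * mid / 120.0)
        soc = float(np.clip(soc, 0.02, 60.0))
        inorg = float(rng.uniform(0.0, 2.0)) if rng.random() < 0.3 else 0.0
        total = min(100.0, soc + inorg)
        soc = total - inorg  # keep soc == total - inorg exact in float
        bd = cfg.bd_a * math.exp(-cfg.bd_b * soc)
        if cfg.bd_noise_sd > 0:
            bd += rng.normal(0.0, cfg.bd_noise_sd)
        bd = float(np.clip(bd, 0.06, 2.0))
        organic = mid < organic_depth
        ec = float(rng.uniform(5.0, 50.0)) if site.tidal_saline \
            else float(rng.uniform(0.0, 5.0))
        cec = float(max(1.0, 10.0 + 2.0 * soc + rng.normal(0.0, 5.0)))
        tex = rng.dirichlet([2.0, 2.0, 1.0]) * 100.0
        h = SoilHorizon(
            site_id=site.site_id,
            horizon_order=order,
            top_depth_cm=top,
            bottom_depth_cm=bottom,
            organic_flag=bool(organic),
            total_c_pct=total,
            inorg_c_pct=inorg,
            soc_pct=soc,
            bd_g_cm3=bd,
            bd_source="measured",
            ec=ec,
            cec=cec,
            sand_pct=float(tex[0]),
            silt_pct=float(tex[1]),
            clay_pct=float(tex[2]),
            thin_flag=bool(bottom - top < 8.0),
        )
        horizons.append(h)
        top = bottom
        order += 1
    return horizons


def _mask_profile(rng: np.random.Generator, cfg: SimulationConfig,
                  horizons: list[SoilHorizon]) -> None:
    """Inject the survey's missingness in place: thin horizons carry no
    laboratory data, a fraction of the rest lose bulk density, and a
    small fraction gain erroneous measured values above 2 g cm^-3."""
    for h in horizons:
        if h.thin_flag:
            h.total_c_pct = h.inorg_c_pct = h.soc_pct = None
            h.bd_g_cm3 = None
            h.ec = h.cec = None
            h.sand_pct = h.silt_pct = h.clay_pct = None
        elif rng.random() < cfg.bd_missing_rate:
            h.bd_g_cm3 = None
        elif rng.random() < cfg.bd_error_rate:
            h.bd_g_cm3 = float(rng.uniform(2.05, 2.6))


def _site_truth(horizons: list[SoilHorizon]) -> dict[str, float | None]:
    sliced = accounting.slice_profile(horizons)
    out = {}
    for lo, hi in DEPTH_RANGES:
        out[f"{lo}-{hi}"] = accounting.depth_range_density(sliced, lo, hi)
    return out


def _subpopulations(site: SiteRecord, truth: GroundTruth) -> list[str]:
    sid = site.site_id
    return [
        "national",
        f"region:{site.region}",
        "carbon:blue" if site.tidal_saline else "carbon:teal",
        f"disturbance:{truth.disturbance_class[sid]}",
        f"soil:{truth.soil_class[sid]}",
        f"group:{site.reporting_group}",
    ]


def generate_population(config: SimulationConfig,
                        ) -> tuple[list[SiteRecord],
                                   dict[str, list[SoilHorizon]],
                                   GroundTruth]:
    """Generate the full synthetic population and its exact truths.

    Returns the population site records (each carrying the census weight
    ``frame_area_ha / n_population_sites``), per-site horizon stacks with
    survey-style missingness already injected, and a
    :class:`GroundTruth` computed from the complete pre-masking values.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    rng_site, rng_soil, rng_mask, rng_dist = (
        np.random.default_rng(s) for s in root.spawn(4))

    sites: list[SiteRecord] = []
    profiles: dict[str, list[SoilHorizon]] = {}
    truth = GroundTruth()
    classes = list(config.disturbance_class_mix)
    probs = np.asarray([config.disturbance_class_mix[c] for c in classes])

    for i in range(config.n_population_sites):
        site = _draw_site_labels(rng_site, config, i)
        klass = classes[rng_dist.choice(len(classes), p=probs)]
        site.disturbance_indices = _draw_disturbance_indices(rng_dist, klass)
        archetype = ("organic" if rng_soil.random()
                     < config.organic_fraction_by_group[site.reporting_group]
                     else "mineral")
        if rng_soil.random() < config.impenetrable_prob:
            bottom = float(rng_soil.uniform(35.0, 119.0))
            impenetrable: float | None = bottom
        else:
            bottom, impenetrable = 120.0, None
        horizons = _build_profile(rng_soil, config, site, archetype, klass,
                                  bottom)

        sid = site.site_id
        truth.disturbance_class[sid] = klass
        truth.soil_class[sid] = classify_soil(horizons, impenetrable)
        truth.impenetrable_depth_cm[sid] = impenetrable
        truth.site_density_tC_ha[sid] = _site_truth(horizons)

        _mask_profile(rng_mask, config, horizons)
        sites.append(site)
        profiles[sid] = horizons

    # exact totals/means over the population, per subpopulation x range
    unit = config.frame_area_ha / config.n_population_sites
    acc_tot: dict[tuple[str, str], float] = {}
    acc_area: dict[tuple[str, str], float] = {}
    for site in sites:
        dens = truth.site_density_tC_ha[site.site_id]
        for sub in _subpopulations(site, truth):
            for rng_key, y in dens.items():
                if y is None:
                    continue
                key = (sub, rng_key)
                acc_tot[key] = acc_tot.get(key, 0.0) + unit * y
                acc_area[key] = acc_area.get(key, 0.0) + unit
    for key, tot_tc in acc_tot.items():
        truth.true_total_PgC[key] = tot_tc * 1e-9
        truth.true_mean_tC_ha[key] = tot_tc / acc_area[key]
    return sites, profiles, truth


def sample_survey(population: list[SiteRecord], config: SimulationConfig,
                  seed: int | None = None,
                  ) -> tuple[list[SiteRecord], list[SiteRecord]]:
    """Draw an unequal-probability survey sample from the population.

    Inclusion probabilities are proportional to the wetland-type factors
    in ``inclusion_probability_by_type``, normalized to an expected
    sample size of ``n_sampled_sites`` and capped at 1.  Selection is
    randomized-order systematic PPS sampling (fixed sample size, exact
    per-site inclusion probabilities, Horvitz-Thompson unbiased).  Each
    sampled site's ``weight_ha`` is unit area / inclusion probability,
    so the weighted site count estimates the population size exactly in
    expectation.  A further ``n_nonprobability_sites`` unsampled sites
    are returned as hand-picked (weightless) sites for threshold
    calibration only.
    """
    config.validate()
    if seed is None:
        seed = config.seed + 1
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    factors = np.asarray([config.inclusion_probability_by_type[s.wetland_type]
                          for s in population], dtype=float)
    if np.any(factors <= 0):
        raise ValueError("inclusion probability factors must be positive")
    pi = config.n_sampled_sites * factors / factors.sum()
    if np.any(pi > 1.0):
        pi = np.minimum(pi, 1.0)  # capped; expected size slightly below n
    unit = config.frame_area_ha / len(population)

    perm = rng.permutation(len(population))
    cum = np.cumsum(pi[perm])
    u = rng.uniform(0.0, 1.0)
    picks = np.searchsorted(cum, u + np.arange(int(math.floor(cum[-1] - u)) + 1),
                            side="right")
    picks = perm[picks[picks < len(population)]]

    sampled = []
    for idx in sorted(picks):
        s = replace(population[idx], weight_ha=unit / pi[idx])
        sampled.append(s)

    remaining = sorted(set(range(len(population))) - set(picks.tolist()))
    n_np = min(config.n_nonprobability_sites, len(remaining))
    np_idx = rng.choice(len(remaining), size=n_np, replace=False) if n_np else []
    nonprob = []
    for j in np_idx:
        s = replace(population[remaining[j]], probability_site=False,
                    weight_ha=unit)
        nonprob.append(s)
    nonprob.sort(key=lambda s: s.site_id)
    return sampled, nonprob
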