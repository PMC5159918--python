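import pytest
from hypothesis import settings

from wetcarbon.model import REGION_BY_GROUP, SiteRecord, SoilHorizon
from wetcarbon.simulate import SimulationConfig, generate_population

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")


def make_profile(spec, site_id="P1", **common):
    """Build a contiguous profile from (thickness, soc, bd[, organic]) tuples.

    soc/bd may be None for missing values.
    """
    horizons = []
    top = 0.0
    for order, layer in enumerate(spec, start=1):
        thickness, soc, bd = layer[:3]
        organic = layer[3] if len(layer) > 3 else False
        horizons.append(SoilHorizon(
            site_id=site_id, horizon_order=order, top_depth_cm=top,
            bottom_depth_cm=top + thickness, organic_flag=organic,
            soc_pct=soc, bd_g_cm3=bd, **common))
        top += thickness
    return horizons


def make_site(site_id="A1", group="CPL-PRLH", weight=1e5, indices=None,
              probability=True):
    return SiteRecord(
        site_id=site_id, reporting_group=group,
        region=REGION_BY_GROUP[group],
        wetland_type="EH" if group.endswith("EH") else
        ("EW" if group.endswith("EW") else
         ("PRL-FO" if group.endswith("PRLW") else "PRL-EM")),
        hgm_class="Depression", tidal_saline=group.startswith("ALL-"),
        weight_ha=weight, probability_site=probability,
        disturbance_indices=indices or {})


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=42, n_population_sites=400,
                            n_sampled_sites=80, n_nonprobability_sites=15)


@pytest.fixture(scope="session")
def small_population(small_config):
    return generate_population(small_config)
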