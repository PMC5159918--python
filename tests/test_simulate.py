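import dataclasses

import numpy as np
import pytest

from wetcarbon import accounting
from wetcarbon.estimation import estimate_subpopulation
from wetcarbon.simulate import (
    SimulationConfig,
    generate_population,
    sample_survey,
)


def test_same_seed_reproduces_everything(small_config):
    a_sites, a_prof, a_truth = generate_population(small_config)
    b_sites, b_prof, b_truth = generate_population(small_config)
    assert a_sites == b_sites
    assert a_prof == b_prof
    assert a_truth.true_total_PgC == b_truth.true_total_PgC
    sa, na = sample_survey(a_sites, small_config)
    sb, nb = sample_survey(b_sites, small_config)
    assert sa == sb and na == nb


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(n_population_sites=10, n_sampled_sites=20).validate()
    with pytest.raises(ValueError):
        SimulationConfig(thin_horizon_rate=1.5).validate()
    cfg = SimulationConfig()
    cfg.group_mix = {"CPL-PRLH": 0.5}
    with pytest.raises(ValueError, match="sum to 1"):
        cfg.validate()


def test_zero_thin_rate_yields_no_thin_horizons():
    cfg = SimulationConfig(seed=3, n_population_sites=100, n_sampled_sites=30,
                           thin_horizon_rate=0.0)
    _, profiles, _ = generate_population(cfg)
    assert not any(h.thin_flag for prof in profiles.values() for h in prof)


def test_rates_materialize_roughly(small_population):
    _, profiles, _ = small_population
    horizons = [h for prof in profiles.values() for h in prof]
    thin = np.mean([h.thin_flag for h in horizons])
    assert 0.15 < thin < 0.35
    sampled = [h for h in horizons if not h.thin_flag]
    missing_bd = np.mean([h.bd_g_cm3 is None for h in sampled])
    assert 0.20 < missing_bd < 0.40


def test_generated_horizons_satisfy_field_invariants(small_population):
    _, profiles, _ = small_population
    for prof in profiles.values():
        for h in prof:
            h.validate()
        for prev, nxt in zip(prof, prof[1:]):
            assert nxt.top_depth_cm == pytest.approx(prev.bottom_depth_cm)


def test_truth_matches_bruteforce_recomputation():
    """With no masking, totals recomputed from the emitted horizons by
    direct slicing and summation equal the stored ground truth."""
    cfg = SimulationConfig(seed=9, n_population_sites=80, n_sampled_sites=20,
                           thin_horizon_rate=0.0, bd_missing_rate=0.0,
                           bd_error_rate=0.0, soc_noise_sd=0.0,
                           bd_noise_sd=0.0)
    sites, profiles, truth = generate_population(cfg)
    unit = cfg.frame_area_ha / cfg.n_population_sites
    total = 0.0
    for s in sites:
        sliced = accounting.slice_profile(profiles[s.site_id])
        d = accounting.depth_range_density(sliced, 0, 120)
        if d is not None:
            total += unit * d * 1e-9
    assert total == pytest.approx(truth.true_total_PgC[("national", "0-120")],
                                  rel=1e-12)


def test_census_draw_returns_everyone_with_unit_weights():
    cfg = SimulationConfig(seed=5, n_population_sites=50, n_sampled_sites=50,
                           n_nonprobability_sites=0,
                           inclusion_probability_by_type={
                               t: 1.0 for t in ("EH", "EW", "PRL-EM", "PRL-SS",
                                                "PRL-FO", "PRL-f", "PRL-UBAB")})
    pop, _, _ = generate_population(cfg)
    sampled, nonprob = sample_survey(pop, cfg)
    assert len(sampled) == 50 and nonprob == []
    unit = cfg.frame_area_ha / 50
    assert all(s.weight_ha == pytest.approx(unit) for s in sampled)
    assert sorted(s.site_id for s in sampled) == sorted(s.site_id for s in pop)


def test_equal_probabilities_give_equal_weights(small_config):
    cfg = dataclasses.replace(
        small_config,
        inclusion_probability_by_type={t: 2.0 for t in ("EH", "EW", "PRL-EM",
                                                        "PRL-SS", "PRL-FO",
                                                        "PRL-f", "PRL-UBAB")})
    pop, _, _ = generate_population(cfg)
    sampled, _ = sample_survey(pop, cfg)
    assert len(sampled) == cfg.n_sampled_sites
    weights = {round(s.weight_ha, 6) for s in sampled}
    assert len(weights) == 1


def test_weighted_site_count_unbiased(small_population, small_config):
    """Horvitz-Thompson estimate of the population size over replicate
    draws stays within 3 Monte-Carlo standard errors of truth."""
    pop, _, _ = small_population
    unit = small_config.frame_area_ha / small_config.n_population_sites
    reps = 200
    counts = []
    for r in range(reps):
        sampled, _ = sample_survey(pop, small_config, seed=5_000 + r)
        counts.append(sum(s.weight_ha for s in sampled) / unit)
    counts = np.asarray(counts)
    mc_se = counts.std(ddof=1) / np.sqrt(reps)
    assert abs(counts.mean() - small_config.n_population_sites) <= 3 * mc_se


def test_ht_total_unbiased_over_replicates(small_population, small_config):
    pop, _, truth = small_population
    y = {s.site_id: truth.site_density_tC_ha[s.site_id]["0-120"] for s in pop}
    reps = 200
    tots = []
    for r in range(reps):
        sampled, _ = sample_survey(pop, small_config, seed=9_000 + r)
        est = estimate_subpopulation([y[s.site_id] for s in sampled],
                                     [s.weight_ha for s in sampled],
                                     "national", 0, 120)
        tots.append(est.total_PgC)
    tots = np.asarray(tots)
    mc_se = tots.std(ddof=1) / np.sqrt(reps)
    target = truth.true_total_PgC[("national", "0-120")]
    assert abs(tots.mean() - target) <= 3 * mc_se


def test_disturbance_classes_separate_in_truth(small_population):
    _, _, truth = small_population
    by_class = {}
    for sid, dens in truth.site_density_tC_ha.items():
        if dens["0-120"] is not None:
            by_class.setdefault(truth.disturbance_class[sid], []).append(
                dens["0-120"])
    assert np.mean(by_class["most"]) < np.mean(by_class["least"])
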