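import math

import numpy as np
import pytest

from wetcarbon.estimation import (
    depth_shares,
    estimate_subpopulation,
    mean_difference,
    scale_to_target,
    stock_shares,
    summarize_fractions,
)
from wetcarbon.model import PopulationEstimate


def _est(sub, lo, hi, total, area):
    return PopulationEstimate(sub, lo, hi, total * 1e9 / (area * 1e6),
                              float("nan"), total, float("nan"), 1, area)


def test_equal_weights_reduce_to_sample_mean():
    y = [100.0, 200.0, 300.0, 400.0]
    w = [5e4] * 4
    est = estimate_subpopulation(y, w, "s", 0, 120)
    assert est.mean_tC_ha == pytest.approx(250.0)
    assert est.total_PgC == pytest.approx(4 * 5e4 * 250.0 * 1e-9)
    assert est.n_sites == 4
    assert est.area_Mha == pytest.approx(0.2)


def test_single_site_unit_chain():
    est = estimate_subpopulation([400.0], [1e6], "s", 0, 120)
    assert est.total_PgC == pytest.approx(0.4)
    assert math.isnan(est.se_total)


def test_census_weights_give_population_total():
    rng = np.random.default_rng(0)
    y = rng.uniform(50, 500, 40)
    unit = 1e4
    est = estimate_subpopulation(y, [unit] * 40, "s", 0, 120)
    assert est.total_PgC == pytest.approx(unit * y.sum() * 1e-9, rel=1e-12)
    assert est.mean_tC_ha == pytest.approx(y.mean(), rel=1e-12)


def test_empty_subpopulation_flagged():
    est = estimate_subpopulation([None, None], [1e4, 1e4], "s", 0, 120)
    assert est.n_sites == 0 and math.isnan(est.total_PgC)


def test_unavailable_sites_enter_variance_not_point_estimate():
    y = [100.0, 200.0, None, None]
    w = [1e4] * 4
    est = estimate_subpopulation(y, w, "s", 90, 120)
    assert est.n_sites == 2
    assert est.total_PgC == pytest.approx(3e6 * 1e-9)
    # zero-extended with-replacement variance over all four sampled sites
    u = np.array([1e6, 2e6, 0.0, 0.0])
    var = 4 / 3 * ((u - u.mean()) ** 2).sum()
    assert est.se_total == pytest.approx(np.sqrt(var) * 1e-9, rel=1e-12)


def test_rejects_bad_weights():
    with pytest.raises(ValueError):
        estimate_subpopulation([1.0], [0.0], "s", 0, 120)


def test_scaling_examples():
    est = _est("national", 0, 120, 7.54, 25.2)
    same = scale_to_target(est, 25.2, 25.2)
    assert same.total_PgC == pytest.approx(7.54)
    scaled = scale_to_target(est, 25.2, 38.4)
    assert scaled.total_PgC == pytest.approx(11.49, abs=0.005)
    assert scaled.mean_tC_ha == est.mean_tC_ha  # density invariant
    assert math.isnan(scaled.se_total)
    with pytest.raises(ValueError):
        scale_to_target(est, 0.0, 38.4)


def test_uniform_depth_stocks_quarter_shares():
    ests = [_est("s", lo, lo + 30, 1.1, 10.0) for lo in (0, 30, 60, 90)]
    shares = depth_shares(ests)
    assert all(v == pytest.approx(25.0) for v in shares.values())


def test_stock_and_mean_difference_helpers():
    a = _est("least", 0, 120, 2.25, 5.5)
    b = _est("most", 0, 120, 1.63, 7.0)
    a.mean_tC_ha, b.mean_tC_ha = 407.0, 236.0
    assert mean_difference(a, b) == pytest.approx(171.0)
    shares = stock_shares([a, b])
    assert shares["least"] + shares["most"] == pytest.approx(100.0)


def test_summarize_fractions_shapes():
    ests = [_est("teal", lo, lo + 30, t, 23.0)
            for lo, t in zip((0, 30, 60, 90), (2.42, 1.91, 1.59, 0.93))]
    blue = _est("blue", 0, 120, 0.76, 2.2)
    teal = _est("teal", 0, 120, 6.85, 23.0)
    rep = summarize_fractions(
        by_depth={"teal": ests},
        partitions={"carbon_type": [blue, teal]},
        contrasts={"blue_minus_teal": (blue, teal)})
    assert rep["depth_share_pct"]["teal"]["0-30"] == pytest.approx(
        100 * 2.42 / 6.85)
    assert rep["area_share_pct"]["carbon_type"]["teal"] == pytest.approx(
        100 * 23.0 / 25.2)
    assert "blue_minus_teal" in rep["mean_difference_tC_ha"]


def test_partition_totals_additive(small_population):
    """Blue + teal totals equal the national total on the same site set."""
    from wetcarbon.estimation import estimate_subpopulation as est_sub
    sites, _, truth = small_population
    y = {s.site_id: truth.site_density_tC_ha[s.site_id]["0-120"] for s in sites}
    w = {s.site_id: s.weight_ha for s in sites}
    nat = est_sub([y[s.site_id] for s in sites],
                  [w[s.site_id] for s in sites], "national", 0, 120)
    parts = []
    for tidal in (True, False):
        sel = [s for s in sites if s.tidal_saline == tidal]
        parts.append(est_sub([y[s.site_id] for s in sel],
                             [w[s.site_id] for s in sel], "part", 0, 120))
    assert sum(p.total_PgC for p in parts) == pytest.approx(nat.total_PgC,
                                                            rel=1e-12)


def test_se_shrinks_like_inverse_sqrt_n():
    """Mean estimated SE over replicated equal-probability designs scales
    as n^-1/2 (log-log slope within +-0.15 of -0.5)."""
    rng = np.random.default_rng(12)
    pop = rng.lognormal(5.0, 0.8, 4000)
    unit = 1e4
    ns = [50, 100, 200, 400]
    mean_se = []
    for n in ns:
        ses = []
        for _ in range(40):
            idx = rng.choice(len(pop), size=n, replace=False)
            est = estimate_subpopulation(pop[idx], [unit * len(pop) / n] * n,
                                         "s", 0, 120)
            ses.append(est.se_total)
        mean_se.append(np.mean(ses))
    slope = np.polyfit(np.log(ns), np.log(mean_se), 1)[0]
    assert slope == pytest.approx(-0.5, abs=0.15)
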