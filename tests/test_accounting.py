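import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wetcarbon import accounting
from wetcarbon.accounting import (
    G_M2_PER_TC_HA,
    depth_range_density,
    horizon_carbon_density,
    slice_profile,
)
from wetcarbon.estimation import PGC_PER_TC

from conftest import make_profile


@pytest.mark.parametrize("d,bd,soc,expected", [
    (10, 1.0, 0.0, 0.0),
    (10, 1.0, 5.0, 5_000.0),        # 10,000 * 10 * 1.0 * 0.05
    (100, 0.2, 30.0, 60_000.0),     # organic-soil magnitude, 600 tC/ha
    (1, 1.0, 10.0, 1_000.0),
])
def test_layer_density_equation(d, bd, soc, expected):
    assert horizon_carbon_density(d, bd, soc) == pytest.approx(expected)


@pytest.mark.parametrize("args", [(-1, 1.0, 5.0), (10, -0.5, 5.0),
                                  (10, 1.0, -2.0), (10, 1.0, 101.0)])
def test_layer_density_rejects_bad_domain(args):
    with pytest.raises(ValueError):
        horizon_carbon_density(*args)


def test_uniform_profile_slices():
    prof = make_profile([(120, 10.0, 1.0)])
    sliced = slice_profile(prof)
    assert sliced.available.all()
    np.testing.assert_allclose(sliced.density_g_m2_per_cm, 1000.0)
    assert depth_range_density(sliced, 0, 30) == pytest.approx(300.0)
    assert depth_range_density(sliced, 0, 120) == pytest.approx(1200.0)


def test_shallow_profile_unavailable_below_bottom():
    sliced = slice_profile(make_profile([(80, 5.0, 1.0)]))
    assert sliced.available[:80].all()
    assert not sliced.available[80:].any()
    assert depth_range_density(sliced, 60, 90) is None
    assert depth_range_density(sliced, 60, 90, prorate=True) == pytest.approx(
        150.0)  # 50 g/m2/cm over 30 cm


def test_fully_unavailable_profile():
    prof = make_profile([(50, None, None)])
    sliced = slice_profile(prof)
    assert not sliced.available.any()
    assert depth_range_density(sliced, 0, 30) is None


def test_malformed_range_rejected():
    sliced = slice_profile(make_profile([(120, 10.0, 1.0)]))
    for lo, hi in [(-1, 30), (30, 30), (60, 30), (0, 121)]:
        with pytest.raises(ValueError):
            depth_range_density(sliced, lo, hi)


@given(st.lists(st.tuples(
    st.floats(1.0, 40.0),      # thickness, possibly non-integer
    st.floats(0.0, 45.0),      # soc %
    st.floats(0.1, 2.0)),      # bulk density
    min_size=1, max_size=8))
@settings(max_examples=150, deadline=None)
def test_slicing_conserves_horizon_totals(layers):
    """Slices re-sum to the piecewise-constant density integral.

    Oracle: over any fully covered integer window [0, W) the stock is
    the sum over horizons of (overlap thickness) x (per-cm density),
    computed directly from the equation without any slicing.
    """
    prof = make_profile([(t, s, b) for t, s, b in layers])
    sliced = slice_profile(prof)
    described = min(prof[-1].bottom_depth_cm, 120.0)
    W = int(np.floor(described))
    if W == 0:
        return
    direct = sum(
        horizon_carbon_density(1.0, h.bd_g_cm3, h.soc_pct)
        * max(0.0, min(h.bottom_depth_cm, float(W)) - h.top_depth_cm)
        for h in prof if h.top_depth_cm < W)
    assert sliced.available[:W].all()
    assert sliced.density_g_m2_per_cm[:W].sum() == pytest.approx(
        direct, rel=1e-9, abs=1e-6)


def test_per_horizon_conservation_integer_bounds():
    prof = make_profile([(30, 12.0, 0.4), (50, 6.0, 0.9), (40, 1.5, 1.4)])
    sliced = slice_profile(prof)
    for h in prof:
        lo, hi = int(h.top_depth_cm), int(h.bottom_depth_cm)
        assert sliced.density_g_m2_per_cm[lo:hi].sum() == pytest.approx(
            horizon_carbon_density(h.thickness_cm, h.bd_g_cm3, h.soc_pct),
            rel=1e-9)


def test_range_additivity():
    prof = make_profile([(25.5, 8.0, 0.7), (60.0, 3.0, 1.1), (34.5, 1.0, 1.5)])
    sliced = slice_profile(prof)
    whole = depth_range_density(sliced, 0, 120)
    assert whole == pytest.approx(
        depth_range_density(sliced, 0, 40) + depth_range_density(sliced, 40, 120),
        rel=1e-12)


def test_unit_chain_identities():
    # 1 g m^-2 is 0.01 tC ha^-1; one tonne of carbon is 1e-9 PgC, so
    # 1e6 ha at 1 tC ha^-1 holds 1e-3 PgC (and 1e6 ha at 400 -> 0.4 PgC).
    assert 1.0 / G_M2_PER_TC_HA == pytest.approx(0.01)
    assert PGC_PER_TC == pytest.approx(1e-9)
    assert 1e6 * 1.0 * PGC_PER_TC == pytest.approx(1e-3)
    assert 1e6 * 400.0 * PGC_PER_TC == pytest.approx(0.4)
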