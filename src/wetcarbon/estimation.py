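"""Design-based estimation of mean carbon density and total stock.

Sites enter with inverse-inclusion-probability weights expressed in
hectares (w_i = unit area / pi_i).  For a subpopulation and depth range
the Horvitz-Thompson total of carbon (tC) is sum(w_i * y_i) with y_i in
tC ha^-1, converted to PgC (1 Pg = 1e15 g, 1 t = 1e6 g); the mean
density is the ratio estimator sum(w_i y_i) / sum(w_i).  Standard errors
use the with-replacement (Hansen-Hurwitz style) approximation

    var(total) = n/(n-1) * sum_i (w_i y_i - mean_j(w_j y_j))^2

with ratio linearization for the mean.  This is a simplification of the
local-neighbourhood variance estimators used with spatially balanced
designs (site coordinates are out of scope here); point estimates are
unaffected, standard errors are typically mildly conservative.
"""

from __future__ import annotations

import numpy as np

from .model import PopulationEstimate

__all__ = ["estimate_subpopulation", "scale_to_target",
           "depth_shares", "area_shares", "mean_difference",
           "summarize_fractions", "PGC_PER_TC"]

#: One tonne of carbon in petagrams (1e6 g / 1e15 g).
PGC_PER_TC = 1e-9


def estimate_subpopulation(densities_tC_ha, weights_ha, subpopulation: str,
                           depth_lo_cm: float, depth_hi_cm: float,
                           ) -> PopulationEstimate:
    """Estimate mean density and total stock for one subpopulation x range.

    ``densities_tC_ha`` holds per-site depth-range densities for every
    sampled site of the subpopulation; entries of None/NaN mark sites
    whose profile does not fully cover the range.  Such sites contribute
    nothing to the point estimates (the contributing n shrinks with
    depth) but remain in the variance as zero-contribution sample
    members — availability is part of the sampling randomness, and
    dropping those terms understates the standard error of the total.
    An empty subpopulation yields a flagged estimate with n=0 and NaN
    values.
    """
    y = np.asarray([np.nan if d is None else d for d in densities_tC_ha],
                   dtype=float)
    w = np.asarray(weights_ha, dtype=float)
    if y.shape != w.shape:
        raise ValueError("densities and weights must align")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    avail = ~np.isnan(y)
    n = int(avail.sum())
    n_all = int(len(y))
    if n == 0:
        return PopulationEstimate(subpopulation, depth_lo_cm, depth_hi_cm,
                                  float("nan"), float("nan"), float("nan"),
                                  float("nan"), 0, float("nan"))
    area_ha = float(w[avail].sum())
    u = np.where(avail, w * np.nan_to_num(y), 0.0)  # zero-extended w_i*y_i
    total_tc = float(u.sum())
    mean = total_tc / area_ha
    if n_all >= 2:
        var_total = n_all / (n_all - 1.0) * float(((u - u.mean()) ** 2).sum())
        resid = np.where(avail, w * (np.nan_to_num(y) - mean), 0.0)
        var_mean = n_all / (n_all - 1.0) * float(
            ((resid - resid.mean()) ** 2).sum()) / area_ha ** 2
    else:
        var_total = var_mean = float("nan")
    return PopulationEstimate(
        subpopulation=subpopulation,
        depth_lo_cm=depth_lo_cm,
        depth_hi_cm=depth_hi_cm,
        mean_tC_ha=mean,
        se_mean=float(np.sqrt(var_mean)),
        total_PgC=total_tc * PGC_PER_TC,
        se_total=float(np.sqrt(var_total)) * PGC_PER_TC,
        n_sites=n,
        area_Mha=area_ha / 1e6,
    )


def scale_to_target(est: PopulationEstimate, inference_area_Mha: float,
                    target_area_Mha: float) -> PopulationEstimate:
    """Scale a total proportionally from the inference to the target area.

    Extrapolation assumes the unsampled area follows the same trends as
    the sampled area: the mean density is unchanged, the total scales by
    the area ratio, and standard errors are not defined for the scaled
    estimate (reported NaN).
    """
    if inference_area_Mha <= 0 or target_area_Mha <= 0:
        raise ValueError("areas must be positive")
    ratio = target_area_Mha / inference_area_Mha
    return PopulationEstimate(
        subpopulation=est.subpopulation,
        depth_lo_cm=est.depth_lo_cm,
        depth_hi_cm=est.depth_hi_cm,
        mean_tC_ha=est.mean_tC_ha,
        se_mean=float("nan"),
        total_PgC=est.total_PgC * ratio,
        se_total=float("nan"),
        n_sites=est.n_sites,
        area_Mha=est.area_Mha * ratio,
    )


def depth_shares(estimates: list[PopulationEstimate]) -> dict[tuple, float]:
    """Percent of a subpopulation's stock in each depth increment.

    All estimates must belong to one subpopulation; shares are of the
    summed increment totals.
    """
    subs = {e.subpopulation for e in estimates}
    if len(subs) != 1:
        raise ValueError(f"expected a single subpopulation, got {subs}")
    grand = sum(e.total_PgC for e in estimates)
    if grand == 0:
        raise ZeroDivisionError("zero total stock")
    return {(e.depth_lo_cm, e.depth_hi_cm): 100.0 * e.total_PgC / grand
            for e in estimates}


def area_shares(estimates: list[PopulationEstimate]) -> dict[str, float]:
    """Percent of total represented area held by each subpopulation."""
    total = sum(e.area_Mha for e in estimates)
    if total == 0:
        raise ZeroDivisionError("zero total area")
    return {e.subpopulation: 100.0 * e.area_Mha / total for e in estimates}


def stock_shares(estimates: list[PopulationEstimate]) -> dict[str, float]:
    """Percent of total stock held by each subpopulation."""
    total = sum(e.total_PgC for e in estimates)
    if total == 0:
        raise ZeroDivisionError("zero total stock")
    return {e.subpopulation: 100.0 * e.total_PgC / total for e in estimates}


def mean_difference(a: PopulationEstimate, b: PopulationEstimate) -> float:
    """Difference of mean densities (a minus b), tC ha^-1."""
    return a.mean_tC_ha - b.mean_tC_ha


def summarize_fractions(by_depth: dict[str, list[PopulationEstimate]] | None = None,
                        partitions: dict[str, list[PopulationEstimate]] | None = None,
                        contrasts: dict[str, tuple[PopulationEstimate,
                                                   PopulationEstimate]] | None = None,
                        ) -> dict:
    """Ratio/percentage report over a set of estimates.

    ``by_depth`` maps subpopulation -> its per-increment estimates
    (yields depth shares); ``partitions`` maps a partition name -> the
    estimates partitioning the population (yields area and stock
    shares); ``contrasts`` maps a label -> (a, b) estimate pairs (yields
    mean-density differences).
    """
    out: dict = {}
    for sub, ests in (by_depth or {}).items():
        out.setdefault("depth_share_pct", {})[sub] = {
            f"{int(lo)}-{int(hi)}": share
            for (lo, hi), share in depth_shares(ests).items()}
    for name, ests in (partitions or {}).items():
        out.setdefault("area_share_pct", {})[name] = area_shares(ests)
        out.setdefault("stock_share_pct", {})[name] = stock_shares(ests)
    for name, (a, b) in (contrasts or {}).items():
        out.setdefault("mean_difference_tC_ha", {})[name] = mean_difference(a, b)
    return out
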