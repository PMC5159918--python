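"""Disturbance-gradient screening over the ten stressor measures.

Each site carries ten non-negative disturbance indices (buffer stressor
counts, in-site hydrologic stressor counts, a soil heavy-metal
exceedance count and alien-plant relative cover).  Screening is a pure
threshold filter applied per reporting group:

* least disturbed — at or below the "least" threshold on all ten
  measures;
* most disturbed — above the "most" threshold on any single measure;
* intermediate — everything else.

Because "most disturbed" is a relative notion, the most-thresholds are
calibrated per reporting group to upper quantiles of the observed
indices so that roughly 20-30% of screened sites land in the most
disturbed class.  Both probability and non-probability sites enter
calibration; only probability sites enter population estimates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .model import DISTURBANCE_MEASURES, SiteRecord

log = logging.getLogger(__name__)

__all__ = ["DisturbanceThresholds", "screen_site", "screen_sites",
           "calibrate_most_thresholds", "gradient_summary"]

CLASSES = ("least", "intermediate", "most")


@dataclass
class DisturbanceThresholds:
    """Per-reporting-group least/most screening thresholds.

    ``least_max[group]`` and ``most_min[group]`` are length-10 arrays in
    :data:`~wetcarbon.model.DISTURBANCE_MEASURES` order; exceeding any
    least_max disqualifies "least", exceeding any most_min forces "most".
    """

    least_max: dict[str, np.ndarray] = field(default_factory=dict)
    most_min: dict[str, np.ndarray] = field(default_factory=dict)

    def validate(self) -> None:
        for g in self.least_max:
            lo, hi = np.asarray(self.least_max[g]), np.asarray(self.most_min[g])
            if lo.shape != (10,) or hi.shape != (10,):
                raise ValueError(f"{g}: thresholds must have 10 entries")
            if np.any(lo > hi + 1e-12):
                raise ValueError(f"{g}: least_max exceeds most_min")


def _bisect_quantile(fraction_at, target: float, decreasing: bool) -> float:
    """Quantile level whose realized fraction is nearest the target.

    ``fraction_at(q)`` must be monotone in q (non-increasing when
    ``decreasing``); ties/plateaus yield the nearest achievable value.
    """
    lo_q, hi_q = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo_q + hi_q)
        f = fraction_at(mid)
        if (f > target) == decreasing:
            lo_q = mid
        else:
            hi_q = mid
    return min((hi_q, lo_q), key=lambda q: abs(fraction_at(q) - target))


def _index_vector(site: SiteRecord) -> np.ndarray | None:
    vals = [site.disturbance_indices.get(m) for m in DISTURBANCE_MEASURES]
    if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in vals):
        return None
    return np.asarray(vals, dtype=float)


def screen_site(indices: np.ndarray, least_max: np.ndarray,
                most_min: np.ndarray) -> str:
    """Classify one ten-index vector against its group's thresholds."""
    indices = np.asarray(indices, dtype=float)
    if indices.shape != (10,):
        raise ValueError("expected 10 disturbance indices")
    if np.all(indices <= least_max):
        return "least"
    if np.any(indices > most_min):
        return "most"
    return "intermediate"


def screen_sites(sites: list[SiteRecord],
                 thresholds: DisturbanceThresholds) -> dict[str, str | None]:
    """Screen every site; missing indices map to None (excluded, logged)."""
    out: dict[str, str | None] = {}
    for s in sites:
        vec = _index_vector(s)
        if vec is None:
            log.warning("%s: missing disturbance index, excluded from gradient",
                        s.site_id)
            out[s.site_id] = None
        else:
            out[s.site_id] = screen_site(
                vec, thresholds.least_max[s.reporting_group],
                thresholds.most_min[s.reporting_group])
    return out


def calibrate_most_thresholds(sites: list[SiteRecord],
                              target_fraction: float = 0.25,
                              least_quantile: float | None = None,
                              least_target_fraction: float = 0.25,
                              min_group_size: int = 20,
                              allow_pooling: bool = True,
                              ) -> DisturbanceThresholds:
    """Set per-group thresholds from the empirical index distributions.

    The "most" thresholds for a group are the common quantile of each
    index chosen (by bisection on the quantile level, which the realized
    most-fraction decreases in) so the realized most-disturbed fraction
    is as close as possible to ``target_fraction``.  The "least"
    thresholds are calibrated the same way against
    ``least_target_fraction`` (the fraction at or below threshold on all
    ten measures) unless a fixed per-index ``least_quantile`` is given;
    either way they are capped at the most thresholds.  With heavily
    tied indices a target may be unattainable; the nearest achievable
    fraction is used with a warning.

    Groups with fewer than ``min_group_size`` screened sites cannot
    support their own quantiles; with ``allow_pooling`` (default) they
    fall back to thresholds calibrated over all screened sites pooled
    (the analogue of relaxing thresholds for sparse groups), otherwise
    they raise.
    """
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must be in (0, 1)")
    by_group: dict[str, list[np.ndarray]] = {}
    for s in sites:
        vec = _index_vector(s)
        if vec is not None:
            by_group.setdefault(s.reporting_group, []).append(vec)
    thr = DisturbanceThresholds()
    pooled = np.vstack([v for vecs in by_group.values() for v in vecs])
    groups = sorted(by_group)
    for g in groups:
        x = np.vstack(by_group[g])
        if len(x) < min_group_size:
            if not allow_pooling:
                raise ValueError(
                    f"{g}: only {len(x)} screened sites, need >= {min_group_size}")
            log.warning("%s: only %d screened sites; using pooled thresholds",
                        g, len(x))
            x = pooled

        def most_fraction(q: float) -> float:
            mm = np.quantile(x, q, axis=0)
            return float(np.mean(np.any(x > mm[None, :], axis=1)))

        def least_fraction(q: float) -> float:
            lm = np.quantile(x, q, axis=0)
            return float(np.mean(np.all(x <= lm[None, :], axis=1)))

        q = _bisect_quantile(most_fraction, target_fraction, decreasing=True)
        realized = most_fraction(q)
        if abs(realized - target_fraction) > 0.05:
            log.warning("%s: most-disturbed fraction %.2f is the nearest "
                        "achievable to target %.2f (tied/degenerate indices)",
                        g, realized, target_fraction)
        most_min = np.quantile(x, q, axis=0)
        if least_quantile is not None:
            lq = least_quantile
        else:
            lq = _bisect_quantile(least_fraction, least_target_fraction,
                                  decreasing=False)
        least_max = np.minimum(np.quantile(x, lq, axis=0), most_min)
        thr.most_min[g] = most_min
        thr.least_max[g] = least_max
    thr.validate()
    return thr


def gradient_summary(assignments: dict[str, str | None] | list[str]) -> dict:
    """Counts and integer percentages per disturbance class.

    Accepts either the per-site assignment mapping or a bare list of
    class labels; None (unscreened) entries are dropped.  Percentages
    are rounded to integers and refer to the screened total.
    """
    labels = (list(assignments.values())
              if isinstance(assignments, dict) else list(assignments))
    labels = [x for x in labels if x is not None]
    counts = {c: labels.count(c) for c in CLASSES}
    total = len(labels)
    pct = {c: (round(100.0 * n / total) if total else 0)
           for c, n in counts.items()}
    return {"counts": counts, "percent": pct, "total": total}
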