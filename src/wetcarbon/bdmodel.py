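"""Gradient-boosted regression-tree model for bulk density.

Bulk density cannot be measured for thin or inaccessible horizons, so it
is predicted from horizon covariates with stagewise boosted shallow
regression trees under squared-error loss (shrinkage + row
subsampling), trained on the horizons that do carry measurements.  The
predictor set is fixed: SOC concentration, reporting group, electrical
conductivity, cation exchange capacity, horizon mid-depth, clay, silt,
HGM class, sand and the 1-based order of the horizon in the profile.
Model quality is summarized by the coefficient of determination on a
held-out split (default 30%) and by per-predictor relative importance
(share of the total squared-error reduction attributable to splits on
each predictor, normalized to 100%).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor

from .model import SoilHorizon, SiteRecord

log = logging.getLogger(__name__)

__all__ = ["BDModelSpec", "BDModelFit", "fit_bd_model", "predict_bd",
           "horizons_to_frame", "PREDICTORS", "BD_PREDICTION_BOUNDS"]

#: The ten predictors, in reporting order.
PREDICTORS = ("soc_pct", "reporting_group", "ec", "cec", "horizon_mid_depth_cm",
              "clay_pct", "silt_pct", "hgm_class", "sand_pct", "horizon_order")

_CATEGORICAL = ("reporting_group", "hgm_class")
_NUMERIC = tuple(p for p in PREDICTORS if p not in _CATEGORICAL)

#: Predictions are truncated into this (lo, hi] interval, g cm^-3; the
#: upper bound is the measurable ceiling also used by QC screening.
BD_PREDICTION_BOUNDS = (0.05, 2.0)


@dataclass
class BDModelSpec:
    """Hyperparameters for the boosted bulk-density model."""

    n_trees: int = 3000
    shrinkage: float = 0.01
    max_tree_depth: int = 5
    bag_fraction: float = 0.5
    train_fraction: float = 0.70
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.shrinkage <= 1:
            raise ValueError("shrinkage must be in (0, 1]")
        if not 0 < self.bag_fraction <= 1:
            raise ValueError("bag_fraction must be in (0, 1]")
        if not 0 < self.train_fraction <= 1:
            raise ValueError("train_fraction must be in (0, 1]")
        if self.n_trees < 1 or self.max_tree_depth < 1:
            raise ValueError("n_trees and max_tree_depth must be >= 1")


@dataclass
class BDModelFit:
    """A fitted bulk-density model with its holdout skill and importances."""

    model: GradientBoostingRegressor
    feature_columns: list[str]
    column_predictor: dict[str, str]
    numeric_fill: dict[str, float]
    categorical_levels: dict[str, list[str]]
    holdout_r2: float
    importance: dict[str, float] = field(default_factory=dict)


def horizons_to_frame(profiles: dict[str, list[SoilHorizon]],
                      sites: dict[str, SiteRecord]) -> pd.DataFrame:
    """Flatten horizons plus their site labels into a predictor frame."""
    rows = []
    for site_id, horizons in profiles.items():
        site = sites[site_id]
        for h in horizons:
            rows.append({
                "site_id": site_id,
                "horizon_order": h.horizon_order,
                "soc_pct": h.soc_pct,
                "ec": h.ec,
                "cec": h.cec,
                "horizon_mid_depth_cm": h.mid_depth_cm,
                "clay_pct": h.clay_pct,
                "silt_pct": h.silt_pct,
                "sand_pct": h.sand_pct,
                "reporting_group": site.reporting_group,
                "hgm_class": site.hgm_class,
                "bd_g_cm3": h.bd_g_cm3,
                "bd_source": h.bd_source,
            })
    return pd.DataFrame(rows)


def _encode(df: pd.DataFrame, fit: BDModelFit) -> np.ndarray:
    """Encode a predictor frame against the fitted design (one-hot +
    median/mode fills; unseen categorical levels map to 'other')."""
    X = pd.DataFrame(index=df.index)
    for p in _NUMERIC:
        col = pd.to_numeric(df[p], errors="coerce")
        if col.isna().any():
            log.debug("filling %d missing %s with training median",
                      int(col.isna().sum()), p)
        X[p] = col.fillna(fit.numeric_fill[p])
    for p in _CATEGORICAL:
        levels = fit.categorical_levels[p]
        vals = df[p].astype(str)
        unseen = ~vals.isin(levels)
        if unseen.any():
            warnings.warn(f"{int(unseen.sum())} unseen {p} level(s) mapped to "
                          f"'other'", stacklevel=2)
            vals = vals.where(~unseen, "other")
        for lev in levels:
            X[f"{p}={lev}"] = (vals == lev).astype(float)
    return X[fit.feature_columns].to_numpy(dtype=float)


def fit_bd_model(frame: pd.DataFrame, spec: BDModelSpec) -> BDModelFit:
    """Fit the boosted model on horizons with measured bulk density.

    ``frame`` is a :func:`horizons_to_frame` output (or any frame with
    the ten predictor columns plus ``bd_g_cm3``); rows lacking the
    response are dropped, missing predictors are median/mode-filled from
    the training split.  A seeded simple random ``train_fraction`` split
    provides the holdout R^2 = 1 - SSE/SST.  A degenerate (constant)
    response still fits, with R^2 reported as 0 and a warning.
    """
    spec.validate()
    data = frame.dropna(subset=["bd_g_cm3"]).reset_index(drop=True)
    if len(data) < 50:
        raise ValueError(f"need >= 50 training records, got {len(data)}")
    rng = np.random.default_rng(spec.seed)
    n = len(data)
    order = rng.permutation(n)
    n_train = max(1, int(round(spec.train_fraction * n)))
    train_idx, test_idx = order[:n_train], order[n_train:]

    train = data.iloc[train_idx]
    numeric_fill = {p: float(pd.to_numeric(train[p], errors="coerce").median())
                    for p in _NUMERIC}
    categorical_levels = {
        p: sorted(train[p].astype(str).unique().tolist()) + ["other"]
        for p in _CATEGORICAL}
    feature_columns = list(_NUMERIC) + [
        f"{p}={lev}" for p in _CATEGORICAL for lev in categorical_levels[p]]
    column_predictor = {c: c.split("=")[0] for c in feature_columns}

    fit = BDModelFit(model=None, feature_columns=feature_columns,
                     column_predictor=column_predictor,
                     numeric_fill=numeric_fill,
                     categorical_levels=categorical_levels,
                     holdout_r2=float("nan"))
    X_train = _encode(train, fit)
    y_train = train["bd_g_cm3"].to_numpy(dtype=float)

    model = GradientBoostingRegressor(
        loss="squared_error",
        n_estimators=spec.n_trees,
        learning_rate=spec.shrinkage,
        max_depth=spec.max_tree_depth,
        subsample=spec.bag_fraction,
        random_state=int(spec.seed) & 0x7FFFFFFF,
    )
    model.fit(X_train, y_train)
    fit.model = model

    # holdout skill
    if len(test_idx):
        test = data.iloc[test_idx]
        y_test = test["bd_g_cm3"].to_numpy(dtype=float)
        pred = model.predict(_encode(test, fit))
        sst = float(((y_test - y_test.mean()) ** 2).sum())
        if np.ptp(y_test) == 0:  # constant response; sst is numerically 0
            warnings.warn("constant bulk-density response; holdout R^2 "
                          "reported as 0", stacklevel=2)
            fit.holdout_r2 = 0.0
        else:
            fit.holdout_r2 = 1.0 - float(((y_test - pred) ** 2).sum()) / sst
    # importance: impurity reductions summed over each predictor's columns
    raw = model.feature_importances_
    imp = {p: 0.0 for p in PREDICTORS}
    for col, v in zip(feature_columns, raw):
        imp[column_predictor[col]] += float(v)
    total = sum(imp.values())
    if total > 0:
        imp = {p: 100.0 * v / total for p, v in imp.items()}
    fit.importance = imp
    return fit


def predict_bd(fit: BDModelFit, frame: pd.DataFrame) -> np.ndarray:
    """Predict bulk density for a predictor frame, truncated to (0.05, 2.0].

    Returns an empty array for empty input; truncations are logged.
    """
    if len(frame) == 0:
        return np.empty(0)
    pred = fit.model.predict(_encode(frame, fit))
    lo, hi = BD_PREDICTION_BOUNDS
    n_trunc = int(((pred < lo) | (pred > hi)).sum())
    if n_trunc:
        log.info("truncated %d bulk-density prediction(s) into (%.2f, %.2f]",
                 n_trunc, lo, hi)
    return np.clip(pred, lo, hi)
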