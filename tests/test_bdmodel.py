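import numpy as np
import pandas as pd
import pytest

from wetcarbon.bdmodel import (
    BDModelSpec,
    PREDICTORS,
    fit_bd_model,
    predict_bd,
)


def _frame(n, rng, bd):
    return pd.DataFrame({
        "soc_pct": rng.uniform(0, 40, n),
        "ec": rng.uniform(0, 10, n),
        "cec": rng.uniform(5, 60, n),
        "horizon_mid_depth_cm": rng.uniform(0, 120, n),
        "clay_pct": rng.uniform(0, 40, n),
        "silt_pct": rng.uniform(0, 40, n),
        "sand_pct": rng.uniform(0, 40, n),
        "horizon_order": rng.integers(1, 6, n),
        "reporting_group": rng.choice(["CPL-PRLH", "EMU-PRLW", "ALL-EH"], n),
        "hgm_class": rng.choice(["Riverine", "Depression"], n),
        "bd_g_cm3": bd,
    })


FAST = dict(n_trees=300, shrinkage=0.1, max_tree_depth=2, bag_fraction=1.0)


def test_constant_response_predicts_constant_with_zero_r2():
    rng = np.random.default_rng(0)
    frame = _frame(120, rng, np.full(120, 1.0))
    with pytest.warns(UserWarning, match="constant"):
        fit = fit_bd_model(frame, BDModelSpec(seed=1, **FAST))
    assert fit.holdout_r2 == 0.0
    pred = predict_bd(fit, frame.drop(columns=["bd_g_cm3"]))
    np.testing.assert_allclose(pred, 1.0, atol=1e-9)


def test_predictions_truncated_to_measurable_range():
    rng = np.random.default_rng(0)
    frame = _frame(120, rng, np.full(120, 2.4))  # above the 2.0 ceiling
    with pytest.warns(UserWarning):
        fit = fit_bd_model(frame, BDModelSpec(seed=1, **FAST))
    pred = predict_bd(fit, frame)
    np.testing.assert_allclose(pred, 2.0)


def test_noise_free_step_function_recovered():
    rng = np.random.default_rng(2)
    frame = _frame(400, rng, 0.0)
    frame["bd_g_cm3"] = np.where(frame["soc_pct"] < 12.0, 1.5, 0.4)
    fit = fit_bd_model(frame, BDModelSpec(seed=3, **FAST))
    assert fit.holdout_r2 >= 0.99
    assert max(fit.importance, key=fit.importance.get) == "soc_pct"


def test_importance_normalized_and_covers_all_predictors():
    rng = np.random.default_rng(3)
    bd = 1.6 * np.exp(-0.08 * rng.uniform(0, 40, 300))
    frame = _frame(300, rng, bd + rng.normal(0, 0.05, 300))
    fit = fit_bd_model(frame, BDModelSpec(seed=4, **FAST))
    assert set(fit.importance) == set(PREDICTORS)
    assert all(v >= 0 for v in fit.importance.values())
    assert sum(fit.importance.values()) == pytest.approx(100.0, abs=1e-6)


def test_deterministic_for_fixed_seed():
    rng = np.random.default_rng(4)
    bd = 1.6 * np.exp(-0.08 * rng.uniform(0, 40, 200)) \
        + rng.normal(0, 0.1, 200)
    frame = _frame(200, rng, np.clip(bd, 0.06, 2.0))
    spec = dict(n_trees=100, shrinkage=0.1, max_tree_depth=2, bag_fraction=0.5)
    fit1 = fit_bd_model(frame, BDModelSpec(seed=7, **spec))
    fit2 = fit_bd_model(frame, BDModelSpec(seed=7, **spec))
    assert fit1.holdout_r2 == fit2.holdout_r2
    np.testing.assert_array_equal(predict_bd(fit1, frame),
                                  predict_bd(fit2, frame))


def test_training_loss_monotone_in_iterations():
    rng = np.random.default_rng(5)
    bd = np.clip(1.6 * np.exp(-0.08 * rng.uniform(0, 40, 200))
                 + rng.normal(0, 0.1, 200), 0.06, 2.0)
    frame = _frame(200, rng, bd)
    fit = fit_bd_model(frame, BDModelSpec(
        n_trees=150, shrinkage=0.1, max_tree_depth=2, bag_fraction=1.0,
        train_fraction=1.0, seed=8))
    X = fit.model
    from wetcarbon.bdmodel import _encode
    Xmat = _encode(frame, fit)
    y = frame["bd_g_cm3"].to_numpy()
    sses = [((y - p) ** 2).sum() for p in X.staged_predict(Xmat)]
    assert all(b <= a + 1e-9 for a, b in zip(sses, sses[1:]))


def test_unseen_categorical_maps_to_other():
    rng = np.random.default_rng(6)
    bd = np.clip(1.6 * np.exp(-0.08 * rng.uniform(0, 40, 150)), 0.06, 2.0)
    frame = _frame(150, rng, bd)
    fit = fit_bd_model(frame, BDModelSpec(seed=9, **FAST))
    new = frame.head(5).copy()
    new["hgm_class"] = "Playa"
    with pytest.warns(UserWarning, match="unseen"):
        pred = predict_bd(fit, new)
    assert np.all(np.isfinite(pred)) and len(pred) == 5


def test_empty_prediction_input():
    rng = np.random.default_rng(7)
    bd = np.clip(1.6 * np.exp(-0.08 * rng.uniform(0, 40, 100)), 0.06, 2.0)
    frame = _frame(100, rng, bd)
    fit = fit_bd_model(frame, BDModelSpec(seed=10, **FAST))
    assert len(predict_bd(fit, frame.head(0))) == 0


def test_too_few_records_rejected():
    rng = np.random.default_rng(8)
    with pytest.raises(ValueError, match="50"):
        fit_bd_model(_frame(20, rng, np.ones(20)), BDModelSpec(seed=0, **FAST))
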