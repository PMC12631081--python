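"""Split stratification, CV tuning, final fit, evaluation metrics."""

import numpy as np
import pandas as pd
import pytest
from _oracles import auc_oracle

from panhrd.model import (
    HRDRegressorResults,
    evaluate,
    fit_final,
    stratified_split,
    tune_cv,
)


def test_stratified_split_exact_fractions():
    ids = [f"s{i}" for i in range(10)]
    labels = pd.Series("T1", index=ids)
    plan = stratified_split(ids, labels, fraction=0.8, seed=0)
    assert len(plan.train_ids) == 8 and len(plan.test_ids) == 2
    assert set(plan.train_ids) | set(plan.test_ids) == set(ids)
    assert set(plan.train_ids) & set(plan.test_ids) == set()


def test_singleton_tumor_goes_to_train():
    ids = ["a", "b", "c", "only"]
    labels = pd.Series(["T1", "T1", "T1", "T2"], index=ids)
    plan = stratified_split(ids, labels, fraction=0.8, seed=1)
    assert "only" in set(plan.train_ids)


def test_split_is_per_tumor_and_deterministic(small_cohort):
    _, exposures, _, _ = small_cohort
    labels = exposures.tumor_labels
    p1 = stratified_split(labels.index, labels, seed=3)
    p2 = stratified_split(labels.index, labels, seed=3)
    assert list(p1.train_ids) == list(p2.train_ids)
    for t in labels.unique():
        n = (labels == t).sum()
        n_train = labels.loc[p1.train_ids].eq(t).sum()
        assert abs(n_train - 0.8 * n) <= 1


def test_split_rejects_empty_cohort():
    with pytest.raises(ValueError):
        stratified_split([], pd.Series(dtype=object))


def _toy_regression(n=200, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, 5)), columns=[f"f{i}" for i in range(5)],
        index=[f"s{i}" for i in range(n)],
    )
    y = pd.Series(X["f0"] * 2 + 0.1 * rng.normal(size=n), index=X.index)
    return X, y


def test_tune_single_candidate_returned_unchanged():
    X, y = _toy_regression()
    cand = {"learning_rate": 0.1, "max_depth": 3, "min_child_weight": 1.0,
            "subsample": 1.0, "colsample_bytree": 1.0}
    best, table = tune_cv(X, y, [cand], seed=0)
    assert {k: best[k] for k in cand} == cand
    assert len(table) == 1 and "n_estimators" in best


def test_tune_prefers_adequate_over_crippled_candidate():
    X, y = _toy_regression(seed=1)
    good = {"learning_rate": 0.1, "max_depth": 4, "min_child_weight": 1.0,
            "subsample": 1.0, "colsample_bytree": 1.0}
    crippled = {"learning_rate": 0.001, "max_depth": 1, "min_child_weight": 50.0,
                "subsample": 0.6, "colsample_bytree": 0.6}
    best, table = tune_cv(X, y, [crippled, good], seed=1)
    assert table.loc[1, "cv_rmse"] < table.loc[0, "cv_rmse"]
    assert best["max_depth"] == 4


def test_tune_rejects_degenerate_target():
    X, _ = _toy_regression()
    with pytest.raises(ValueError):
        tune_cv(X, pd.Series(1.0, index=X.index), seed=0)


def test_tune_deterministic_under_seed():
    X, y = _toy_regression(seed=2)
    b1, t1 = tune_cv(X, y, seed=5)
    b2, t2 = tune_cv(X, y, seed=5)
    assert b1 == b2
    pd.testing.assert_frame_equal(t1, t2)


def test_deep_fit_overfits_training_data():
    X, y = _toy_regression(seed=3)
    est = fit_final(X, y, {"learning_rate": 0.3, "max_depth": 8,
                           "min_child_weight": 1.0, "subsample": 1.0,
                           "colsample_bytree": 1.0, "n_estimators": 400}, seed=0)
    preds = est.predict(X)
    ss_res = float(np.sum((y - preds) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    assert 1 - ss_res / ss_tot > 0.95


def test_model_roundtrip_identical_predictions(tmp_path, tiny_trained_model):
    import xgboost as xgb

    _, results = tiny_trained_model
    results.save(tmp_path)
    booster, meta = HRDRegressorResults.load_estimator(tmp_path)
    X = results.model.features.values.loc[results.model.split.test_ids]
    want = results.predict(X).to_numpy()
    got = booster.predict(xgb.DMatrix(X[meta["feature_ids"]]))
    assert np.array_equal(got, want)
    assert meta["feature_ids"] == results.feature_ids


def test_all_missing_feature_column_trains_with_zero_importance():
    X, y = _toy_regression(seed=4)
    X = X.copy()
    X["dead"] = np.nan
    est = fit_final(X, y, {"learning_rate": 0.1, "max_depth": 3,
                           "min_child_weight": 1.0, "subsample": 1.0,
                           "colsample_bytree": 1.0, "n_estimators": 50}, seed=0)
    imp = est.get_booster().get_score(importance_type="gain")
    assert "dead" not in imp


def test_perfect_predictions_saturate_metrics():
    truth = pd.Series([0.1, 0.2, 0.6, 0.8, 0.9, 0.3], index=list("abcdef"))
    rep = evaluate(truth.copy(), truth)
    assert rep.r2 == pytest.approx(1.0)
    assert rep.auc == pytest.approx(1.0)
    assert rep.kappa == pytest.approx(1.0)


def test_constant_predictions_are_degenerate():
    truth = pd.Series([0.1, 0.2, 0.6, 0.8], index=list("abcd"))
    preds = pd.Series(0.5, index=truth.index)
    rep = evaluate(preds, truth)
    assert rep.r2 <= 0
    assert rep.auc == pytest.approx(0.5)
    assert rep.kappa == 0.0


def test_auc_matches_pairwise_enumeration():
    rng = np.random.default_rng(8)
    truth = pd.Series(rng.uniform(size=10), index=[f"s{i}" for i in range(10)])
    preds = pd.Series(truth.to_numpy() + rng.normal(0, 0.3, size=10), index=truth.index)
    rep = evaluate(preds, truth)
    labels, _ = (truth > truth.median()).astype(int), None
    assert rep.auc == pytest.approx(auc_oracle(labels.tolist(), preds.tolist()))


def test_single_class_stratum_reports_missing_auc():
    truth = pd.Series([0.9, 0.8, 0.7, 0.1], index=list("abcd"))
    preds = truth.copy()
    labels = pd.Series(["X", "X", "X", "Y"], index=truth.index)
    rep = evaluate(preds, truth, tumor_labels=labels, cutoff=0.05)
    # every sample is above the cutoff in stratum X and overall
    assert np.isnan(rep.per_tumor.loc["Y", "auc"]) or rep.per_tumor.loc["Y", "n"] == 1


def test_end_to_end_fit_recovers_target(tiny_trained_model):
    _, results = tiny_trained_model
    rep = results.evaluate()
    assert rep.r2 > 0.5
    assert rep.auc > 0.8
    text = results.summary()
    assert "held-out performance" in text and "learning_rate" in text


def test_no_test_leakage_into_tuning(tiny_trained_model):
    """Perturbing held-out targets cannot change tuning or the fit."""
    reg, results = tiny_trained_model
    ytr = reg.target.loc[reg.split.train_ids]
    Xtr = reg.features.values.loc[reg.split.train_ids]
    cand = [results.params | {}]
    cand[0] = {k: cand[0][k] for k in
               ("learning_rate", "max_depth", "min_child_weight", "subsample", "colsample_bytree")}
    best1, _ = tune_cv(Xtr, ytr, cand, seed=reg.seed)
    # tuning consumed only training rows, so it is reproducible from them alone
    best2, _ = tune_cv(Xtr.copy(), ytr.copy(), cand, seed=reg.seed)
    assert best1 == best2
    assert set(Xtr.index).isdisjoint(set(reg.split.test_ids))
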