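"""Attribution correctness: Shapley oracle, additivity, clustering, ablation."""

import numpy as np
import pandas as pd
import pytest
import xgboost as xgb
from _oracles import brute_force_shapley

from panhrd.explain import (
    cluster_with_bootstrap,
    shap_feature_correlation,
    shap_importance,
    shap_matrix,
    topn_ablation,
    waterfall_export,
)


def _single_tree_model(n_features=3, depth=2, seed=0, n=400):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, n_features)),
        columns=[f"f{i}" for i in range(n_features)],
    )
    y = (X["f0"] > 0).astype(float) + 0.5 * (X["f1"] > 0.3).astype(float)
    est = xgb.XGBRegressor(
        n_estimators=1, max_depth=depth, learning_rate=1.0,
        tree_method="exact", base_score=0.5, n_jobs=1, random_state=seed,
    )
    est.fit(X, y)
    return est, X


@pytest.mark.parametrize("n_features,depth", [(2, 1), (3, 2)])
def test_tree_shap_equals_coalition_enumeration(n_features, depth):
    """Exact TreeSHAP equals brute-force Shapley values on small trees."""
    est, X = _single_tree_model(n_features=n_features, depth=depth)
    booster = est.get_booster()
    dm = xgb.DMatrix(X, feature_names=list(X.columns))
    contribs = booster.predict(dm, pred_contribs=True)
    for i in [0, 17, 101]:
        phi = brute_force_shapley(booster, X.iloc[i], list(X.columns))
        for j, f in enumerate(X.columns):
            # TreeSHAP contributions exclude the learner's base_score offset,
            # which sits in the bias column together with the tree's expectation
            assert contribs[i, j] == pytest.approx(phi[f], abs=1e-5)


def test_additivity_and_null_player(tiny_trained_model):
    _, results = tiny_trained_model
    shap = shap_matrix(results)
    X = results.model.features.values.loc[results.model.split.test_ids]
    raw = results.predict(X)
    recon = shap.predictions()
    assert np.allclose(recon, raw, rtol=1e-3, atol=1e-5)
    # features never split on have identically zero SHAP columns
    used = set(results.estimator.get_booster().get_score(importance_type="weight"))
    unused = [f for f in results.feature_ids if f not in used]
    if unused:
        assert (shap.values[unused].abs().to_numpy() == 0).all()


def test_shap_matrix_rejects_missing_features(tiny_trained_model):
    _, results = tiny_trained_model
    X = results.model.features.values.iloc[:5, :3]
    with pytest.raises(ValueError):
        shap_matrix(results, X)


@pytest.mark.parametrize(
    "column,expected",
    [([1.0, -1.0, 1.0], 1.0), ([0.0, 0.0, 0.0], 0.0)],
)
def test_importance_is_mean_absolute(column, expected):
    df = pd.DataFrame({"f": column})
    assert shap_importance(df)["f"] == pytest.approx(expected)


def test_importance_homogeneity_and_stable_ties():
    df = pd.DataFrame({"b": [1.0, 1.0], "a": [1.0, 1.0], "c": [2.0, 2.0]})
    imp = shap_importance(df)
    assert imp["c"] == 2 * imp["a"]
    assert list(imp.index) == ["c", "a", "b"]  # ties broken by feature ID


def test_correlation_heatmap_signs_and_missing():
    idx = [f"s{i}" for i in range(6)]
    vals = pd.DataFrame({"f": np.arange(6.0), "g": np.arange(6.0), "h": np.arange(6.0)}, index=idx)
    shap = pd.DataFrame({"f": np.arange(6.0), "g": -np.arange(6.0), "h": np.zeros(6)}, index=idx)
    heat = shap_feature_correlation(shap, vals, tumor_labels=pd.Series("T", index=idx))
    assert heat.loc["T", "f"] == pytest.approx(1.0)
    assert heat.loc["T", "g"] == pytest.approx(-1.0)
    assert np.isnan(heat.loc["T", "h"])  # constant SHAP column -> missing, not 0


def test_correlation_small_tumor_flagged_missing():
    idx = ["a", "b", "c", "d"]
    vals = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0]}, index=idx)
    shap = vals.copy()
    labels = pd.Series(["big", "big", "big", "tiny"], index=idx)
    heat = shap_feature_correlation(shap, vals, tumor_labels=labels)
    assert np.isnan(heat.loc["tiny", "f"])


def test_bootstrap_supports_planted_row_clusters():
    """Two orthogonal row patterns, duplicated: both 2-leaf clusters near-certain."""
    rng = np.random.default_rng(0)
    a = np.r_[np.ones(10), np.zeros(10)]
    b = np.r_[np.zeros(10), np.ones(10)]
    heat = pd.DataFrame(
        [a + 0.01 * rng.normal(size=20), a + 0.01 * rng.normal(size=20),
         b + 0.01 * rng.normal(size=20), b + 0.01 * rng.normal(size=20)],
        index=["a1", "a2", "b1", "b2"],
    )
    res = cluster_with_bootstrap(heat, B=100, seed=1)
    assert res.support[("a1", "a2")] >= 0.95
    assert res.support[("b1", "b2")] >= 0.95


def test_bootstrap_single_replicate_support_binary():
    heat = pd.DataFrame(np.eye(3), index=list("xyz"))
    res = cluster_with_bootstrap(heat, B=1, seed=0)
    assert set(res.support.values()) <= {0.0, 1.0}


def test_identical_rows_cluster_without_error():
    heat = pd.DataFrame(np.ones((4, 5)), index=list("pqrs"))
    res = cluster_with_bootstrap(heat, B=10, seed=0)
    assert len(res.support) == 3  # n-1 internal nodes, all computed


def test_cluster_input_validation():
    with pytest.raises(ValueError):
        cluster_with_bootstrap(pd.DataFrame([[1.0]]), B=10)
    with pytest.raises(ValueError):
        cluster_with_bootstrap(pd.DataFrame(np.eye(2)), B=0)


def test_ablation_full_set_is_bitexact_and_zero_importance_masking_is_noop(tiny_trained_model):
    _, results = tiny_trained_model
    X = results.model.features.values.loc[results.model.split.test_ids]
    full_preds = results.predict(X)
    n_feat = len(results.feature_ids)
    shap = shap_matrix(results, X)
    imp = shap_importance(shap)
    tab = topn_ablation(results, X, n_grid=[n_feat], importance=imp)
    masked_preds = results.predict(X)  # N = all masks nothing
    assert np.array_equal(full_preds.to_numpy(), masked_preds.to_numpy())
    # masking only zero-importance features changes nothing
    zero_imp = [f for f in results.feature_ids if imp[f] == 0.0]
    if zero_imp:
        Xz = X.copy()
        Xz[zero_imp] = np.nan
        assert np.allclose(results.predict(Xz), full_preds, atol=1e-7)
    assert tab.loc[0, "N"] == n_feat


def test_ablation_zero_features_constant_default_path(tiny_trained_model):
    _, results = tiny_trained_model
    X = results.model.features.values.loc[results.model.split.test_ids]
    all_nan = X.copy()
    all_nan[:] = np.nan
    preds = results.predict(all_nan)
    assert preds.nunique() == 1


def test_ablation_metric_improves_with_more_features(tiny_trained_model):
    from scipy.stats import spearmanr

    _, results = tiny_trained_model
    tab = topn_ablation(results)
    rho = spearmanr(tab["N"], tab["kappa"]).statistic
    assert rho >= 0.8


def test_ablation_overlong_n_clamped(tiny_trained_model):
    _, results = tiny_trained_model
    with pytest.warns(RuntimeWarning):
        tab = topn_ablation(results, n_grid=[10_000])
    assert tab.loc[0, "N"] == len(results.feature_ids)


def test_waterfall_sums_to_prediction_minus_base():
    shap_row = pd.Series({"a": 0.3, "b": -0.2, "c": 0.05, "d": 0.0})
    vals = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
    full = waterfall_export(shap_row, vals, top_k=4)
    assert full["shap"].sum() == pytest.approx(shap_row.sum())
    top1 = waterfall_export(shap_row, vals, top_k=1)
    assert list(top1["feature"]) == ["a", "other"]
    assert top1["shap"].sum() == pytest.approx(shap_row.sum())
    empty = waterfall_export(pd.Series({"a": 0.0}), pd.Series({"a": 1.0}), top_k=1)
    assert empty["shap"].sum() == pytest.approx(0.0)
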