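"""SHAP-based interpretation of the fitted HRD regression model.

Per-sample attributions come from exact TreeSHAP on the boosted-tree
ensemble (computed on the raw margin scale, where additivity is exact):
for every scored row, the attributions plus the base value reproduce the
model's prediction. On top of the attribution matrix the module provides
global importance (mean |SHAP| per feature), per-tumor correlation between
feature values and their SHAP values, hierarchical clustering of that
correlation heatmap with ordinary-bootstrap node support, top-N feature
ablation via the booster's native missing-value routing, and per-sample
waterfall exports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.stats import pearsonr, spearmanr

from panhrd.model import HRDRegressorResults, evaluate


@dataclass
class ShapMatrix:
    """Samples x features SHAP values with the base value and the aligned
    feature values; row sums + base reproduce raw predictions."""

    values: pd.DataFrame
    base_value: float
    feature_values: pd.DataFrame = field(repr=False, default=None)

    def predictions(self) -> pd.Series:
        return self.values.sum(axis=1) + self.base_value


def shap_matrix(results: HRDRegressorResults, X: pd.DataFrame | None = None) -> ShapMatrix:
    """Exact tree-path SHAP attribution for every row of ``X``.

    Defaults to the model's held-out test rows. Features never used by any
    tree receive identically zero columns (null-player property).
    """
    if X is None:
        X = results.model.features.values.loc[results.model.split.test_ids]
    feats = results.feature_ids
    missing = [f for f in feats if f not in X.columns]
    if missing:
        raise ValueError(f"feature(s) absent from input: {missing[:5]}")
    X = X[feats]
    dm = xgb.DMatrix(X, feature_names=list(map(str, feats)))
    contrib = results.estimator.get_booster().predict(dm, pred_contribs=True)
    values = pd.DataFrame(contrib[:, :-1], index=X.index, columns=feats)
    base = float(contrib[0, -1])
    return ShapMatrix(values=values, base_value=base, feature_values=X)


def shap_importance(shap: ShapMatrix | pd.DataFrame) -> pd.Series:
    """Global importance: mean absolute SHAP value per feature.

    Returned sorted descending; ties keep a stable order by feature ID so
    rankings are reproducible.
    """
    values = shap.values if isinstance(shap, ShapMatrix) else shap
    if values.shape[0] == 0:
        raise ValueError("empty SHAP matrix")
    imp = values.abs().mean(axis=0)
    order = sorted(imp.index, key=lambda f: (-imp[f], str(f)))
    return imp.loc[order].rename("importance")


def shap_feature_correlation(
    shap: ShapMatrix | pd.DataFrame,
    feature_values: pd.DataFrame | None = None,
    tumor_labels: pd.Series | None = None,
    method: str = "pearson",
    min_samples: int = 3,
) -> pd.DataFrame:
    """Per-tumor correlation between feature values and their SHAP values.

    Returns a tumors x features matrix; entries are NaN where either
    column is constant or the tumor has fewer than ``min_samples`` test
    samples (flagged missing rather than forced to 0).
    """
    if isinstance(shap, ShapMatrix):
        feature_values = shap.feature_values if feature_values is None else feature_values
        shap = shap.values
    if feature_values is None:
        raise ValueError("feature_values required")
    if tumor_labels is None:
        tumor_labels = pd.Series("ALL", index=shap.index)
    corr_fn = pearsonr if method == "pearson" else spearmanr
    labels = pd.Series(tumor_labels).loc[shap.index]
    rows = {}
    for t, ids in labels.groupby(labels).groups.items():
        row = {}
        for f in shap.columns:
            s = shap.loc[ids, f].to_numpy(dtype=float)
            v = feature_values.loc[ids, f].to_numpy(dtype=float)
            ok = np.isfinite(s) & np.isfinite(v)
            s, v = s[ok], v[ok]
            if len(s) < min_samples or np.std(s) == 0 or np.std(v) == 0:
                row[f] = np.nan
            else:
                row[f] = float(corr_fn(v, s)[0])
        rows[t] = row
    return pd.DataFrame.from_dict(rows, orient="index")[list(shap.columns)]


def _internal_leaf_sets(link: np.ndarray, labels: list) -> list[frozenset]:
    """Leaf-label sets of every internal node of a scipy linkage tree."""
    tree = to_tree(link)
    sets = []

    def rec(node):
        if node.is_leaf():
            return frozenset([labels[node.id]])
        s = rec(node.left) | rec(node.right)
        sets.append(s)
        return s

    rec(tree)
    return sets


@dataclass
class ClusterResult:
    row_linkage: np.ndarray
    col_linkage: np.ndarray | None
    support: dict  # internal-node leaf set (as sorted tuple) -> bootstrap support
    row_order: list


def cluster_with_bootstrap(
    heatmap: pd.DataFrame, B: int = 100, seed: int = 0, method: str = "average"
) -> ClusterResult:
    """Hierarchical clustering of heatmap rows with bootstrap node support.

    Missing entries are imputed with the column median (all-missing
    columns with 0). Rows are clustered with average linkage on Euclidean
    distance; ``B`` bootstrap replicates resample columns with
    replacement, and each internal node's support is the fraction of
    replicate dendrograms containing the same leaf set.
    """
    if heatmap.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    if B < 1:
        raise ValueError("B must be >= 1")
    filled = heatmap.apply(lambda c: c.fillna(c.median()), axis=0).fillna(0.0)
    arr = filled.to_numpy(dtype=float)
    labels = list(heatmap.index)
    link = linkage(arr, method=method, metric="euclidean")
    col_link = (
        linkage(arr.T, method=method, metric="euclidean") if arr.shape[1] >= 2 else None
    )
    original = _internal_leaf_sets(link, labels)
    counts = {s: 0 for s in original}
    rng = np.random.default_rng(seed)
    p = arr.shape[1]
    for _ in range(B):
        cols = rng.integers(0, p, size=p)
        blink = linkage(arr[:, cols], method=method, metric="euclidean")
        bsets = set(_internal_leaf_sets(blink, labels))
        for s in original:
            if s in bsets:
                counts[s] += 1
    support = {tuple(sorted(map(str, s))): counts[s] / B for s in original}
    order = list(pd.DataFrame(arr, index=labels).index[_leaf_order(link)])
    return ClusterResult(row_linkage=link, col_linkage=col_link, support=support, row_order=order)


def _leaf_order(link: np.ndarray) -> list[int]:
    from scipy.cluster.hierarchy import leaves_list

    return list(leaves_list(link))


def topn_ablation(
    results: HRDRegressorResults,
    X: pd.DataFrame | None = None,
    truth: pd.Series | None = None,
    n_grid: list | None = None,
    importance: pd.Series | None = None,
    cutoff: float | None = None,
) -> pd.DataFrame:
    """Re-predict with only the top-N features visible, for each N.

    Features outside the top N (ranked by mean |SHAP|) are set to NaN and
    routed by the booster's default directions, so N = number of features
    reproduces the full-model predictions exactly. Reports Cohen's kappa
    and R-squared against the true score at the cohort-median cutoff.
    """
    if X is None:
        X = results.model.features.values.loc[results.model.split.test_ids]
    if truth is None:
        truth = results.model.target.loc[X.index]
    if cutoff is None:
        cutoff = float(np.median(results.model.target))
    if importance is None:
        importance = shap_importance(shap_matrix(results, X))
    feats = results.feature_ids
    ranked = list(importance.index)
    n_feat = len(feats)
    if n_grid is None:
        n_grid = [n for n in (1, 5, 10, 50, 100, 500) if n < n_feat] + [n_feat]
    rows = []
    for n in n_grid:
        n_eff = n_feat if (n == "all" or n is None) else int(n)
        if n_eff > n_feat:
            warnings.warn(f"N={n_eff} exceeds {n_feat} features; clamped", RuntimeWarning)
            n_eff = n_feat
        keep = set(ranked[:n_eff])
        masked = X.copy()
        drop = [f for f in feats if f not in keep]
        masked[drop] = np.nan
        preds = results.predict(masked)
        rep = evaluate(preds, truth, cutoff=cutoff)
        rows.append({"N": n_eff, "kappa": rep.kappa, "r2": rep.r2, "rmse": rep.rmse})
    return pd.DataFrame(rows)


def waterfall_export(
    shap_row: pd.Series, feature_values: pd.Series, top_k: int = 10
) -> pd.DataFrame:
    """Ordered per-sample contribution table for waterfall plotting.

    The top ``top_k`` features by |SHAP| are listed individually with their
    observed values; the remainder is aggregated as an ``other`` row, so
    the ``shap`` column always sums to prediction minus base value.
    """
    nonzero = shap_row[shap_row != 0.0]
    order = sorted(nonzero.index, key=lambda f: (-abs(nonzero[f]), str(f)))
    top = order[: int(top_k)]
    rows = [
        {"feature": f, "value": feature_values.get(f, np.nan), "shap": float(shap_row[f])}
        for f in top
    ]
    rest = float(shap_row.sum() - sum(r["shap"] for r in rows))
    rows.append({"feature": "other", "value": np.nan, "shap": rest})
    return pd.DataFrame(rows)
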