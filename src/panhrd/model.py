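"""Gradient-boosted regression of the HRD score on multi-omics features.

Follows the model/results idiom: :class:`HRDRegressor` is built from a
feature table and a target score (plus tumor labels for stratification);
``fit()`` tunes hyperparameters by 5-fold cross-validated RMSE over a
random search space, trains the final booster on the full training split,
and returns :class:`HRDRegressorResults` carrying the fitted ensemble,
evaluation metrics and a ``summary()`` table.

The cohort is split 80/20 stratified by tumor type; feature z-scaling
statistics come from the training rows only; missing feature values are
routed by the booster's native default-direction mechanism.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import cohen_kappa_score, mean_squared_error, r2_score, roc_auc_score
from sklearn.model_selection import KFold

from panhrd.preprocess import FeatureTable, zscale
from panhrd.scoring import discretize_by_median


@dataclass
class SplitPlan:
    """Train/test membership, stratified by tumor type."""

    train_ids: pd.Index
    test_ids: pd.Index
    tumor_labels: pd.Series
    fraction: float = 0.8
    cv_folds: int = 5
    seed: int = 0


def stratified_split(
    sample_ids,
    tumor_labels: pd.Series,
    fraction: float = 0.8,
    seed: int = 0,
    cv_folds: int = 5,
) -> SplitPlan:
    """Per-tumor random split at the given training fraction.

    Within each tumor type, ``round(fraction * n)`` samples go to train
    (at least one); tumor types with a single sample go entirely to train.
    """
    sample_ids = pd.Index(sample_ids)
    if len(sample_ids) == 0:
        raise ValueError("empty cohort")
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    labels = pd.Series(tumor_labels).loc[sample_ids]
    rng = np.random.default_rng(seed)
    train, test = [], []
    for _, ids in labels.groupby(labels, sort=True).groups.items():
        ids = list(ids)
        rng.shuffle(ids)
        n_train = max(1, int(round(fraction * len(ids))))
        train.extend(ids[:n_train])
        test.extend(ids[n_train:])
    return SplitPlan(
        train_ids=pd.Index(train),
        test_ids=pd.Index(test),
        tumor_labels=labels,
        fraction=fraction,
        cv_folds=cv_folds,
        seed=seed,
    )


def sample_search_space(n_candidates: int = 20, seed: int = 0) -> list[dict]:
    """Random draws over the default hyperparameter search space.

    Learning rate log-uniform on [0.01, 0.3]; max depth 3-8; min child
    weight 1-10; row and column subsampling 0.6-1.0. The number of
    boosting rounds is not drawn: it is set per candidate by early
    stopping on the cross-validation folds.
    """
    rng = np.random.default_rng(seed)
    cands = []
    for _ in range(n_candidates):
        cands.append(
            {
                "learning_rate": float(np.exp(rng.uniform(np.log(0.01), np.log(0.3)))),
                "max_depth": int(rng.integers(3, 9)),
                "min_child_weight": float(rng.integers(1, 11)),
                "subsample": float(rng.uniform(0.6, 1.0)),
                "colsample_bytree": float(rng.uniform(0.6, 1.0)),
            }
        )
    return cands


_FIXED_PARAMS = {
    "objective": "reg:squarederror",
    "tree_method": "hist",
    "n_jobs": 1,
    "verbosity": 0,
}
_MAX_ROUNDS = 1000
_EARLY_STOP = 30


def tune_cv(
    X: pd.DataFrame,
    y: pd.Series,
    candidates: list[dict] | None = None,
    seed: int = 0,
    cv_folds: int = 5,
) -> tuple[dict, pd.DataFrame]:
    """5-fold cross-validated RMSE selection over candidate hyperparameters.

    Each candidate trains with up to 1,000 boosting rounds and early
    stopping on the held-out fold; its score is the mean best RMSE across
    folds and its round count the mean best iteration. The winner is the
    candidate with the lowest mean RMSE; ties break toward fewer boosting
    rounds, then lower learning rate, then draw order.
    """
    if float(np.var(np.asarray(y, dtype=float))) == 0.0:
        raise ValueError("target has zero variance; nothing to tune")
    if candidates is None:
        candidates = sample_search_space(seed=seed)
    if len(X) < cv_folds:
        raise ValueError(f"need at least {cv_folds} training samples")
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(kf.split(X))
    rows = []
    for idx, params in enumerate(candidates):
        rmses, best_iters = [], []
        for tr, va in folds:
            est = xgb.XGBRegressor(
                n_estimators=_MAX_ROUNDS,
                early_stopping_rounds=_EARLY_STOP,
                random_state=seed,
                **_FIXED_PARAMS,
                **params,
            )
            est.fit(
                X.iloc[tr], y.iloc[tr],
                eval_set=[(X.iloc[va], y.iloc[va])],
                verbose=False,
            )
            rmses.append(float(est.best_score))
            best_iters.append(int(est.best_iteration) + 1)
        rows.append(
            {
                "candidate": idx,
                **params,
                "cv_rmse": float(np.mean(rmses)),
                "n_estimators": int(round(np.mean(best_iters))),
            }
        )
    table = pd.DataFrame(rows)
    order = table.sort_values(
        ["cv_rmse", "n_estimators", "learning_rate", "candidate"]
    ).index
    best_row = table.loc[order[0]]
    best = {k: best_row[k] for k in candidates[0]}
    best["max_depth"] = int(best["max_depth"])
    best["n_estimators"] = int(best_row["n_estimators"])
    return best, table


def fit_final(X: pd.DataFrame, y: pd.Series, params: dict, seed: int = 0) -> xgb.XGBRegressor:
    """Train the final booster on the entire training split."""
    if list(X.index) != list(y.index):
        raise ValueError("feature/target sample IDs do not match")
    est = xgb.XGBRegressor(random_state=seed, **_FIXED_PARAMS, **params)
    est.fit(X, y, verbose=False)
    return est


@dataclass
class EvalReport:
    """Regression and thresholded-classification metrics."""

    r2: float
    rmse: float
    auc: float
    kappa: float
    sensitivity: float
    specificity: float
    precision: float
    cutoff: float
    per_tumor: pd.DataFrame

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "r2": self.r2,
                "rmse": self.rmse,
                "auc": self.auc,
                "kappa": self.kappa,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "precision": self.precision,
                "cutoff": self.cutoff,
            }
        )


def evaluate(
    predictions: pd.Series,
    truth: pd.Series,
    tumor_labels: pd.Series | None = None,
    cutoff: float | None = None,
) -> EvalReport:
    """Score continuous predictions against the true HRD score.

    Binary ground truth comes from thresholding the TRUE score at the
    supplied cutoff (by default, the median of ``truth``); the predicted
    score is the ranking statistic for AUC, and the same cutoff applied to
    predictions yields the kappa / sensitivity / specificity / precision
    operating point. Strata with a single truth class get a missing AUC.
    """
    if len(truth) == 0:
        raise ValueError("empty evaluation set")
    predictions = predictions.loc[truth.index]
    true_labels, cutoff = discretize_by_median(truth, cutoff=cutoff)
    pred_labels, _ = discretize_by_median(predictions, cutoff=cutoff)
    r2 = r2_score(truth, predictions)
    rmse = float(np.sqrt(mean_squared_error(truth, predictions)))

    def _auc(yt, yp):
        if len(np.unique(yt)) < 2:
            return np.nan
        return float(roc_auc_score(yt, yp))

    auc = _auc(true_labels, predictions)
    if np.isnan(auc):
        warnings.warn("single-class truth: AUC undefined", RuntimeWarning, stacklevel=2)
    if true_labels.nunique() < 2 and pred_labels.nunique() < 2:
        kappa = 0.0
    else:
        kappa = float(cohen_kappa_score(true_labels, pred_labels))
    tp = int(((true_labels == 1) & (pred_labels == 1)).sum())
    fn = int(((true_labels == 1) & (pred_labels == 0)).sum())
    tn = int(((true_labels == 0) & (pred_labels == 0)).sum())
    fp = int(((true_labels == 0) & (pred_labels == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    prec = tp / (tp + fp) if tp + fp else np.nan

    per_tumor = pd.DataFrame(columns=["n", "positive_fraction", "auc"])
    if tumor_labels is not None:
        rows = {}
        labs = pd.Series(tumor_labels).loc[truth.index]
        for t, ids in labs.groupby(labs).groups.items():
            yt = true_labels.loc[ids]
            a = _auc(yt, predictions.loc[ids])
            rows[t] = {
                "n": len(ids),
                "positive_fraction": float(yt.mean()),
                "auc": a,
            }
        per_tumor = pd.DataFrame.from_dict(rows, orient="index")
    return EvalReport(
        r2=float(r2), rmse=rmse, auc=auc, kappa=kappa,
        sensitivity=sens, specificity=spec, precision=prec,
        cutoff=float(cutoff), per_tumor=per_tumor,
    )


class HRDRegressor:
    """Boosted-tree regression model of an HRD score on omics features.

    Parameters
    ----------
    features
        Unscaled :class:`~panhrd.preprocess.FeatureTable` or DataFrame
        (samples x features).
    target
        True HRD score per sample (the regression target).
    tumor_labels
        Tumor type per sample, used for split stratification and per-tumor
        evaluation.
    split
        Optional pre-computed :class:`SplitPlan`; by default an 80/20
        stratified split is drawn from ``seed``.
    scale
        If True (default), z-scale features with train-only statistics.
    """

    def __init__(
        self,
        features: FeatureTable | pd.DataFrame,
        target: pd.Series,
        tumor_labels: pd.Series | None = None,
        split: SplitPlan | None = None,
        scale: bool = True,
        seed: int = 0,
    ) -> None:
        table = features if isinstance(features, FeatureTable) else FeatureTable(values=features)
        self.target = target.loc[table.sample_ids]
        if tumor_labels is None:
            tumor_labels = pd.Series("ALL", index=table.sample_ids)
        self.tumor_labels = pd.Series(tumor_labels).loc[table.sample_ids]
        self.seed = seed
        self.split = split or stratified_split(
            table.sample_ids, self.tumor_labels, seed=seed
        )
        if scale:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                table = zscale(table, self.split.train_ids)
        self.features = table

    @classmethod
    def from_dataframes(
        cls,
        features: pd.DataFrame,
        target: pd.Series,
        tumor_labels: pd.Series | None = None,
        **kwargs,
    ) -> "HRDRegressor":
        return cls(FeatureTable(values=features), target, tumor_labels, **kwargs)

    def fit(
        self,
        candidates: list[dict] | None = None,
        n_candidates: int = 20,
        seed: int | None = None,
    ) -> "HRDRegressorResults":
        """Tune by cross-validated RMSE, then fit on the full training split."""
        seed = self.seed if seed is None else seed
        Xtr = self.features.values.loc[self.split.train_ids]
        ytr = self.target.loc[self.split.train_ids]
        if candidates is None:
            candidates = sample_search_space(n_candidates=n_candidates, seed=seed)
        best, cv_table = tune_cv(Xtr, ytr, candidates, seed=seed, cv_folds=self.split.cv_folds)
        booster = fit_final(Xtr, ytr, best, seed=seed)
        return HRDRegressorResults(
            model=self, estimator=booster, params=best, cv_table=cv_table
        )


@dataclass
class HRDRegressorResults:
    """Fitted boosted-tree ensemble with its tuning and evaluation record."""

    model: HRDRegressor
    estimator: xgb.XGBRegressor
    params: dict
    cv_table: pd.DataFrame = field(repr=False, default=None)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.model.features.feature_ids)

    @property
    def base_value(self) -> float:
        """Expected model output (the bias term of the attribution)."""
        dm = xgb.DMatrix(
            self.model.features.values.loc[self.model.split.train_ids].iloc[:1]
        )
        contrib = self.estimator.get_booster().predict(dm, pred_contribs=True)
        return float(contrib[0, -1])

    def predict(self, X: pd.DataFrame | None = None) -> pd.Series:
        if X is None:
            X = self.model.features.values.loc[self.model.split.test_ids]
        raw = self.estimator.predict(X[self.feature_ids])
        return pd.Series(raw, index=X.index, name="panHRD_pred")

    def evaluate(self, cutoff: float | None = None, on: str = "test") -> EvalReport:
        """Held-out evaluation; the default cutoff is the median of the
        true score over the full cohort (the operating point used for all
        discretized metrics)."""
        ids = self.model.split.test_ids if on == "test" else self.model.split.train_ids
        if cutoff is None:
            cutoff = float(np.median(self.model.target))
        preds = self.predict(self.model.features.values.loc[ids])
        return evaluate(
            preds, self.model.target.loc[ids],
            tumor_labels=self.model.tumor_labels.loc[ids], cutoff=cutoff,
        )

    def summary(self) -> str:
        rep = self.evaluate()
        lines = [
            "HRD score regression (gradient-boosted trees)",
            "=" * 52,
            f"n train / test: {len(self.model.split.train_ids)} / {len(self.model.split.test_ids)}",
            f"features: {len(self.feature_ids)}",
            "tuned hyperparameters:",
        ]
        for k, v in self.params.items():
            lines.append(f"  {k:>18}: {v:.4g}" if isinstance(v, float) else f"  {k:>18}: {v}")
        lines.append("held-out performance (cutoff = cohort median of true score):")
        for k, v in rep.to_series().items():
            lines.append(f"  {k:>18}: {v:.4f}")
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        """Persist booster (native JSON) plus a sidecar with feature order,
        split membership, scaling statistics and tuned hyperparameters."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.estimator.get_booster().save_model(str(out / "model.json"))
        ft = self.model.features
        sidecar = {
            "feature_ids": self.feature_ids,
            "params": self.params,
            "seed": self.model.seed,
            "train_ids": list(map(str, self.model.split.train_ids)),
            "test_ids": list(map(str, self.model.split.test_ids)),
            "scale_means": None if ft.scale_means is None else ft.scale_means.to_dict(),
            "scale_sds": None if ft.scale_sds is None else ft.scale_sds.to_dict(),
        }
        (out / "model_meta.json").write_text(json.dumps(sidecar, indent=1))

    @staticmethod
    def load_estimator(out_dir: str | Path) -> tuple[xgb.Booster, dict]:
        """Reload the serialized booster and its sidecar metadata."""
        out = Path(out_dir)
        booster = xgb.Booster()
        booster.load_model(str(out / "model.json"))
        meta = json.loads((out / "model_meta.json").read_text())
        return booster, meta
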