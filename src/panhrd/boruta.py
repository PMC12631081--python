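"""All-relevant feature selection with shadow features (Boruta).

Each iteration appends a shuffled "shadow" copy of every active feature,
fits a random-forest regressor on the extended matrix, and credits a
feature with a hit when its importance strictly exceeds the best shadow
importance. Accumulated hits are tested against Binomial(n_iter, 1/2) with
a two-sided binomial test, Bonferroni-corrected over the features still in
play: significantly more hits than chance confirms a feature,
significantly fewer rejects it (and drops it from later forests). The
shadow pool always spans every original feature, so the max-shadow bar
does not fall as features are rejected. The loop stops when nothing is
left undecided or after ``max_iterations``; undecided features are
returned as tentative.

The forest runs in regression mode with impurity-based importances, since
the selection target here is a continuous HRD score. Splits consider a
single random candidate feature (``max_features=1``): greedy candidate
selection lets a tree reuse whichever feature happens to correlate best
with the target, amplifying its importance over fresh shadows and — under
a pure-noise target — driving false confirmations of the most spuriously
correlated feature. Random-candidate splits keep importances proportional
to each feature's marginal association, which preserves the recovery of
genuinely informative features while restoring type-I control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

logger = logging.getLogger(__name__)

CONFIRMED = "confirmed"
TENTATIVE = "tentative"
REJECTED = "rejected"


@dataclass
class BorutaConfig:
    max_iterations: int = 100
    alpha: float = 0.01
    correction: str = "bonferroni"
    n_trees: int = 100
    max_depth: int | None = 7
    max_features: str | float | int = 1  # single random candidate per split; see module docstring
    importance: str = "impurity"  # or "permutation"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")
        if self.correction not in {"bonferroni", "none"}:
            raise ValueError("correction must be 'bonferroni' or 'none'")
        if self.importance not in {"impurity", "permutation"}:
            raise ValueError("importance must be 'impurity' or 'permutation'")


@dataclass
class BorutaResult:
    """Per-feature decisions plus the evidence that produced them."""

    decisions: pd.Series  # feature -> confirmed | tentative | rejected
    hits: pd.Series  # feature -> number of iterations it beat all shadows
    importance_history: pd.DataFrame  # iterations x features (NaN once dropped)
    iterations_run: int

    @property
    def confirmed(self) -> list[str]:
        return list(self.decisions.index[self.decisions == CONFIRMED])

    @property
    def tentative(self) -> list[str]:
        return list(self.decisions.index[self.decisions == TENTATIVE])

    @property
    def rejected(self) -> list[str]:
        return list(self.decisions.index[self.decisions == REJECTED])


def _forest_importance(forest, X, y, kind: str, rng) -> np.ndarray:
    if kind == "impurity":
        return forest.feature_importances_
    res = permutation_importance(
        forest, X, y, n_repeats=5, random_state=rng.integers(2**31 - 1)
    )
    return res.importances_mean


def boruta_select(
    X: pd.DataFrame | np.ndarray,
    y: pd.Series | np.ndarray,
    config: BorutaConfig | None = None,
) -> BorutaResult:
    """Run the shadow-feature selection loop on one feature matrix.

    NaN entries are imputed with the column median for the forest (random
    forests have no native missing routing).
    """
    config = config or BorutaConfig()
    X = pd.DataFrame(X).copy()
    y = np.asarray(y, dtype=float)
    if X.shape[1] == 0:
        raise ValueError("X must have at least one feature")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    X.columns = X.columns.astype(str)
    if X.isna().any().any():
        X = X.fillna(X.median(axis=0))

    features = list(X.columns)
    rng = np.random.default_rng(config.seed)
    hits = pd.Series(0, index=features, dtype=int)
    decisions = pd.Series(TENTATIVE, index=features, dtype=object)
    history = []
    active = list(features)  # confirmed features keep competing; rejected drop out
    n_iter = 0

    Xall = X.to_numpy()
    for n_iter in range(1, config.max_iterations + 1):
        Xa = X[active].to_numpy()
        # Shadows are fresh permutations of EVERY original feature, not just
        # the active ones: shrinking the shadow pool as features are
        # rejected would lower the max-shadow bar and let spuriously
        # correlated survivors rack up hits under a null target.
        shadows = Xall.copy()
        for j in range(shadows.shape[1]):  # independent column-wise shuffles
            shadows[:, j] = rng.permutation(shadows[:, j])
        Xfull = np.hstack([Xa, shadows])
        forest = RandomForestRegressor(
            n_estimators=config.n_trees,
            max_depth=config.max_depth,
            max_features=config.max_features,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(Xfull, y)
        imp = _forest_importance(forest, Xfull, y, config.importance, rng)
        real_imp = imp[: len(active)]
        shadow_max = imp[len(active):].max()
        row = pd.Series(np.nan, index=features)
        row[active] = real_imp
        history.append(row)
        beat = np.array(real_imp) > shadow_max
        hits[np.array(active)[beat]] += 1

        undecided = [f for f in active if decisions[f] == TENTATIVE]
        # correct over ALL original features, not just the undecided ones: a
        # shrinking correction becomes anti-conservative late in the run and
        # lets lingering spuriously-correlated features reach confirmation
        bonf = len(features) if config.correction == "bonferroni" else 1
        newly_rejected = []
        for f in undecided:
            p = binomtest(int(hits[f]), n_iter, 0.5).pvalue * bonf
            if p < config.alpha:
                if hits[f] > n_iter / 2:
                    decisions[f] = CONFIRMED
                else:
                    decisions[f] = REJECTED
                    newly_rejected.append(f)
        if newly_rejected:
            active = [f for f in active if f not in set(newly_rejected)]
        if not (decisions == TENTATIVE).any() or not active:
            break

    hist = pd.DataFrame(history, index=pd.RangeIndex(1, n_iter + 1, name="iteration"))
    n_conf = int((decisions == CONFIRMED).sum())
    logger.info(
        "boruta: %d confirmed / %d rejected / %d tentative after %d iterations",
        n_conf, int((decisions == REJECTED).sum()),
        int((decisions == TENTATIVE).sum()), n_iter,
    )
    return BorutaResult(
        decisions=decisions, hits=hits, importance_history=hist, iterations_run=n_iter
    )


@dataclass
class PerLayerSelection:
    """Confirmed genes per omics layer with a per-layer summary table."""

    confirmed: dict[str, list[str]]
    results: dict[str, BorutaResult] = field(repr=False, default_factory=dict)
    summary: pd.DataFrame | None = None


def select_per_layer(
    bundle,
    scores,
    config: BorutaConfig | None = None,
    include_tentative: bool = False,
    sample_ids=None,
) -> PerLayerSelection:
    """Run Boruta independently on each omics layer against the HRD score.

    Parameters
    ----------
    bundle
        :class:`~panhrd.preprocess.OmicsBundle` (transformed or raw; raw
        layers are transformed first).
    scores
        :class:`~panhrd.scoring.ScoreResult` or a Series of target values
        indexed by sample ID.
    include_tentative
        If True, tentative features count as selected; by default only
        confirmed features go downstream.
    sample_ids
        Optional subset of samples to run the selection on (e.g., the
        training split, to keep held-out samples out of selection).
    """
    config = config or BorutaConfig()
    target = getattr(scores, "scores", scores)
    bundle = bundle.transformed() if hasattr(bundle, "transformed") else bundle
    confirmed: dict[str, list[str]] = {}
    results: dict[str, BorutaResult] = {}
    rows = []
    for i, (name, mat) in enumerate(bundle.layers.items()):
        ids = mat.index if sample_ids is None else pd.Index(sample_ids)
        Xl = mat.loc[ids]
        yl = target.loc[ids]
        layer_cfg = replace(config, seed=config.seed + i)
        res = boruta_select(Xl, yl, layer_cfg)
        keep = res.confirmed + (res.tentative if include_tentative else [])
        confirmed[name] = sorted(keep)
        results[name] = res
        rows.append(
            {
                "layer": name,
                "presented": mat.shape[1],
                "confirmed": len(res.confirmed),
                "selected": len(keep),
                "pct_selected": 100.0 * len(keep) / mat.shape[1],
            }
        )
    summary = pd.DataFrame(rows).set_index("layer")
    return PerLayerSelection(confirmed=confirmed, results=results, summary=summary)
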