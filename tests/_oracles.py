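"""Independent brute-force oracles used by the test suite.

Everything here is a deliberately naive transcription of the underlying
definitions (explicit loops, coalition enumeration, pairwise counting),
kept separate from the package's vectorized implementations so the two
routes stay independent.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd


def score_oracle(exposures, epsilon: float = 0.1) -> pd.Series:
    """Straight-line loop transcription of the aggregated-score chain.

    Normalize each class per sample, select SBS3 / ID6 / combined CN1-CN17 /
    scarHRD, compute inclusive-threshold weights per tumor type, rescale
    them to sum to one, and form the weighted sum.
    """
    labels = exposures.tumor_labels
    samples = list(labels.index)
    # plain-dict views so the transcription below is pure-python loops
    rows = {
        cls: exposures.classes[cls].to_dict(orient="index")
        for cls in ("SBS", "ID", "CN", "scarHRD")
    }

    # per-sample normalized selected exposures, one per class
    e_hat: dict[str, dict] = {k: {} for k in ("SBS", "ID", "CN", "scarHRD")}
    for cls, marker in (("SBS", "SBS3"), ("ID", "ID6")):
        for i in samples:
            row = rows[cls][i]
            total = sum(row.values())
            e_hat[cls][i] = row[marker] / total if total > 0 else 0.0
    for i in samples:
        row = rows["CN"][i]
        total = sum(row.values())
        cn1 = row["CN1"] / total if total > 0 else 0.0
        cn17 = row["CN17"] / total if total > 0 else 0.0
        e_hat["CN"][i] = ((1.0 - cn1) + cn17) / 2.0
    scar = {i: list(rows["scarHRD"][i].values())[0] for i in samples}
    mx = max(scar.values()) if scar else 0.0
    for i in samples:
        e_hat["scarHRD"][i] = scar[i] / mx if mx > 0 else 0.0

    # per-tumor weights with the inclusive indicator, then rescale
    scores = {}
    for t in sorted(set(labels)):
        members = [i for i in samples if labels.loc[i] == t]
        w = {}
        for cls in ("SBS", "ID", "CN", "scarHRD"):
            w[cls] = sum(1 for i in members if e_hat[cls][i] >= epsilon) / len(members)
        total_w = sum(w.values())
        if total_w == 0:
            w_hat = {cls: 0.25 for cls in w}
        else:
            w_hat = {cls: w[cls] / total_w for cls in w}
        for i in members:
            scores[i] = sum(w_hat[cls] * e_hat[cls][i] for cls in w_hat)
    return pd.Series(scores).loc[samples]


# ---------------------------------------------------------------------------
# brute-force Shapley values for xgboost tree ensembles


def _tree_cond_expectation(nodes: dict, node_id: str, x: dict, known: set) -> float:
    """E[f(x) | x_S] under the tree's cover-weighted path distribution."""
    node = nodes[node_id]
    if node["Feature"] == "Leaf":
        return float(node["Gain"])  # leaf value is stored in the Gain column
    feat = node["Feature"]
    if feat in known:
        val = x[feat]
        if val is None or (isinstance(val, float) and math.isnan(val)):
            nxt = node["Missing"]
        elif val < node["Split"]:
            nxt = node["Yes"]
        else:
            nxt = node["No"]
        return _tree_cond_expectation(nodes, nxt, x, known)
    cl, cr = nodes[node["Yes"]]["Cover"], nodes[node["No"]]["Cover"]
    wl = cl / (cl + cr)
    return wl * _tree_cond_expectation(nodes, node["Yes"], x, known) + (
        1 - wl
    ) * _tree_cond_expectation(nodes, node["No"], x, known)


def brute_force_shapley(booster, x_row: pd.Series, features: list[str]) -> dict[str, float]:
    """Shapley values by full coalition enumeration over the tree ensemble.

    The value of a coalition S is the ensemble's cover-weighted conditional
    expectation with the features in S fixed at the row's values. Feasible
    only for a handful of features.
    """
    df = booster.trees_to_dataframe()
    trees = {}
    for tid, sub in df.groupby("Tree"):
        trees[tid] = {r["ID"]: r for _, r in sub.iterrows()}
    x = {f: x_row[f] for f in features}

    def value(S: frozenset) -> float:
        total = 0.0
        for tid, nodes in trees.items():
            root = f"{tid}-0"
            total += _tree_cond_expectation(nodes, root, x, S)
        return total

    m = len(features)
    phi = {}
    for f in features:
        others = [g for g in features if g != f]
        contrib = 0.0
        for r in range(len(others) + 1):
            for S in itertools.combinations(others, r):
                S = frozenset(S)
                weight = (
                    math.factorial(len(S)) * math.factorial(m - len(S) - 1) / math.factorial(m)
                )
                contrib += weight * (value(S | {f}) - value(S))
        phi[f] = contrib
    return phi


def mann_whitney_u_oracle(x, y) -> float:
    """U statistic by explicit pairwise comparison (ties count 1/2)."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def mann_whitney_exact_p(x, y) -> float:
    """Exact two-sided p-value by enumerating all group assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = mann_whitney_u_oracle(x, y)
    n0 = len(y)
    mu = n1 * n0 / 2.0
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        grp = [pooled[i] for i in comb]
        rest = [pooled[i] for i in range(len(pooled)) if i not in set(comb)]
        u = mann_whitney_u_oracle(grp, rest)
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


def auc_oracle(truth, scores) -> float:
    """AUC as the pairwise probability that a positive outranks a negative."""
    pos = [s for t, s in zip(truth, scores) if t == 1]
    neg = [s for t, s in zip(truth, scores) if t == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def es_oracle(ranked: pd.Series, gene_set, weight: float = 1.0) -> float:
    """Running-sum enrichment score computed with an explicit loop."""
    order = ranked.sort_values(ascending=False)
    in_set = [g in set(gene_set) for g in order.index]
    n = len(order)
    n_hits = sum(in_set)
    n_miss = n - n_hits
    denom = sum(abs(order.iloc[j]) ** weight for j in range(n) if in_set[j])
    running = 0.0
    best = 0.0
    for j in range(n):
        if in_set[j]:
            running += (abs(order.iloc[j]) ** weight) / denom
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


def random_exposure_set(rng: np.random.Generator, n_samples: int = 200, n_tumors: int = 3):
    """Arbitrary non-negative exposure cohort for property tests."""
    from panhrd.scoring import ExposureSet
    from panhrd.simulate import CN_NAMES, ID_NAMES, SBS_NAMES

    idx = pd.Index([f"R{i:04d}" for i in range(n_samples)], name="sample_id")
    labels = pd.Series(
        rng.choice([f"T{j}" for j in range(n_tumors)], size=n_samples), index=idx
    )
    classes = {}
    for name, markers in (("SBS", SBS_NAMES), ("ID", ID_NAMES), ("CN", CN_NAMES)):
        mat = rng.gamma(1.0, 1.0, size=(n_samples, len(markers)))
        # sprinkle some all-zero rows to exercise the zero-sum convention
        zero_rows = rng.random(n_samples) < 0.02
        mat[zero_rows] = 0.0
        classes[name] = pd.DataFrame(mat, index=idx, columns=list(markers))
    classes["scarHRD"] = pd.DataFrame(
        {"scarHRD": rng.gamma(2.0, 10.0, size=n_samples)}, index=idx
    )
    return ExposureSet(classes=classes, tumor_labels=labels)
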