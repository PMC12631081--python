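"""Feature ranking and preranked gene-set enrichment.

Features selected by the model are ranked by a statistic that combines the
direction of the SHAP/value relationship with the magnitude of the SHAP
importance:

    rank_v = corr(shap_v, value_v) * 10 ** importance_v

so a feature's rank carries the sign of its association and grows
multiplicatively with its global importance (a linear reading
``corr * 10 * importance`` is available via ``exponent=False``).

Enrichment uses the classic weighted Kolmogorov-Smirnov running-sum
statistic on the ranked list, with a gene-permutation null (random
same-size gene sets), sign-stratified permutation p-values, NES
normalization by the mean |ES| of the matching-sign null, and
Benjamini-Hochberg adjustment across tested sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, pearsonr
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class GMTParseError(ValueError):
    pass


@dataclass
class GeneSetCollection:
    """Named gene sets parsed from a GMT file."""

    sets: dict[str, list[str]]
    label: str = ""

    def __len__(self) -> int:
        return len(self.sets)


def load_gmt(path, label: str = "") -> GeneSetCollection:
    """Parse a GMT file: ``set_name TAB description TAB gene [TAB gene ...]``.

    Duplicate genes within a set are deduplicated (order preserved);
    duplicate set names or empty gene lists are parse errors reported with
    their line number.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GMTParseError(f"{path}:{lineno}: expected name, description, genes")
            name, _desc, *genes = parts
            genes = [g for g in genes if g.strip()]
            if not genes:
                raise GMTParseError(f"{path}:{lineno}: gene set {name!r} has no genes")
            if name in sets:
                raise GMTParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = list(dict.fromkeys(genes))
    return GeneSetCollection(sets=sets, label=label or str(path))


def rank_features(
    shap_values: pd.DataFrame,
    feature_values: pd.DataFrame,
    importance: pd.Series | None = None,
    exponent: bool = True,
) -> pd.DataFrame:
    """Rank statistic per feature: correlation sign times importance scale.

    Features whose SHAP or value column is constant (undefined
    correlation) are dropped with a warning. Returns a DataFrame with
    columns ``corr``, ``importance``, ``rank``, sorted by rank descending.
    """
    if shap_values.shape[1] == 0:
        raise ValueError("empty input")
    if importance is None:
        importance = shap_values.abs().mean(axis=0)
    rows = {}
    dropped = []
    for f in shap_values.columns:
        s = shap_values[f].to_numpy(dtype=float)
        v = feature_values[f].to_numpy(dtype=float)
        ok = np.isfinite(s) & np.isfinite(v)
        s, v = s[ok], v[ok]
        if len(s) < 2 or np.std(s) == 0 or np.std(v) == 0:
            dropped.append(f)
            continue
        c = float(pearsonr(s, v)[0])
        imp = float(importance[f])
        rank = c * (10.0 ** imp) if exponent else c * 10.0 * imp
        rows[f] = {"corr": c, "importance": imp, "rank": rank}
    if dropped:
        warnings.warn(
            f"{len(dropped)} feature(s) with undefined correlation dropped",
            RuntimeWarning,
            stacklevel=2,
        )
    out = pd.DataFrame.from_dict(rows, orient="index")
    if out.empty:
        raise ValueError("no feature has a defined correlation")
    return out.sort_values("rank", ascending=False)


def enrichment_score(
    ranked: pd.Series, gene_set: list[str], weight: float = 1.0
) -> tuple[float, int]:
    """Weighted KS running-sum enrichment score of one gene set.

    ``ranked`` maps gene -> rank value, already sorted descending. Hits
    advance the running sum by |rank|^weight (normalized), misses retreat
    by 1/(N - n_hits); the ES is the running-sum value of largest
    magnitude. Also returns the leading-edge size (hits at or before the
    extremum for positive ES, at or after it for negative).
    """
    genes = list(ranked.index)
    in_set = np.isin(genes, list(gene_set))
    n = len(genes)
    n_hits = int(in_set.sum())
    if n_hits == 0:
        raise ValueError("gene set has no overlap with the ranked universe")
    w = np.abs(ranked.to_numpy(dtype=float)) ** weight
    hit_w = np.where(in_set, w, 0.0)
    denom = hit_w.sum()
    p_hit = np.cumsum(hit_w) / (denom if denom > 0 else 1.0)
    n_miss = n - n_hits
    if n_miss > 0:
        p_miss = np.cumsum(np.where(in_set, 0.0, 1.0)) / n_miss
    else:
        # set covers the whole universe: compare the hit curve against the
        # uniform ramp so the running sum still returns to 0 at the end
        p_miss = np.arange(1, n + 1) / n
    running = p_hit - p_miss
    i_ext = int(np.argmax(np.abs(running)))
    es = float(running[i_ext])
    if es >= 0:
        leading = int(in_set[: i_ext + 1].sum())
    else:
        leading = int(in_set[i_ext:].sum())
    return es, leading


def gsea_preranked(
    ranked: pd.Series | pd.DataFrame,
    collection: GeneSetCollection | dict,
    n_perm: int = 1000,
    min_size: int = 5,
    max_size: int = 500,
    seed: int = 0,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Preranked gene-set enrichment over a collection.

    The null distribution draws ``n_perm`` random gene sets of the same
    size from the ranked universe. For each set,
    ``p = (1 + #{matching-sign null with |ES_null| >= |ES|}) / (1 + n_perm)``
    and ``NES = ES / mean(|ES_null| of matching sign)``; p-values are BH
    adjusted across all tested sets.
    """
    if isinstance(ranked, pd.DataFrame):
        ranked = ranked["rank"]
    ranked = ranked.sort_values(ascending=False)
    sets = collection.sets if isinstance(collection, GeneSetCollection) else dict(collection)
    universe = set(ranked.index)
    rows = []
    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}
    gene_arr = np.array(list(ranked.index))
    for name, genes in sets.items():
        members = [g for g in genes if g in universe]
        if not members:
            logger.info("gene set %r has no genes in the universe; skipped", name)
            continue
        size = len(members)
        if not (min_size <= size <= max_size):
            continue
        es, leading = enrichment_score(ranked, members, weight=weight)
        if size not in null_cache:
            null = np.empty(n_perm)
            for b in range(n_perm):
                draw = rng.choice(gene_arr, size=size, replace=False)
                null[b], _ = enrichment_score(ranked, draw, weight=weight)
            null_cache[size] = null
        null = null_cache[size]
        same_sign = null >= 0 if es >= 0 else null < 0
        n_extreme = int((np.abs(null[same_sign]) >= abs(es)).sum())
        p = (1 + n_extreme) / (1 + n_perm)
        denom = np.abs(null[same_sign]).mean() if same_sign.any() else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        rows.append(
            {
                "set": name,
                "size": size,
                "es": es,
                "nes": nes,
                "pval": p,
                "leading_edge": leading,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["padj"] = multipletests(out["pval"], method="fdr_bh")[1]
    return out


def partition_by_collections(
    genes: list[str], collections: dict[str, GeneSetCollection | set]
) -> pd.DataFrame:
    """Boolean membership of each gene in each collection.

    Genes belonging to no collection get a ``Complementary`` flag; the
    columns partition the gene list, so bucket counts over membership
    patterns sum to the number of genes.
    """
    memberships = {}
    for label, coll in collections.items():
        if isinstance(coll, GeneSetCollection):
            pool = set().union(*coll.sets.values()) if coll.sets else set()
        else:
            pool = set(coll)
        memberships[label] = pool
    table = pd.DataFrame(
        {label: [g in pool for g in genes] for label, pool in memberships.items()},
        index=pd.Index(genes, name="gene"),
    )
    table["Complementary"] = ~table.any(axis=1)
    return table


def intersection_counts(membership: pd.DataFrame) -> pd.Series:
    """UpSet-style counts of each observed membership pattern."""
    patterns = membership.apply(
        lambda row: "&".join(c for c in membership.columns if row[c]) or "(none)", axis=1
    )
    return patterns.value_counts()


def mutation_association(
    scores: pd.Series,
    mutation_counts: pd.Series,
    tumor_labels: pd.Series,
    min_group: int = 3,
) -> pd.DataFrame:
    """Per-tumor Mann-Whitney test of the HRD score by mutation carrier status.

    Carrier status is ``count >= 1``. Tumors where either group has fewer
    than ``min_group`` samples are skipped; p-values are BH adjusted
    across the tested tumors.
    """
    idx = scores.index
    carriers = (mutation_counts.loc[idx] >= 1)
    labels = pd.Series(tumor_labels).loc[idx]
    rows = []
    for t, ids in labels.groupby(labels).groups.items():
        c = scores.loc[ids][carriers.loc[ids]]
        nc = scores.loc[ids][~carriers.loc[ids]]
        if len(c) < min_group or len(nc) < min_group:
            continue
        u, p = mannwhitneyu(c, nc, alternative="two-sided")
        rows.append(
            {
                "tumor_type": t,
                "n_carrier": len(c),
                "n_noncarrier": len(nc),
                "U": float(u),
                "pval": float(p),
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["padj"] = multipletests(out["pval"], method="fdr_bh")[1]
    return out
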