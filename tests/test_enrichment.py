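"""Rank statistic, GMT parsing, preranked GSEA, association tests."""

import numpy as np
import pandas as pd
import pytest
from _oracles import es_oracle, mann_whitney_exact_p, mann_whitney_u_oracle

from panhrd.enrichment import (
    GMTParseError,
    enrichment_score,
    gsea_preranked,
    intersection_counts,
    load_gmt,
    mutation_association,
    partition_by_collections,
    rank_features,
)


def _shap_and_values(corrs: dict[str, float], n=50, seed=0):
    """Build SHAP/value column pairs with exact target correlations +-1/0."""
    rng = np.random.default_rng(seed)
    shap = {}
    vals = {}
    base = rng.normal(size=n)
    for f, c in corrs.items():
        v = rng.normal(size=n)
        vals[f] = v
        shap[f] = c * v if c != 0 else np.zeros(n)
    return pd.DataFrame(shap), pd.DataFrame(vals)


def test_rank_statistic_arithmetic():
    shap, vals = _shap_and_values({"up": 1.0, "down": -1.0})
    imp = pd.Series({"up": 0.3, "down": 0.0})
    ranked = rank_features(shap, vals, importance=imp)
    assert ranked.loc["up", "rank"] == pytest.approx(1.0 * 10 ** 0.3)
    assert ranked.loc["down", "rank"] == pytest.approx(-1.0)
    linear = rank_features(shap, vals, importance=imp, exponent=False)
    assert linear.loc["up", "rank"] == pytest.approx(1.0 * 10 * 0.3)


def test_rank_zero_correlation_is_zero_and_constants_dropped():
    shap, vals = _shap_and_values({"flat": 0.0, "up": 1.0})
    with pytest.warns(RuntimeWarning):
        ranked = rank_features(shap, vals, importance=pd.Series({"flat": 5.0, "up": 0.1}))
    assert "flat" not in ranked.index  # constant SHAP -> undefined correlation
    shap2 = pd.DataFrame({"weak": [0.1, -0.1, 0.1, -0.1]})
    vals2 = pd.DataFrame({"weak": [1.0, 1.0, -1.0, -1.0]})
    r2 = rank_features(shap2, vals2, importance=pd.Series({"weak": 9.9}))
    assert r2.loc["weak", "rank"] == pytest.approx(0.0)


def test_gmt_parsing(tmp_path):
    p = tmp_path / "sets.gmt"
    p.write_text("SET_A\tdesc\tg1\tg2\tg3\nSET_B\tdesc\tg1\tg4\tg5\tg6\tg7\n")
    coll = load_gmt(p)
    assert len(coll) == 2
    assert coll.sets["SET_A"] == ["g1", "g2", "g3"]
    assert len(coll.sets["SET_B"]) == 5


@pytest.mark.parametrize(
    "content",
    [
        "SET_A\tdesc\n",  # empty gene list
        "SET_A\tdesc\tg1\nSET_A\tdesc\tg2\n",  # duplicate set name
        "JUSTONEFIELD\n",  # malformed line
    ],
)
def test_gmt_parse_errors(tmp_path, content):
    p = tmp_path / "bad.gmt"
    p.write_text(content)
    with pytest.raises(GMTParseError):
        load_gmt(p)


def test_gmt_deduplicates_within_set(tmp_path):
    p = tmp_path / "dup.gmt"
    p.write_text("S\td\tg1\tg2\tg1\n")
    assert load_gmt(p).sets["S"] == ["g1", "g2"]


def test_es_matches_bruteforce_on_tiny_universe():
    rng = np.random.default_rng(1)
    ranked = pd.Series(
        rng.normal(size=8), index=[f"g{i}" for i in range(8)]
    ).sort_values(ascending=False)
    gene_set = ["g1", "g4", "g6"]
    es, _ = enrichment_score(ranked, gene_set)
    assert es == pytest.approx(es_oracle(ranked, gene_set), abs=1e-12)


def test_es_top_placement_beats_bottom_placement():
    ranked = pd.Series(
        np.linspace(10, 1, 10), index=[f"g{i}" for i in range(10)]
    )
    top = ["g0", "g1", "g2"]
    bottom = ["g7", "g8", "g9"]
    es_top, _ = enrichment_score(ranked, top)
    es_bottom, _ = enrichment_score(ranked, bottom)
    assert es_top > 0
    assert es_top > es_bottom


def test_es_whole_universe_near_zero():
    ranked = pd.Series(np.ones(6), index=[f"g{i}" for i in range(6)])
    es, _ = enrichment_score(ranked, list(ranked.index))
    assert abs(es) < 1e-9


def test_es_unweighted_invariant_to_monotone_rescaling():
    rng = np.random.default_rng(2)
    ranked = pd.Series(rng.uniform(1, 5, size=9), index=[f"g{i}" for i in range(9)])
    gene_set = ["g2", "g5"]
    es1, _ = enrichment_score(ranked, gene_set, weight=0.0)
    es2, _ = enrichment_score(ranked ** 3, gene_set, weight=0.0)
    assert es1 == pytest.approx(es2)


def test_gsea_preranked_pvalue_floor_and_bh():
    rng = np.random.default_rng(3)
    n = 40
    ranked = pd.Series(np.linspace(3, -3, n), index=[f"g{i}" for i in range(n)])
    sets = {"TOP": [f"g{i}" for i in range(6)],
            "RANDOM": list(rng.choice(ranked.index, 6, replace=False))}
    res = gsea_preranked(ranked, sets, n_perm=200, min_size=2, seed=0).set_index("set")
    assert (res["pval"] >= 1 / 201 - 1e-12).all()
    assert res.loc["TOP", "es"] > 0
    assert res.loc["TOP", "pval"] <= res.loc["RANDOM", "pval"]
    # BH never lowers a p-value and preserves order monotonicity
    assert (res["padj"] >= res["pval"] - 1e-12).all()


def test_bh_adjustment_matches_reference_values():
    """BH on a 5-value toy vector, frozen from an independent implementation."""
    from statsmodels.stats.multitest import multipletests

    p = [0.01, 0.04, 0.03, 0.005, 0.2]
    adj = multipletests(p, method="fdr_bh")[1]
    assert np.allclose(adj, [0.025, 0.05, 0.05, 0.025, 0.2], atol=1e-10)


def test_gsea_determinism_and_skip_logging():
    ranked = pd.Series(np.linspace(2, -2, 12), index=[f"g{i}" for i in range(12)])
    sets = {"IN": ["g0", "g1", "g2"], "OUT": ["absent1", "absent2"]}
    r1 = gsea_preranked(ranked, sets, n_perm=100, min_size=2, seed=4)
    r2 = gsea_preranked(ranked, sets, n_perm=100, min_size=2, seed=4)
    pd.testing.assert_frame_equal(r1, r2)
    assert list(r1["set"]) == ["IN"]  # no-overlap set skipped


def test_partition_by_collections_is_a_partition():
    genes = [f"g{i}" for i in range(10)]
    colls = {"H": {"g0", "g1"}, "K": {"g1", "g2", "g3"}}
    table = partition_by_collections(genes, colls)
    assert table.loc["g0"].tolist() == [True, False, False]
    assert table.loc["g5", "Complementary"]
    counts = intersection_counts(table)
    assert counts.sum() == len(genes)


def test_mann_whitney_full_separation_and_exact_p():
    idx = [f"s{i}" for i in range(20)]
    scores = pd.Series(np.r_[np.arange(10) + 100.0, np.arange(10)], index=idx)
    carriers = pd.Series(np.r_[np.ones(10), np.zeros(10)], index=idx)
    labels = pd.Series("T1", index=idx)
    res = mutation_association(scores, carriers, labels).set_index("tumor_type")
    assert res.loc["T1", "U"] == 100.0  # n1 * n0 for full separation
    assert res.loc["T1", "U"] == mann_whitney_u_oracle(scores[:10], scores[10:])
    # small groups: scipy's exact two-sided p equals assignment enumeration
    x, y = [3.1, 4.5, 2.2, 6.6], [1.0, 0.5, 5.0]
    from scipy.stats import mannwhitneyu

    p_scipy = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
    assert p_scipy == pytest.approx(mann_whitney_exact_p(x, y))


def test_mutation_association_skips_small_groups_and_bh_identity():
    idx = [f"s{i}" for i in range(23)]
    rng = np.random.default_rng(5)
    scores = pd.Series(rng.uniform(size=23), index=idx)
    carriers = pd.Series(np.r_[np.ones(10), np.zeros(10), np.ones(2), np.zeros(1)], index=idx)
    labels = pd.Series(["A"] * 20 + ["B"] * 3, index=idx)
    res = mutation_association(scores, carriers, labels)
    assert list(res["tumor_type"]) == ["A"]  # B has <3 per group
    assert res.loc[0, "padj"] == pytest.approx(res.loc[0, "pval"])  # BH with m=1


def test_mutation_association_null_rejection_rate():
    """Identical distributions: few adjusted rejections across replicates."""
    rng = np.random.default_rng(6)
    rejections = 0
    reps = 50
    for _ in range(reps):
        idx = range(60)
        scores = pd.Series(rng.uniform(size=60), index=idx)
        carriers = pd.Series(rng.integers(0, 2, size=60), index=idx)
        labels = pd.Series(["T1"] * 30 + ["T2"] * 30, index=idx)
        res = mutation_association(scores, carriers, labels)
        rejections += int((res["padj"] < 0.05).any())
    assert rejections / reps <= 0.15
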