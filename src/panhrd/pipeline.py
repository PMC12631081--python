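"""End-to-end orchestration: simulate -> score -> select -> train -> explain -> enrich.

``run_pipeline`` executes the stages in order from a single
:class:`PipelineConfig`, persists every intermediate artifact as TSV/JSON
under the output directory, and writes a manifest recording per-stage
status, parameters, seeds, metrics and SHA-256 checksums of the artifacts.
Deterministic stages are pure functions of (inputs, config, seed), so a
rerun with the same config reproduces identical artifact checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from panhrd import io as pio
from panhrd.boruta import BorutaConfig, select_per_layer
from panhrd.enrichment import gsea_preranked, load_gmt, partition_by_collections, rank_features
from panhrd.explain import shap_feature_correlation, shap_importance, shap_matrix, topn_ablation
from panhrd.model import HRDRegressor, stratified_split
from panhrd.preprocess import assemble
from panhrd.scoring import ScoreConfig, panhrd_scores
from panhrd.simulate import SyntheticConfig, generate_cohort

logger = logging.getLogger(__name__)

STAGES = ("simulate", "score", "select", "train", "explain", "enrich")


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """One config object for the whole run.

    Either ``synthetic`` (a :class:`SyntheticConfig`) or the input paths
    (``exposures_path`` + ``omics_paths``) must be provided.
    """

    out_dir: str | Path = "panhrd_run"
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    exposures_path: str | None = None
    omics_paths: dict[str, str] | None = None
    score: ScoreConfig = field(default_factory=ScoreConfig)
    boruta: BorutaConfig | None = None
    n_candidates: int = 20
    boot: int = 100
    n_grid: list | None = None
    gmt_paths: dict[str, str] | None = None
    n_perm: int = 500

    def __post_init__(self) -> None:
        if self.synthetic is None and (
            self.exposures_path is None or self.omics_paths is None
        ):
            raise PipelineConfigError(
                "config needs either a synthetic block or exposures_path + omics_paths"
            )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _synthetic_collections(bundle, truth, rng) -> dict[str, dict[str, list[str]]]:
    """Stand-in gene-set collections for synthetic runs: one planted set per
    layer plus random sets of the same sizes (labelled synthetic)."""
    collections = {}
    for name, mat in bundle.layers.items():
        genes = list(mat.columns)
        sets = {}
        planted = truth.informative_genes.get(name, [])
        if planted:
            sets[f"SYNTH_PLANTED_{name}"] = list(planted)
        for j in range(4):
            size = max(5, len(planted) or 10)
            sets[f"SYNTH_RANDOM_{name}_{j}"] = list(
                rng.choice(genes, size=min(size, len(genes)), replace=False)
            )
        collections[name] = sets
    return collections


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all six stages and return the manifest (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "artifacts": {}, "metrics": {}}
    manifest_path = out / "manifest.json"

    def record(stage: str, t0: float, **info) -> None:
        manifest["stages"][stage] = {"status": "complete", "seconds": round(time.time() - t0, 2), **info}
        manifest_path.write_text(json.dumps(manifest, indent=1, default=str))

    def add_artifact(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {"path": str(path), "sha256": _sha256(path)}

    stage = "simulate"
    try:
        t0 = time.time()
        if config.synthetic is not None:
            exposures, bundle, truth = generate_cohort(config.synthetic)
            pio.write_exposures(exposures, out / "exposures.tsv")
            add_artifact("exposures", out / "exposures.tsv")
            for name, p in pio.write_bundle(bundle, out / "omics").items():
                add_artifact(f"omics_{name}", p)
        else:
            exposures = pio.read_exposures(config.exposures_path)
            bundle = pio.read_bundle(config.omics_paths)
            truth = None
        record(stage, t0, n_samples=exposures.n_samples)

        stage = "score"
        t0 = time.time()
        score_result = panhrd_scores(exposures, config.score, discretize=True)
        pio.write_scores(score_result, exposures.tumor_labels, out / "scores.tsv")
        add_artifact("scores", out / "scores.tsv")
        manifest["metrics"]["median_panhrd"] = float(np.median(score_result.scores))
        record(stage, t0, epsilon=config.score.epsilon)

        stage = "select"
        t0 = time.time()
        split = stratified_split(
            exposures.sample_ids, exposures.tumor_labels, seed=config.seed
        )
        bcfg = config.boruta or BorutaConfig(seed=config.seed)
        transformed = bundle.transformed()
        selection = select_per_layer(
            transformed, score_result, bcfg, sample_ids=split.train_ids
        )
        selection.summary.to_csv(out / "selection_summary.tsv", sep="\t")
        add_artifact("selection_summary", out / "selection_summary.tsv")
        for name, genes in selection.confirmed.items():
            pio.write_gene_list(genes, out / f"confirmed_{name}.tsv")
        manifest["metrics"]["n_selected_features"] = int(
            sum(len(v) for v in selection.confirmed.values())
        )
        record(stage, t0, per_layer={k: len(v) for k, v in selection.confirmed.items()})

        stage = "train"
        t0 = time.time()
        features = assemble(transformed, selected_genes=selection.confirmed)
        reg = HRDRegressor(
            features, score_result.scores, exposures.tumor_labels,
            split=split, seed=config.seed,
        )
        results = reg.fit(n_candidates=config.n_candidates)
        results.save(out / "model")
        add_artifact("model_meta", out / "model" / "model_meta.json")
        report = results.evaluate()
        report.to_series().to_csv(out / "eval_overall.tsv", sep="\t", header=["value"])
        report.per_tumor.rename_axis("tumor_type").to_csv(out / "eval_per_tumor.tsv", sep="\t")
        add_artifact("eval_overall", out / "eval_overall.tsv")
        manifest["metrics"].update(
            {k: (None if pd.isna(v) else float(v)) for k, v in report.to_series().items()}
        )
        record(stage, t0, params=results.params)

        stage = "explain"
        t0 = time.time()
        shap = shap_matrix(results)
        shap.values.rename_axis("sample_id").to_csv(out / "shap_values.tsv", sep="\t")
        add_artifact("shap_values", out / "shap_values.tsv")
        importance = shap_importance(shap)
        importance.rename_axis("feature").to_csv(out / "shap_importance.tsv", sep="\t")
        heat = shap_feature_correlation(
            shap, tumor_labels=exposures.tumor_labels.loc[shap.values.index]
        )
        heat.rename_axis("tumor_type").to_csv(out / "shap_corr_heatmap.tsv", sep="\t")
        ablation = topn_ablation(results, n_grid=config.n_grid)
        ablation.to_csv(out / "topn_ablation.tsv", sep="\t", index=False)
        add_artifact("topn_ablation", out / "topn_ablation.tsv")
        record(stage, t0, n_test=shap.values.shape[0])

        stage = "enrich"
        t0 = time.time()
        ranked = rank_features(shap.values, shap.feature_values, importance=importance)
        ranked.rename_axis("feature").to_csv(out / "ranked_features.tsv", sep="\t")
        add_artifact("ranked_features", out / "ranked_features.tsv")
        if config.gmt_paths:
            collections = {
                lbl: load_gmt(p, label=lbl).sets for lbl, p in config.gmt_paths.items()
            }
        elif truth is not None:
            rng = np.random.default_rng(config.seed + 7)
            collections = _synthetic_collections(bundle, truth, rng)
        else:
            collections = {}
        enrich_frames = []
        for lbl, sets in collections.items():
            # per-layer ranked list: strip the layer prefix to gene IDs
            sub = ranked[ranked.index.str.startswith(f"{lbl}:")].copy()
            if sub.empty:
                continue
            sub.index = sub.index.str.split(":", n=1).str[1]
            res = gsea_preranked(
                sub["rank"], sets, n_perm=config.n_perm, min_size=2, seed=config.seed
            )
            if not res.empty:
                res.insert(0, "collection", lbl)
                enrich_frames.append(res)
        enrichment = (
            pd.concat(enrich_frames, ignore_index=True) if enrich_frames else pd.DataFrame()
        )
        enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        add_artifact("enrichment", out / "enrichment.tsv")
        all_genes = sorted(
            {f.split(":", 1)[1] for f in ranked.index if ":" in f}
        )
        membership = partition_by_collections(
            all_genes,
            {lbl: set().union(*sets.values()) if sets else set() for lbl, sets in collections.items()},
        )
        membership.to_csv(out / "collection_membership.tsv", sep="\t")
        record(stage, t0, n_sets=int(sum(len(s) for s in collections.values())))
    except Exception as exc:  # tag the failing stage, keep the partial manifest
        manifest["stages"][stage] = {"status": "failed", "error": f"{type(exc).__name__}: {exc}"}
        manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
        raise RuntimeError(f"pipeline stage {stage!r} failed") from exc

    manifest_path.write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
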