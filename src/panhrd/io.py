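"""Plain-text readers and writers for the pipeline's tabular artifacts.

All formats are TSV with a header row. Exposures travel in long format
(``sample_id, tumor_type, class, biomarker, exposure``); omics layers,
feature tables and score tables are wide matrices with a ``sample_id``
index column; mutation tables are MAF-like long tables
(``sample_id, gene, impact``). Synthetic and real data use identical
layouts, so the writers here emit what the readers consume.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from panhrd.preprocess import OmicsBundle
from panhrd.scoring import ExposureSet, ScoreResult


def write_exposures(exposures: ExposureSet, path) -> None:
    exposures.to_long().to_csv(path, sep="\t", index=False)


def read_exposures(path) -> ExposureSet:
    long = pd.read_csv(path, sep="\t")
    return ExposureSet.from_long(long)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.rename_axis("sample_id").to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_bundle(bundle: OmicsBundle, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, mat in bundle.layers.items():
        p = out / f"{name.lower()}.tsv"
        write_matrix(mat, p)
        paths[name] = p
    return paths


def read_bundle(paths: dict[str, str]) -> OmicsBundle:
    return OmicsBundle(layers={name: read_matrix(p) for name, p in paths.items()})


def write_scores(result: ScoreResult, tumor_labels: pd.Series, path) -> None:
    out = result.to_frame()
    out.insert(0, "tumor_type", tumor_labels.loc[out.index])
    out.rename_axis("sample_id").to_csv(path, sep="\t")


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def read_mutation_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gene_list(path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_gene_list(genes: list[str], path) -> None:
    Path(path).write_text("\n".join(genes) + ("\n" if genes else ""))
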