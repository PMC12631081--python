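"""Omics-layer transforms and assembly of the model-ready feature table.

Four gene-level layers are supported:

- ``CNV`` — copy-number scores with diploid = 2, transformed as
  ``log2(1 + x/2)`` so diploid maps to 1 and homozygous deletion to 0;
- ``EXP`` — TPM expression, transformed as ``log(1 + x)`` (natural log;
  the base only rescales the column and cannot change tree-model splits);
- ``MET`` — beta values in [0, 1], used as-is;
- ``MUT`` — per-gene counts of protein-altering mutations (VEP impact HIGH
  or MODERATE), used as-is.

Features are z-scaled with statistics computed on training samples only
(sample SD, ddof=1), then concatenated column-wise with layer-prefixed IDs.
Samples missing an entire layer keep NaN entries there; the downstream
boosted-tree model routes missing values natively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LAYER_NAMES = ("CNV", "EXP", "MET", "MUT")

#: VEP impact classes counted as protein-altering
QUALIFYING_IMPACTS = frozenset({"HIGH", "MODERATE"})
KNOWN_IMPACTS = frozenset({"HIGH", "MODERATE", "LOW", "MODIFIER"})


class OmicsValidationError(ValueError):
    pass


@dataclass
class OmicsBundle:
    """Aligned gene-level matrices (samples x genes) for up to four layers.

    ``transformation_state`` tracks whether each layer is raw, transformed,
    or scaled; transforms refuse to run twice.
    """

    layers: dict[str, pd.DataFrame]
    transformation_state: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [k for k in self.layers if k not in LAYER_NAMES]
        if unknown:
            raise OmicsValidationError(
                f"unknown layer name(s) {unknown}; expected subset of {LAYER_NAMES}"
            )
        for name in self.layers:
            self.transformation_state.setdefault(name, "raw")
        self._validate_raw()

    def _validate_raw(self) -> None:
        met = self.layers.get("MET")
        if met is not None and self.transformation_state.get("MET") == "raw":
            vals = met.to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            if ((finite < 0) | (finite > 1)).any():
                raise OmicsValidationError("raw methylation beta values must lie in [0, 1]")
        mut = self.layers.get("MUT")
        if mut is not None and self.transformation_state.get("MUT") == "raw":
            vals = mut.to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            if (finite < 0).any() or not np.allclose(finite, np.round(finite)):
                raise OmicsValidationError("raw mutation counts must be non-negative integers")

    @property
    def sample_ids(self) -> pd.Index:
        return next(iter(self.layers.values())).index

    def transformed(self) -> "OmicsBundle":
        """Apply the standard per-layer transforms, returning a new bundle."""
        out: dict[str, pd.DataFrame] = {}
        state: dict[str, str] = {}
        for name, mat in self.layers.items():
            if self.transformation_state[name] != "raw":
                out[name] = mat
                state[name] = self.transformation_state[name]
                continue
            if name == "EXP":
                out[name] = transform_expression(mat)
            elif name == "CNV":
                out[name] = transform_cnv(mat)
            else:  # MET, MUT used on their natural scale
                out[name] = mat
            state[name] = "transformed"
        return OmicsBundle(layers=out, transformation_state=state)


@dataclass
class FeatureTable:
    """Samples x features matrix with layer-prefixed feature IDs.

    ``scale_means`` / ``scale_sds`` hold the z-scaling statistics, computed
    from training rows only, so held-out samples can never leak into them.
    """

    values: pd.DataFrame
    scale_means: pd.Series | None = None
    scale_sds: pd.Series | None = None
    train_ids: pd.Index | None = None

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index


def transform_expression(tpm: pd.DataFrame) -> pd.DataFrame:
    """log(1 + x) on TPM expression (natural log)."""
    arr = tpm.to_numpy(dtype=float)
    if (arr[np.isfinite(arr)] < 0).any():
        raise OmicsValidationError("TPM values must be non-negative")
    return pd.DataFrame(np.log1p(arr), index=tpm.index, columns=tpm.columns)


def transform_cnv(scores: pd.DataFrame) -> pd.DataFrame:
    """log2(1 + x/2) on gene-level copy-number scores (diploid 2 -> 1)."""
    arr = scores.to_numpy(dtype=float)
    if (arr[np.isfinite(arr)] < 0).any():
        raise OmicsValidationError("CNV scores must be non-negative")
    return pd.DataFrame(np.log2(1.0 + arr / 2.0), index=scores.index, columns=scores.columns)


def filter_and_count_mutations(
    mutation_table: pd.DataFrame,
    sample_ids: list | pd.Index,
    gene_universe: list | pd.Index,
    strict_impacts: bool = True,
) -> pd.DataFrame:
    """Gene-level counts of protein-altering mutations per sample.

    Only rows with VEP impact HIGH or MODERATE are counted. Genes of the
    declared universe with no qualifying mutations are retained as all-zero
    columns so layers stay aligned.

    Parameters
    ----------
    mutation_table
        Long table with columns ``sample_id``, ``gene``, ``impact``.
    strict_impacts
        If True (default), an impact label outside
        HIGH/MODERATE/LOW/MODIFIER raises; if False, unknown labels are
        treated as non-qualifying.
    """
    required = {"sample_id", "gene", "impact"}
    if not required.issubset(mutation_table.columns):
        raise OmicsValidationError(f"mutation table needs columns {sorted(required)}")
    impacts = mutation_table["impact"].astype(str).str.upper()
    if strict_impacts:
        unknown = set(impacts.unique()) - KNOWN_IMPACTS
        if unknown:
            raise OmicsValidationError(f"unknown VEP impact label(s): {sorted(unknown)}")
    keep = mutation_table.loc[impacts.isin(QUALIFYING_IMPACTS)]
    counts = (
        keep.groupby(["sample_id", "gene"], sort=False).size().unstack(fill_value=0)
    )
    out = counts.reindex(index=pd.Index(sample_ids), columns=pd.Index(gene_universe)).fillna(0)
    return out.astype(int)


def zscale(features: FeatureTable, train_ids: list | pd.Index) -> FeatureTable:
    """z-scale all rows using mean/SD computed on training rows only.

    Uses the sample SD (ddof=1). Constant training columns (SD = 0) map to
    0 everywhere with a warning. NaN entries stay NaN.
    """
    train_ids = pd.Index(train_ids)
    if len(train_ids) == 0:
        raise ValueError("train_ids must be non-empty")
    train = features.values.loc[train_ids]
    means = train.mean(axis=0)
    sds = train.std(axis=0, ddof=1)
    constant = sds.fillna(0.0) == 0.0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant feature column(s) scaled to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    safe_sds = sds.where(~constant, 1.0)
    scaled = (features.values - means) / safe_sds
    scaled.loc[:, constant] = scaled.loc[:, constant].where(
        features.values.loc[:, constant].isna(), 0.0
    )
    return FeatureTable(
        values=scaled, scale_means=means, scale_sds=sds, train_ids=train_ids
    )


def assemble(
    bundle: OmicsBundle,
    selected_genes: dict[str, list] | None = None,
    sample_ids: pd.Index | None = None,
) -> FeatureTable:
    """Concatenate (optionally gene-filtered) layers into one feature table.

    Feature IDs are prefixed by layer, e.g. ``EXP:GENE1``. Samples absent
    from a layer get NaN entries for that layer's columns.
    """
    if sample_ids is None:
        all_ids = pd.Index([])
        for mat in bundle.layers.values():
            all_ids = all_ids.union(mat.index, sort=False)
        sample_ids = all_ids
    if pd.Index(sample_ids).has_duplicates:
        raise OmicsValidationError("duplicate sample IDs in assembly")
    blocks = []
    for name in LAYER_NAMES:
        if name not in bundle.layers:
            continue
        mat = bundle.layers[name]
        if selected_genes is not None:
            genes = list(selected_genes.get(name, []))
            mat = mat.loc[:, [g for g in genes if g in mat.columns]]
        if mat.shape[1] == 0:
            continue
        block = mat.reindex(pd.Index(sample_ids)).astype(float)
        block.columns = [f"{name}:{g}" for g in block.columns]
        blocks.append(block)
    if not blocks:
        values = pd.DataFrame(index=pd.Index(sample_ids))
    else:
        values = pd.concat(blocks, axis=1)
    if values.columns.has_duplicates:
        raise OmicsValidationError("duplicate feature IDs after assembly")
    return FeatureTable(values=values)
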