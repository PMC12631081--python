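"""Aggregated HRD score (panHRD) from mutational-signature exposures.

The score combines four biomarker classes — single-base-substitution (SBS)
signatures, indel (ID) signatures, copy-number (CN) signatures, and the
scarHRD genomic-scar sum (LOH + LST + TAI) — into a single per-sample value
in [0, 1]:

1. Within each sample, SBS/ID/CN exposures are converted to proportions of
   that sample's total class exposure; scarHRD is divided by the cohort-wide
   maximum.
2. One HRD-linked biomarker is selected per class: SBS3, ID6, and for the CN
   class the pair CN1/CN17 is collapsed to ``((1 - Ê_CN1) + Ê_CN17) / 2``
   (CN1 marks copy-number-quiet, HR-proficient genomes and anti-correlates
   with the HRD signature CN17).
3. Per tumor type t and class k, a weight ``w_{k,t}`` is the fraction of
   samples of that type whose normalized exposure is at least ``epsilon``;
   weights are rescaled to sum to 1 within each tumor type so scores remain
   comparable across types.
4. The panHRD score of sample i of tumor type t is the weighted sum
   ``s_{t,i} = sum_k ŵ_{k,t} Ê_{k,i}``.

Because each Ê lies in [0, 1] and the rescaled weights sum to 1, the score
is a convex combination and itself lies in [0, 1].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical order of the four biomarker classes
CLASS_ORDER = ("SBS", "ID", "CN", "scarHRD")

#: classes normalized within-sample (proportion of the class total)
PROPORTION_CLASSES = ("SBS", "ID", "CN")

#: default HRD-linked biomarker selection per class
DEFAULT_SELECTION = {
    "SBS": ("SBS3",),
    "ID": ("ID6",),
    "CN": ("CN1", "CN17"),
    "scarHRD": ("scarHRD",),
}


class ExposureValidationError(ValueError):
    """Raised when an exposure table violates its contract."""


@dataclass
class ExposureSet:
    """Per-class signature-exposure matrices with tumor-type labels.

    Parameters
    ----------
    classes
        Mapping class name -> (samples x biomarkers) DataFrame of
        non-negative exposures. Must contain the four classes in
        :data:`CLASS_ORDER`; the scarHRD class has a single column.
    tumor_labels
        Tumor-type label per sample, indexed by sample ID; index must match
        the row index of every class matrix.
    """

    classes: dict[str, pd.DataFrame]
    tumor_labels: pd.Series

    def __post_init__(self) -> None:
        missing = [c for c in CLASS_ORDER if c not in self.classes]
        if missing:
            raise ExposureValidationError(f"missing exposure classes: {missing}")
        self.tumor_labels = pd.Series(self.tumor_labels)
        idx = self.tumor_labels.index
        if idx.has_duplicates:
            raise ExposureValidationError("sample IDs must be unique")
        for name, mat in self.classes.items():
            if not isinstance(mat, pd.DataFrame):
                raise ExposureValidationError(f"class {name!r} must be a DataFrame")
            if not mat.index.equals(idx):
                raise ExposureValidationError(
                    f"class {name!r} sample index does not match tumor_labels"
                )
            if (mat.to_numpy() < 0).any():
                raise ExposureValidationError(f"class {name!r} has negative exposures")
        if self.classes["scarHRD"].shape[1] != 1:
            raise ExposureValidationError("scarHRD class must have exactly one column")

    @property
    def sample_ids(self) -> pd.Index:
        return self.tumor_labels.index

    @property
    def n_samples(self) -> int:
        return len(self.tumor_labels)

    def to_long(self) -> pd.DataFrame:
        """Long-format view: sample_id, tumor_type, class, biomarker, exposure."""
        frames = []
        for name in CLASS_ORDER:
            mat = self.classes[name]
            long = mat.stack().rename("exposure").reset_index()
            long.columns = ["sample_id", "biomarker", "exposure"]
            long.insert(1, "tumor_type", self.tumor_labels.loc[long["sample_id"]].to_numpy())
            long.insert(2, "class", name)
            frames.append(long)
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "ExposureSet":
        """Build from a long table with columns sample_id, tumor_type, class, biomarker, exposure."""
        required = {"sample_id", "tumor_type", "class", "biomarker", "exposure"}
        if not required.issubset(long.columns):
            raise ExposureValidationError(f"long table needs columns {sorted(required)}")
        labels = (
            long[["sample_id", "tumor_type"]]
            .drop_duplicates("sample_id")
            .set_index("sample_id")["tumor_type"]
        )
        classes = {}
        for name, sub in long.groupby("class", sort=False):
            wide = sub.pivot(index="sample_id", columns="biomarker", values="exposure")
            classes[name] = wide.reindex(labels.index).fillna(0.0)
        return cls(classes=classes, tumor_labels=labels)


@dataclass
class ScoreConfig:
    """Configuration of the aggregated-score computation.

    ``epsilon`` is the exposure threshold defining the per-tumor weights
    (fraction of samples with normalized exposure >= epsilon); the default
    0.1 is the operating point used throughout.
    """

    epsilon: float = 0.1
    selected_biomarkers: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SELECTION)
    )

    def __post_init__(self) -> None:
        if not (0.0 < self.epsilon < 1.0):
            raise ValueError(f"epsilon must lie in (0, 1), got {self.epsilon}")


@dataclass
class WeightTable:
    """Raw and rescaled per-tumor class weights (tumor types x 4 classes)."""

    raw: pd.DataFrame
    rescaled: pd.DataFrame


@dataclass
class ScoreResult:
    """panHRD scores with the intermediates needed to audit them."""

    scores: pd.Series
    normalized_exposures: pd.DataFrame  # samples x 4 selected biomarkers
    weights: WeightTable
    labels: pd.Series | None = None
    cutoff: float | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"panHRD": self.scores}
        )
        if self.labels is not None:
            out["label"] = self.labels
        return out


def normalize_signature_exposures(class_matrix: pd.DataFrame) -> pd.DataFrame:
    """Within-sample proportion normalization for SBS/ID/CN exposures.

    Each row is divided by its row sum; all-zero rows stay all-zero (such a
    sample contributes no signal in that class).
    """
    arr = np.asarray(class_matrix, dtype=float)
    if (arr < 0).any():
        raise ExposureValidationError("exposures must be non-negative")
    row_sums = arr.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(row_sums > 0, arr / np.where(row_sums == 0, 1.0, row_sums), 0.0)
    return pd.DataFrame(out, index=class_matrix.index, columns=class_matrix.columns)


def normalize_scarhrd(values: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Cohort-max normalization of the scarHRD scar sum.

    Divides by the maximum observed value across all samples; an all-zero
    cohort maps to all zeros.
    """
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ExposureValidationError("scarHRD values must be non-negative")
    mx = arr.max() if arr.size else 0.0
    out = arr / mx if mx > 0 else np.zeros_like(arr)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def combine_cn(e_cn1, e_cn17):
    """Collapse the normalized CN1/CN17 pair into a single HRD biomarker.

    ``((1 - Ê_CN1) + Ê_CN17) / 2`` — low CN1 (few quiet diploid segments)
    and high CN17 (HRD-pattern LOH segments) both push toward 1.
    """
    a = np.asarray(e_cn1, dtype=float)
    b = np.asarray(e_cn17, dtype=float)
    if ((a < 0) | (a > 1) | (b < 0) | (b > 1)).any():
        raise ExposureValidationError("combine_cn inputs must lie in [0, 1]")
    out = ((1.0 - a) + b) / 2.0
    if np.isscalar(e_cn1) or np.ndim(e_cn1) == 0:
        return float(out)
    return out


def selected_normalized_exposures(
    exposures: ExposureSet, config: ScoreConfig | None = None
) -> pd.DataFrame:
    """Normalize each class and extract the selected HRD biomarker per class.

    Returns a samples x 4 DataFrame with columns named after the classes
    (the CN column carries the combined CN1/CN17 biomarker).
    """
    config = config or ScoreConfig()
    cols = {}
    for name in CLASS_ORDER:
        sel = config.selected_biomarkers.get(name)
        if sel is None:
            raise ExposureValidationError(f"no selected biomarker for class {name!r}")
        mat = exposures.classes[name]
        missing = [b for b in sel if b not in mat.columns and name != "scarHRD"]
        if missing:
            raise ExposureValidationError(
                f"selected biomarkers {missing} absent from class {name!r}"
            )
        if name == "scarHRD":
            cols[name] = normalize_scarhrd(mat.iloc[:, 0])
        elif name == "CN":
            norm = normalize_signature_exposures(mat)
            b1, b17 = sel
            cols[name] = pd.Series(
                combine_cn(norm[b1], norm[b17]), index=mat.index
            )
        else:
            norm = normalize_signature_exposures(mat)
            (b,) = sel
            cols[name] = norm[b]
    return pd.DataFrame(cols, index=exposures.sample_ids)[list(CLASS_ORDER)]


def compute_weights(
    selected: pd.DataFrame, tumor_labels: pd.Series, epsilon: float
) -> pd.DataFrame:
    """Per-tumor raw weights: fraction of samples with exposure >= epsilon.

    The indicator is inclusive at epsilon. Rows are tumor types, columns the
    four classes.
    """
    if not (0.0 < epsilon < 1.0):
        raise ValueError("epsilon must lie in (0, 1)")
    labels = pd.Series(tumor_labels)
    counts = labels.value_counts()
    if (counts == 0).any():
        raise ValueError("tumor type with zero samples")
    hits = (selected >= epsilon).astype(float)
    raw = hits.groupby(labels).mean()
    return raw[list(CLASS_ORDER)]


def rescale_weights(raw: pd.DataFrame) -> pd.DataFrame:
    """Rescale each tumor's class weights to sum to 1.

    A tumor type whose four raw weights are all zero (no sample of that type
    exceeds epsilon in any class) falls back to uniform 1/4 weights; this is
    logged as a warning since such scores carry little signal.
    """
    arr = raw.to_numpy(dtype=float)
    sums = arr.sum(axis=1, keepdims=True)
    zero_rows = (sums == 0).ravel()
    if zero_rows.any():
        bad = list(raw.index[zero_rows])
        warnings.warn(
            f"all-zero weight row(s) for tumor type(s) {bad}; using uniform weights",
            RuntimeWarning,
            stacklevel=2,
        )
    out = np.where(zero_rows[:, None], 0.25, arr / np.where(sums == 0, 1.0, sums))
    return pd.DataFrame(out, index=raw.index, columns=raw.columns)


def panhrd_scores(
    exposures: ExposureSet,
    config: ScoreConfig | None = None,
    weights: pd.DataFrame | None = None,
    discretize: bool = False,
    cutoff: float | None = None,
) -> ScoreResult:
    """Full aggregated-score chain: normalize, select, weight, combine.

    Parameters
    ----------
    exposures
        Cohort exposures with tumor-type labels.
    config
        Epsilon and biomarker selection; defaults to ``ScoreConfig()``.
    weights
        Optional externally computed rescaled weights (tumors x classes);
        by default weights are computed from the cohort passed here, so
        train-only weighting is possible by scoring the training cohort
        first and passing its weights when scoring held-out samples.
    discretize
        If True, also attach binary labels from :func:`discretize_by_median`.
    cutoff
        Externally supplied discretization cutoff (e.g., a cohort median
        computed elsewhere); ignored unless ``discretize``.
    """
    config = config or ScoreConfig()
    selected = selected_normalized_exposures(exposures, config)
    raw = compute_weights(selected, exposures.tumor_labels, config.epsilon)
    if weights is None:
        rescaled = rescale_weights(raw)
    else:
        rescaled = weights[list(CLASS_ORDER)]
    per_sample_w = rescaled.loc[exposures.tumor_labels].to_numpy()
    scores = pd.Series(
        (per_sample_w * selected.to_numpy()).sum(axis=1),
        index=exposures.sample_ids,
        name="panHRD",
    )
    result = ScoreResult(
        scores=scores,
        normalized_exposures=selected,
        weights=WeightTable(raw=raw, rescaled=rescaled),
    )
    if discretize:
        result.labels, result.cutoff = discretize_by_median(scores, cutoff=cutoff)
    return result


def discretize_by_median(
    scores: pd.Series | np.ndarray, cutoff: float | None = None
) -> tuple[pd.Series | np.ndarray, float]:
    """Binarize scores at the cohort median (or a supplied cutoff).

    A sample is labeled positive iff its score is strictly greater than the
    cutoff, so ties at the median fall in the negative class.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot discretize an empty score vector")
    if cutoff is None:
        cutoff = float(np.median(arr))
    labels = (arr > cutoff).astype(int)
    if isinstance(scores, pd.Series):
        labels = pd.Series(labels, index=scores.index, name="label")
    return labels, float(cutoff)
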