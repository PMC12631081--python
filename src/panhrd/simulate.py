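"""Synthetic multi-omics cohorts with a known latent HRD signal.

The generator emulates the statistical structure of a pan-cancer cohort:
a latent per-sample HRD level drawn from a bimodal Beta mixture (an
HR-proficient and an HR-deficient subpopulation) drives the HRD-linked
signature exposures — SBS3, ID6, CN17 and the scarHRD scar sum increase
with the latent level, CN1 decreases — while all other biomarkers are
latent-independent Gamma noise. In each omics layer a small set of planted
"informative" genes is coupled to the same latent level so downstream
feature selection and regression have a parameter-recovery ground truth.

Exposures use Gamma baselines with latent-scaled means: non-negative and
overdispersed, like NMF-estimated signature activities. The planted
biomarker's mean is expressed as a fraction of the rest of its class, so
after within-sample proportion normalization the normalized exposure rises
smoothly from ~0.05 (latent 0) toward ~0.5 (latent 1) at the default
effect size of 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from panhrd.preprocess import LAYER_NAMES, OmicsBundle
from panhrd.scoring import ExposureSet

#: biomarker catalogs per class (COSMIC-style names)
SBS_NAMES = tuple(f"SBS{i}" for i in range(1, 31))
ID_NAMES = tuple(f"ID{i}" for i in range(1, 24))
CN_NAMES = tuple(f"CN{i}" for i in range(1, 22))

#: Gamma shape of exposure noise (CV = 1/sqrt(shape))
_GAMMA_SHAPE = 5.0
#: planted-biomarker mean as a fraction of its class's noise total:
#: baseline_frac + slope * effect_size * latent
_BASE_FRAC = 0.05
_SLOPE = 0.225


class SyntheticConfigError(ValueError):
    pass


def _as_layer_map(value, default: int) -> dict[str, int]:
    if value is None:
        return {name: default for name in LAYER_NAMES}
    if isinstance(value, int):
        return {name: value for name in LAYER_NAMES}
    return dict(value)


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic cohort.

    Defaults are desk-scale: 2,000 samples, 3 tumor types, 75 genes per
    layer (300 features in total across the four layers) of which 10 per
    layer are informative, effect size 2, unit noise SD.
    """

    n_samples: int = 2000
    n_tumor_types: int = 3
    tumor_proportions: list[float] | None = None
    n_genes_per_layer: dict[str, int] | int | None = None
    n_informative_per_layer: dict[str, int] | int | None = None
    effect_size: float = 2.0
    noise_sd: float = 1.0
    hrd_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_tumor_types <= 0:
            raise SyntheticConfigError("n_samples and n_tumor_types must be positive")
        if self.tumor_proportions is None:
            self.tumor_proportions = [1.0 / self.n_tumor_types] * self.n_tumor_types
        if len(self.tumor_proportions) != self.n_tumor_types:
            raise SyntheticConfigError("tumor_proportions length must equal n_tumor_types")
        if abs(sum(self.tumor_proportions) - 1.0) > 1e-9:
            raise SyntheticConfigError("tumor_proportions must sum to 1")
        self.n_genes_per_layer = _as_layer_map(self.n_genes_per_layer, 75)
        self.n_informative_per_layer = _as_layer_map(self.n_informative_per_layer, 10)
        unknown = set(self.n_genes_per_layer) - set(LAYER_NAMES)
        unknown |= set(self.n_informative_per_layer) - set(LAYER_NAMES)
        if unknown:
            raise SyntheticConfigError(
                f"unknown layer name(s) {sorted(unknown)}; expected {LAYER_NAMES}"
            )
        for name in self.n_genes_per_layer:
            n_g = self.n_genes_per_layer[name]
            n_i = self.n_informative_per_layer.get(name, 0)
            if n_g <= 0:
                raise SyntheticConfigError(f"layer {name}: n_genes must be positive")
            if not (0 <= n_i <= n_g):
                raise SyntheticConfigError(
                    f"layer {name}: informative count must lie in [0, n_genes]"
                )
        if self.effect_size < 0:
            raise SyntheticConfigError("effect_size must be non-negative")
        if self.noise_sd <= 0:
            raise SyntheticConfigError("noise_sd must be positive")
        if not (0.0 <= self.hrd_fraction <= 1.0):
            raise SyntheticConfigError("hrd_fraction must lie in [0, 1]")


@dataclass
class CohortTruth:
    """Ground truth of a synthetic cohort: the latent HRD level per sample,
    the planted informative genes per layer, and the tumor labels."""

    latent_hrd: pd.Series
    informative_genes: dict[str, list[str]]
    tumor_labels: pd.Series


def _planted_exposure(rng, noise_total: float, latent: np.ndarray, effect: float) -> np.ndarray:
    mean = noise_total * (_BASE_FRAC + _SLOPE * effect * latent)
    return rng.gamma(_GAMMA_SHAPE, np.maximum(mean, 1e-12) / _GAMMA_SHAPE)


def _signature_class(
    rng, names: tuple[str, ...], planted: dict[str, np.ndarray], n: int
) -> pd.DataFrame:
    """Gamma noise (mean 1) for every biomarker, planted columns overridden."""
    mat = rng.gamma(_GAMMA_SHAPE, 1.0 / _GAMMA_SHAPE, size=(n, len(names)))
    df = pd.DataFrame(mat, columns=list(names))
    for name, col in planted.items():
        df[name] = col
    return df


def generate_exposures(config: SyntheticConfig) -> tuple[ExposureSet, CohortTruth]:
    """Draw the latent HRD level, tumor labels, and all four exposure classes.

    SBS3, ID6, CN17 and scarHRD increase monotonically (in the mean) with
    the latent level; CN1 decreases; every other biomarker is
    latent-independent.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_latent, rng_expo, _ = [np.random.default_rng(s) for s in ss.spawn(3)]
    n = config.n_samples

    deficient = rng_latent.random(n) < config.hrd_fraction
    latent = np.where(
        deficient,
        rng_latent.beta(8.0, 2.0, size=n),
        rng_latent.beta(2.0, 8.0, size=n),
    )
    sample_ids = pd.Index([f"S{i:05d}" for i in range(n)], name="sample_id")
    types = [f"T{j + 1}" for j in range(config.n_tumor_types)]
    labels = pd.Series(
        rng_latent.choice(types, size=n, p=config.tumor_proportions),
        index=sample_ids,
        name="tumor_type",
    )

    e = config.effect_size
    sbs = _signature_class(
        rng_expo,
        SBS_NAMES,
        {"SBS3": _planted_exposure(rng_expo, len(SBS_NAMES) - 1, latent, e)},
        n,
    )
    idm = _signature_class(
        rng_expo,
        ID_NAMES,
        {"ID6": _planted_exposure(rng_expo, len(ID_NAMES) - 1, latent, e)},
        n,
    )
    cn = _signature_class(
        rng_expo,
        CN_NAMES,
        {
            "CN17": _planted_exposure(rng_expo, len(CN_NAMES) - 2, latent, e),
            "CN1": _planted_exposure(rng_expo, len(CN_NAMES) - 2, 1.0 - latent, e),
        },
        n,
    )
    scar_mean = 10.0 + 20.0 * e * latent
    scar = pd.DataFrame(
        {"scarHRD": rng_expo.gamma(_GAMMA_SHAPE, scar_mean / _GAMMA_SHAPE)}
    )
    for df in (sbs, idm, cn, scar):
        df.index = sample_ids

    informative = {
        name: [f"{name}_G{g:04d}" for g in range(config.n_informative_per_layer.get(name, 0))]
        for name in config.n_genes_per_layer
    }
    truth = CohortTruth(
        latent_hrd=pd.Series(latent, index=sample_ids, name="latent_hrd"),
        informative_genes=informative,
        tumor_labels=labels,
    )
    exposures = ExposureSet(
        classes={"SBS": sbs, "ID": idm, "CN": cn, "scarHRD": scar},
        tumor_labels=labels,
    )
    return exposures, truth


def generate_omics(config: SyntheticConfig, truth: CohortTruth) -> OmicsBundle:
    """Generate the four gene-level omics layers given the cohort truth.

    The first ``n_informative`` genes of each layer are the planted ones
    (they match ``truth.informative_genes``): their distribution shifts
    with the latent HRD level, scaled by ``effect_size``; remaining genes
    are latent-independent noise.

    - CNV: Normal around diploid 2 (SD ``0.25 * noise_sd``), informative
      genes shifted by ``effect_size * latent``; clipped at 0.
    - EXP: log-normal TPM, per-gene log-mean U(1, 3), log-SD ``noise_sd``;
      informative log-means shifted by ``effect_size * latent``.
    - MET: Beta values with concentration 20; informative means move from
      0.3 toward 1 with ``0.25 * effect_size * latent`` (clipped).
    - MUT: Poisson counts, baseline rate 0.1; informative rates scaled by
      ``1 + 2 * effect_size * latent``.
    """
    if len(truth.latent_hrd) != config.n_samples:
        raise SyntheticConfigError("truth sample count does not match config")
    ss = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(ss.spawn(3)[2])
    latent = truth.latent_hrd.to_numpy()
    n = config.n_samples
    e = config.effect_size
    sd = config.noise_sd
    layers: dict[str, pd.DataFrame] = {}

    for name in LAYER_NAMES:
        if name not in config.n_genes_per_layer:
            continue
        n_g = config.n_genes_per_layer[name]
        n_i = config.n_informative_per_layer.get(name, 0)
        genes = [f"{name}_G{g:04d}" for g in range(n_g)]
        shift = e * latent[:, None]  # (n, 1), applied to the first n_i genes
        if name == "CNV":
            vals = 2.0 + rng.normal(0.0, 0.25 * sd, size=(n, n_g))
            vals[:, :n_i] += shift
            vals = np.clip(vals, 0.0, None)
        elif name == "EXP":
            log_mu = rng.uniform(1.0, 3.0, size=n_g)
            logv = log_mu[None, :] + rng.normal(0.0, sd, size=(n, n_g))
            logv[:, :n_i] += shift
            vals = np.exp(logv)
        elif name == "MET":
            mu = rng.uniform(0.2, 0.8, size=n_g)
            mean = np.broadcast_to(mu[None, :], (n, n_g)).copy()
            mean[:, :n_i] = 0.3 + 0.25 * shift
            mean = np.clip(mean, 0.01, 0.99)
            kappa = 20.0
            vals = rng.beta(mean * kappa, (1.0 - mean) * kappa)
        elif name == "MUT":
            rate = np.full((n, n_g), 0.1)
            rate[:, :n_i] *= 1.0 + 2.0 * shift
            vals = rng.poisson(rate)
        layers[name] = pd.DataFrame(vals, index=truth.latent_hrd.index, columns=genes)

    return OmicsBundle(layers=layers)


def generate_cohort(config: SyntheticConfig) -> tuple[ExposureSet, OmicsBundle, CohortTruth]:
    """Convenience wrapper: exposures + omics + truth in one call."""
    exposures, truth = generate_exposures(config)
    bundle = generate_omics(config, truth)
    return exposures, bundle, truth
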