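# Methods

## The aggregated HRD score

The score treats HRD as a latent property expressed through four largely
independent mutational readouts: the flat SBS3 substitution signature, the
deletion-heavy ID6 indel signature, copy-number signatures (CN17 marks
HRD-pattern LOH segments; CN1 marks quiet diploid genomes and
anti-correlates with it), and the scarHRD sum of three genomic-scar counts
(LOH segments, large-scale state transitions, telomeric allelic
imbalance). Signature exposures are taken as inputs — estimating them from
mutation catalogs (NMF deconvolution) or computing scarHRD from SNP-array
segmentation is upstream of this package.

Normalization makes the classes commensurable: within-sample proportions
for the three signature classes, cohort-maximum scaling for the scalar
scarHRD. The ε-threshold weights address tumor-type composition: a class
only earns weight in a tumor type to the degree that samples of that type
actually express it above ε, and rescaling the four weights to sum to 1
keeps scores on a common [0, 1] scale across types. Because each
normalized biomarker lies in [0, 1] and weights are a probability vector,
the score is a convex combination; boundedness holds for any non-negative
input.

Conventions where the formulas are silent:

- A sample with zero total exposure in a class gets normalized exposure 0
  (it contributes no evidence in that class).
- A tumor type whose four raw weights are all 0 falls back to uniform 1/4
  weights, with a warning — preferable to NaN scores.
- The ε indicator is inclusive (≥ ε), and the same ε applies to all four
  classes including the max-normalized scarHRD.
- Median discretization labels ties as negative (strict >), keeping the
  positive class the "high" half.
- Weights are computed over whatever cohort is passed; passing
  training-cohort weights when scoring held-out samples gives train-only
  weighting if leakage matters for a downstream model.

Default ε = 0.1, exposed in `ScoreConfig`.

## Synthetic cohorts

The generator emulates the statistical structure the analysis needs, not
mutational biology. A latent HRD level per sample is drawn from a
two-component Beta mixture (Beta(2,8) for HR-proficient, Beta(8,2) for
deficient, 40% deficient by default), giving the bimodal population that
makes median discretization a meaningful classification target.

Exposures are Gamma distributed (shape 5, so CV ≈ 0.45) — non-negative
and overdispersed like NMF exposure estimates. Each planted biomarker's
mean is a fraction of its class's noise total, `0.05 + 0.225 · effect ·
latent` (CN1 uses `1 − latent`), so after proportion normalization the
planted biomarker rises from ~0.05 toward ~0.5 across the latent range at
the default effect size of 2 — straddling the ε = 0.1 threshold, which
keeps the weight computation non-degenerate. scarHRD has mean
`10 + 20 · effect · latent`.

Omics layers couple their first `n_informative` genes to the same latent
level: CNV adds `effect · latent` to the diploid baseline 2 (Normal noise,
SD 0.25·noise_sd, clipped at 0); expression shifts a log-normal TPM's
log-mean by `effect · latent` (log-SD = noise_sd); methylation moves a
Beta(mean·20, (1−mean)·20) mean from 0.3 by `0.25 · effect · latent`
(clipped to [0.01, 0.99]); mutation counts are Poisson with baseline rate
0.1 scaled by `1 + 2 · effect · latent`. All other genes are
latent-independent noise.

Defaults are desk-scale: 2,000 samples, 3 tumor types, 75 genes per layer
(300 features total), 10 informative per layer, effect size 2, unit noise
SD. What the generator does **not** model: realistic trinucleotide
catalogs, gene–gene correlation structure, batch effects, tumor-purity
confounding, or missingness patterns of real arrays — so passing tests
demonstrate that the chain recovers a planted signal under clean
conditions, not that it would achieve the same metrics on real cohorts.

## Feature selection

Boruta-style all-relevant selection, regression mode: each iteration adds
a freshly permuted shadow copy of every feature, fits a random forest, and
credits a "hit" to features whose impurity importance strictly exceeds the
best shadow's. Cumulative hits are tested two-sided against
Binomial(n_iter, ½) at α = 0.01 with Bonferroni correction over all
original features; significantly many hits confirm, significantly few
reject (and remove the feature from later forests). Undecided features
after `max_iterations` (default 100) are tentative and excluded downstream
by default.

Two choices matter for type-I control and were adopted after the naive
variants failed a pure-noise target:

- **The shadow pool never shrinks.** Shadows of rejected features are
  kept. With few surviving shadows, "max shadow importance" is a low bar
  that the most spuriously target-correlated survivor clears almost every
  iteration — the spurious correlation persists because the target is
  fixed while shadows are re-permuted.
- **Forests use one random split candidate** (`max_features=1`). Greedy
  candidate selection lets trees preferentially reuse the best-correlated
  feature, amplifying its importance gap over shadows; random-candidate
  splits keep importance proportional to marginal association, which
  leaves genuinely informative features (which beat every shadow anyway)
  untouched but removes the amplification that falsely confirmed the
  extreme spurious feature.

Per-layer selection runs independently per omics layer against the HRD
score, on the training split by default (a full-cohort flag exists; note
the leakage caveat).

## Regression model

80/20 split stratified by tumor type (singleton types go to train), then
random-search hyperparameter tuning (default 20 draws: learning rate
log-uniform [0.01, 0.3], depth 3–8, min child weight 1–10, row/column
subsampling 0.6–1) by 5-fold cross-validated RMSE. Boosting rounds are not
drawn: each candidate trains to at most 1,000 rounds with early stopping
(patience 30) on the held-out fold, and the winner refits on the full
training split at its mean best iteration. Ties break toward fewer rounds,
then lower learning rate, then draw order. Features are z-scaled with
train-only statistics (sample SD; constant columns map to 0 with a
warning); missing values — including samples missing an entire layer — are
routed by XGBoost's native default directions, which is also what makes
top-N ablation well-defined.

Evaluation thresholds the **true** score at the full-cohort median to
define binary ground truth, uses the predicted score as the AUC ranking
statistic, and applies the same cutoff to predictions for kappa /
sensitivity / specificity / precision. Strata with one truth class report
missing AUC. Both a global-median and per-tumor-median cutoff policy are
supported.

## Explanation

SHAP values come from exact TreeSHAP on the raw margin scale, where
additivity (row sum + base value = prediction) is exact up to float error.
Global importance is the mean absolute SHAP value per feature, ties broken
by feature ID for reproducible rankings. Per-tumor heatmaps are Pearson
correlations (Spearman behind a flag) between feature values and their
SHAP values within each tumor's test samples; constant columns and tumors
with <3 samples are missing, not 0. Hierarchical clustering uses average
linkage on Euclidean row distances after column-median imputation; node
support is the ordinary bootstrap proportion over column resamples — not
a multiscale-bootstrap AU p-value, so supports are interpretable as plain
resampling frequencies and tend to be conservative for small clusters.
Top-N ablation masks all but the top-N features as missing and re-predicts
with the same trained model, so N = all is bit-exact to the full model and
masking zero-importance features is a no-op.

## Enrichment

Features are ranked by `corr(shap_v, value_v) · 10^importance_v` — sign
from the direction of the SHAP/value relationship, magnitude growing
multiplicatively with global importance. A linear reading
(`corr · 10 · importance`) is available via `exponent=False`; both
preserve the correlation sign, and the exponent form is the default
because it lets importance dominate the ordering. Preranked GSEA uses the
classic weighted KS running sum (weight exponent 1 on |rank|; 0 gives the
unweighted statistic, which is invariant to monotone rescaling). The null
draws random same-size gene sets; p = (1 + #{matching-sign null with
|ES| ≥ |ES_obs|}) / (1 + n_perm), so p ≥ 1/(n_perm+1); NES divides by the
mean |ES| of the matching-sign null; BH adjustment across tested sets.
Set-size window defaults to [5, 500]. A set covering the whole universe is
compared against the uniform ramp so its running sum still returns to 0.
Mann–Whitney association tests (carrier = ≥1 protein-altering mutation)
run per tumor with BH across tumors, skipping groups under 3 samples.

## Problem sizes and determinism

The shipped tests and the acceptance script run at the generator defaults
(2,000 samples, 300 features) and smaller; selection, tuning, and
permutation counts are sized so the whole suite completes in a few minutes
on one CPU. All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`, so every stage is bit-reproducible; reruns of
the pipeline produce identical artifact checksums.

## Known limitations

- Exposure distributions are stand-ins; no public description of real
  exposure distributions was available to match.
- Boruta decisions on borderline features can remain tentative
  indefinitely; downstream exclusion of tentatives is a conservative
  default, not a claim about their relevance.
- The gene-permutation GSEA null ignores inter-gene correlation, as all
  preranked permutation schemes do.
- Bootstrap support on few rows (tumor types) is coarse; with B
  replicates, supports are multiples of 1/B.
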