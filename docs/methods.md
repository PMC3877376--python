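# Methods

This note documents the statistical models behind `melprs`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that make results reproducible
bit for bit.

## The weighted polygenic risk score

For a panel of J biallelic SNPs with risk-allele dosages
`g_ij ∈ {0,1,2}` and per-allele log odds ratios `w_j`, the score is the
inner product `PRS_i = Σ_j w_j g_ij`. The default panel is the eleven
GWAS-replicated melanoma variants with their published risk alleles and
allele frequencies; the default weights are the natural logs of the
published pooled per-allele odds ratios. Two caveats are deliberate,
documented defaults rather than claims about truth:

* The published frequency column is a *minor*-allele frequency. The
  default configuration treats it as the risk-allele frequency, but for
  several panel SNPs the risk allele is plausibly the major allele (the
  published per-person totals of 2–19 risk alleles, centred near 10–11,
  are not reachable if every risk allele is minor — under the default
  frequencies the total-count distribution is centred near 7 and the
  ≥15-allele band has probability ≈ 3.6 × 10⁻⁴ per person). Users with
  real orientation information should override `risk_allele_freq` per SNP.
  The pipeline therefore fits the ≥15-vs-≤6 band contrast only when both
  extreme bands are populated and otherwise emits an explicit
  "not estimable" row.
* The original external weights (from prior studies) were never printed;
  pooled-OR weights are the stand-in. Any weight vector can be supplied
  via `SnpPanel.with_weights` or a panel YAML/JSON file.

Missing dosages follow one of two policies: `mean` (default) imputes
`2 × risk_allele_freq`, keeping the modelled n aligned with covariate
availability rather than genotyping gaps; `drop` flags individuals with
any missing SNP and excludes them from fits. An individual missing every
SNP always gets a missing score.

Groupings: tertile cutpoints are the 1/3 and 2/3 quantiles of the
reference sample (by default the same study sample, cases plus controls;
a `reference_scores` argument switches to pooled or external references).
Quantiles use linear interpolation between order statistics
(`numpy.quantile`, `method="linear"`) so cutpoints are reproducible
exactly; scores at or below a cutpoint fall in the lower group. The
top-5% split flags scores strictly above the 0.95 quantile.

## Association models

All models are maximum-likelihood logistic regressions (statsmodels
`Logit`, Newton iterations). Per-SNP models are additive in dosage and
unadjusted. PRS models come as continuous (per-unit score), tertile
(two indicators, T3-vs-T1 reported with T2 retained in the fit), band,
and top-5%. Adjustment sets follow each study template exactly: the
discovery scheme uses sex, age, skin, eye and hair colour and tanning
ability; the all-female cohort uses age, hair colour, tanning and family
history; the all-male cohort uses age, eye and hair colour and family
history. Age enters linearly in years; categorical traits enter as
indicator blocks (first level reference), not linear scores — the level
count then never changes the model family. Requesting a covariate a
scheme lacks raises an error naming the scheme; nothing is imputed.

Inference is Wald throughout: `CI = exp(β̂ ∓ 1.959964·se)`, two-sided
normal p-values. This matches the `OR (95% CI)` presentation convention
and is exactly what the meta-analysis layer inverts. Non-convergence and
separation raise `SeparationError` rather than returning estimates with
unreliable standard errors.

`variance_explained` is the squared Pearson correlation between the score
and an ordinal trait coding (1..k, fairest level first), the convention
used to check the PRS–pigmentation calibration below.

## Random-effects meta-analysis

Per-study log-ORs `θ_i` with variances `se_i²` are pooled with the
DerSimonian–Laird moment estimator:

    Q   = Σ w_i (θ_i − θ̄_FE)²,  w_i = 1/se_i²,  df = k − 1
    τ̂²  = max(0, (Q − df) / (Σw − Σw²/Σw))
    θ̂   = Σ w*_i θ_i / Σ w*_i,  w*_i = 1/(se_i² + τ̂²)

I² = max(0, (Q − df)/Q) × 100. With τ̂² = 0 the pool equals the
fixed-effect inverse-variance mean; with one study it is the identity.
Printed `OR (95% CI)` rows are inverted via
`se = (ln hi − ln lo)/(2·1.959964)`; recomputation from rounded inputs
reproduces published pooled columns to about ±0.01–0.02 on the OR scale
and within ~1.5 points on I², which is the tolerance the tests encode.
An independent cross-check against
`statsmodels.stats.meta_analysis.combine_effects` (method `chi2`) agrees
to 1e-8 on pooled effect, SE and τ².

## Discrimination

AUC is the Mann–Whitney estimator via midranks (ties count one half);
an exhaustive all-pairs oracle and `sklearn.roc_auc_score` agree to
machine precision in the tests. Paired model contrasts use DeLong's
placement-value covariance; single-model CIs use the same machinery with
one score column. Two caveats the tests make explicit:

* AUCs are in-sample (apparent), matching the original procedure; no
  cross-validation is applied by default.
* For *nested* in-sample fits the apparent AUC can only increase, so the
  DeLong test of a nested contrast is conservative under the null (its
  p-values are right-shifted, not uniform). The suite asserts
  non-over-rejection rather than uniformity.

The model suite fits all five models on the complete-case subset for the
richest model, so every contrast is paired on identical individuals.

## The synthetic-cohort generator

The generator exists to give every downstream stage a realistic, fully
known truth; its defaults are the study conditions, not tuning knobs.

* **Genotypes**: per SNP, two Bernoulli(p) draws summed — Hardy–Weinberg
  proportions (p², 2pq, q²) — with SNPs mutually independent, matching a
  panel selected to avoid linkage disequilibrium.
* **Disease**: `P(Y=1) = logistic(β₀ + Σ_j β_j g_ij)` with `β_j` equal to
  the panel weights by default, so the true per-unit-PRS log-OR is
  exactly 1. Cases and controls accrue by rejection sampling until the
  exact target counts are reached (default sizes 1,804/1,025, 317/3,376
  and 177/2,251). β₀ defaults to −2.5 (population case rate ≈ 0.19 under
  the default effects), chosen once for sampling efficiency; logistic
  odds ratios are invariant to both the intercept and outcome-dependent
  sampling, so estimands are unaffected. Unattainable targets fail
  explicitly after a bounded number of draws.
* **Covariates**: ages are normal with the published per-group means and
  SDs; sex is ~59% male in the discovery scheme and constant in the
  single-sex cohorts; family history is Bernoulli with the published
  case/control rates (independent of genotype — it is an adjustment
  covariate with no specified generative link to the PRS). Pigmentation
  traits (skin, eye, hair colour, tanning) are cut from a latent
  "fairness" score `√r²·z_PRS + √(1−r²)·ε` at fixed normal quantiles
  matched to the published control marginals, with `r²` the target
  squared correlation between trait and PRS (default 0.03, inside the
  reported 1–3.6% range; categorical cutting attenuates the realised
  value slightly). Covariates a scheme does not collect are explicitly
  missing.
* **Determinism**: one master seed spawns per-study seeds through
  `numpy.random.SeedSequence`; the same seed yields bit-identical
  cohorts and byte-identical pipeline output files.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: linkage disequilibrium and imputation
uncertainty (dosages are exact integers); direct effects of pigmentation
or other phenotypes on disease (all risk flows through genotype, so
simulated phenotype-model AUCs — e.g. ~0.57 for the sex+age+pigmentation
model — sit well below the ~0.64 observed in real cohorts, while the
orderings between nested models are preserved); population structure;
nevus phenotypes; and gene–gene or gene–environment interaction.

## Reclassification

Predicted risks are binned at 0.20 and 0.50 (boundaries assigned upward,
so 0.50 is high risk). For events and non-events separately, "up" is any
move to a higher category. The event component is `(up_e − down_e)/n_e`;
the non-event quantity is stored as `(up_ne − down_ne)/n_ne` — the
printed orientation, subtracted inside the total — because that is the
only reading under which the published triple (0.1220, 0.1111, 0.0109)
is internally consistent; `nri_nonevents_signed` exposes the
conventional sign. The z-test is Pencina's:
`NRI / sqrt((up_e+down_e)/n_e² + (up_ne+down_ne)/n_ne²)`. IDI is the
difference in mean predicted-probability change between events and
non-events, with a two-sample paired-difference z-test. Individuals
lacking a category under either model are excluded listwise.

## Problem sizes used in the checks

Calibration and recovery checks run at sizes chosen to keep Monte-Carlo
error well inside the asserted bands: HWE proportions at n = 50,000
(within three binomial SEs); type-I error of the per-SNP Wald test over
400 seeded replicates of 250/250 cohorts (±2 percentage points around
5%); CI coverage of the simulation truth over 100 seeded replicates at
2,000/2,000 (single SNP) and 1,000/1,000 (per-unit PRS), asserting ≥90%
coverage; model-ordering checks (AUC₅ ≥ AUC₄, AUC₂ > AUC₁) over six
full-size discovery-cohort replicates; and the DeLong-vs-bootstrap
comparison with 10,000 resamples at n = 120.
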