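# Methods

## Overview

`pwaskit` implements a summary-statistics proteome-wide association
pipeline: cis-genetic prediction models for protein abundance are trained
in a small genotyped tissue cohort and applied to GWAS summary statistics
through a weighted Z statistic, followed by FDR control, novelty
annotation against known risk loci, and approximate conditional analysis.
A synthetic-data module generates all inputs with recorded ground truth so
that each stage is testable against independent oracles.

## Synthetic data model

**Genotypes.** Variants are organized in loci (one per gene). For each
locus, two latent haplotype vectors follow a first-order autoregressive
Gaussian process across variants with adjacent correlation `ld_rho`
(default 0.5); thresholding each haplotype at `Φ⁻¹(1 − MAF)` yields hard
genotypes in Hardy-Weinberg proportions with the target allele frequency
(drawn uniformly from `maf_range`, default 0.05–0.5). Imputation
uncertainty is emulated as posterior-mean-like shrinkage toward `2f` plus
Gaussian noise, clipped to [0, 2]; because clipping biases any closed-form
noise scale, the noise SD is solved numerically per variant so the squared
correlation between dosage and hard genotype equals the variant's tagged
imputation R² exactly on the realized sample. The tissue panel (n = 120 by
default, matching the reference-cohort design the pipeline targets), the
LD reference panel (n = 500) and any GWAS cohort are independent draws
from the same population, sharing variant metadata.

**Proteome.** Per protein, the latent log2 abundance is

    √h2_cis · (standardized cis genetic score)
    + √factor_share · (hidden-factor term) + noise,

with total variance 1. The genetic score uses `n_causal_snps` variants
drawn from the gene's ±500 kb window with standard-normal weights; the
hidden-factor term projects `k_hidden` shared standard-normal factor
scores through per-protein loadings. Reported intensity is
`2^(latent + baseline)` with per-protein baselines ~ N(20, 1) on the log2
scale (typical mass-spec reporter magnitudes). Missingness is
intensity-dependent: each entry is missing with probability
`logistic((c − latent)/0.5)`, with the cutoff `c` solved by root finding
so the overall missing fraction matches `missing_rate`. This
left-censoring flavor reproduces the detection-limit mechanism that
motivates the 80%-detection filter; it does not model peptide-level or
batch-structured missingness.

**Trait and GWAS summary statistics.** The trait is a quantitative
liability: `y = Σ_p γ_p · g_p + ε`, where `g_p` is protein *p*'s genetic
score scaled to unit variance and `γ_p` is nonzero for a
`prop_causal_proteins` fraction of proteins (drawn N(0, `gamma_sd`)). The
Z statistic consumes only `β/se`, so a quantitative liability is
interchangeable with log-odds effects for calibration purposes. Two
generation modes:

* **cohort** — an independent cohort of `n_gwas` individuals is simulated,
  the liability built explicitly, and per-variant marginal `β, se` come
  from single-variant least squares;
* **analytic** — per locus, marginal Z vectors are drawn from
  `N(√n · R·λ, R)` with `R` the reference dosage correlation matrix and
  `λ` the standardized joint effects implied by the truth; `β = Z · se`
  with `se = 1/(σ_s √n)`. This is the standard multivariate-normal model
  of marginal Z given LD, exact under the null and fast at desk scale.

`inject_index_signal` adds `R·z·e_index` to a locus Z vector, creating a
locus whose apparent signal is entirely attributable to one index variant
— the canonical conditional-analysis fixture.

What the generator does **not** emulate: haplotype/recombination-map
realism, population structure or admixture, case-control ascertainment,
batch-structured proteomic artifacts, and trans-pQTL effects. Passing
tests therefore demonstrate the statistical machinery is correct under
the stated model, not that real-data confounders are handled.

## Genotype QC and harmonization

Variant filters run in a fixed order so removal counts are deterministic:
call rate ≥ 0.95 → allele-frequency consistency with an external
reference (|panel freq − ref freq| ≤ 4 binomial SEs at the reference
frequency; a concrete, testable rendering of the usual ">4 SD" screen) →
Hardy-Weinberg (1-df chi-square on rounded hard calls, p ≥ 1e-6;
monomorphic variants pass by convention) → MAF strictly > 0.05 →
imputation R² ≥ 0.8. Samples with hard-call rate < 95% are removed.
Harmonization with GWAS summary statistics intersects variants, flips
`β` sign and frequency where the allele pair is swapped, and drops
incompatible pairs as well as strand-ambiguous pairs (A/T, C/G) with
MAF > 0.40 (the usual harmonization default, since those cannot be
oriented reliably near MAF 0.5).

## Proteome normalization

Fixed chain: detection filter (protein kept if non-missing in ≥ 80% of
samples; optional autosome restriction) → log2 → across-sample quantile
normalization (each sample's quantile function interpolated onto a common
grid, averaged, and read back at each sample's ranks, ties averaged) →
per-protein rank-based inverse-normal transform with the rankit offset
`(r − 0.5)/n` (the common eQTL convention) → OLS residualization on age,
the top 3 genotype principal components and `k` principal-component
hidden factors (default 15). PCs replace a variational-Bayes latent
factor model: top PCs of the standardized proteome are the standard
lightweight substitute for hidden technical confounders, and a sweep
utility over k ∈ {5, 10, 15, 20, 25} reproduces the factor-count
selection curve. Missing entries are median-imputed only inside factor
estimation and residualization, and every imputed cell is counted in the
returned log — nothing is filled silently.

One caveat established during development: the full chain is *not*
numerically idempotent. Re-running quantile normalization after the
per-protein inverse-normal transform can flip cross-sample ranks (and
introduce ties), so "re-run equals original" holds only up to re-ranking.
Quantile normalization and the inverse-normal transform are each exactly
idempotent on their own output, and the tests assert precisely that.

## Cis prediction models

For each protein, variants within gene body ± 500 kb (inclusive bounds,
window anchored on the gene, not the TSS) are candidate predictors.
Dosages are standardized; an elastic net with L1/L2 mixing 0.5 minimizes
`(1/2n)‖y − Xb‖² + λ(0.5‖b‖₁ + 0.25‖b‖²)` with λ chosen on a 25-point
geometric grid (from the data-driven λ_max down 2 decades) by 5-fold
cross-validated MSE, minimum rule — the minimum rule rather than 1-SE
because it maximizes model yield. Performance is estimated by nested CV:
an outer seeded 5-fold split, λ re-selected on each training 4/5, and
R = Pearson correlation between observed residuals and the pooled
out-of-fold predictions, with the t-test p (df = n − 2). Models are
retained only with R > 0.1 and p < 0.05 (both strict), then refit on all
samples; standardized weights are mapped back to the per-allele scale.

A property worth knowing: under the null, pooled out-of-fold correlations
are biased *negative* (the familiar cross-validation anti-correlation),
so the two-sided p alone is anticonservative in the wrong tail. The
retention gate R > 0.1 ∧ p < 0.05 is one-sided in effect and its measured
null retention rate is ~0–2% at n = 120, which is what matters for model
yield; tests assert calibration at the gate level.

## Association statistic

`Z_p = Σ_s w_sp (σ_s/σ_p)(β_s/se_s)` with σ taken from a designated LD
reference panel: `σ_s` the dosage SD (n − 1 denominator) and
`σ_p = √(wᵀΓw)` with Γ the dosage covariance restricted to the model's
variants (covariance is never computed outside within-model variant
sets). Model variants missing from a GWAS are dropped *without*
renormalizing remaining weights (the convention of the summary-statistic
family this follows), with the drop count reported per result. p-values
are two-sided normal tails; BH FDR is applied separately within each
phenotype; output ordering is deterministic (phenotype, p ascending, ties
by protein id). A gene is a novel locus when every known risk variant on
its chromosome is ≥ 1 Mb from the gene boundary (distance 0 inside the
gene body; other chromosomes count as infinitely far).

The statsmodels-style surface is `PWAS(model_db, gwas, ld_reference,
known_variants, annotation).fit() → PWASResults` with `.table`,
`.significant()`, `.summary()` and `.conditional()`.

## Conditional analysis

Operating in standardized Z space with se held fixed (the downstream
statistic consumes only β/se, and this form is exactly testable against a
joint-regression oracle):

    z_{s|C} = (z_s − R_sC R_CC⁻¹ z_C) / √(1 − R_sC R_CC⁻¹ R_Cs)

for each non-index variant s, index set C within ±1 Mb of a known risk
variant. Index variants with pairwise |r| > 0.9 are pruned (smallest p
kept) before inversion; variants with residual variance < 0.01 are
flagged fully explained and set to 0 (numerical guard). β is replaced by
`z_cond · se` and the association re-run; independence is declared at
adjusted p < 1e-4. Attenuation is reported as `1 − |Z_adj|/|Z_marginal|`.
This is an approximation to the allele-count algebra of full conditional
and joint analysis; it agrees with individual-level joint least squares
to |ΔZ| < 0.1 at n = 20,000 in the oracle tests.

## Reporting

Protein-vs-RNA agreement uses Spearman rho (Pearson on average ranks)
with the t-approximation p and a Fisher-z 95% CI (SE `1/√(n−3)`), with
pairwise deletion of missing entries and per-protein n reported. The CI
is validated by coverage simulation (95% ± 2% at rho ≈ 0.29, n = 120),
not against any external table. PWAS/TWAS comparison joins on gene ids
and reports sign concordance and joint significance counts.

## Pipeline, determinism, problem sizes

`run_pipeline` executes simulate → qc → preprocess → train → associate →
condition → report, writing plain-text TSVs plus a JSON manifest with
per-stage input hashes; unchanged stages are skipped on re-run. One
global seed fans out to per-stage seeds by fixed offsets; identical
configuration yields bit-identical outputs.

Test and acceptance problem sizes are chosen for single-CPU desk scale:
oracle cohorts of 20,000 individuals, 60–130 proteins per training sweep,
≥ 1,000 protein-phenotype tests for null calibration (one trained model
set × replicate analytic GWAS draws), 10,000-resample permutation and
2,000-replicate coverage checks for the correlation utilities. These
sizes put Monte-Carlo error comfortably inside the asserted tolerances
(e.g. SE of a variance estimate over 1,000 Z values ≈ 0.045 against a
[0.9, 1.1] band).

## Known limitations

* Analytic GWAS mode draws finite-sample Z with the *reference-panel* LD;
  using a different panel for association than for generation introduces
  LD-mismatch noise, as it does with real data.
* The conditional analysis holds se fixed and ignores effective-sample-
  size differences between variants; fine for the Z-consuming statistic,
  not a replacement for full joint effect-size estimation.
* Hidden-factor correction by principal components can absorb genuine
  broad genetic signal if cis effects are widespread and correlated.
* The simulator's single-scalar GWAS n and homogeneous population omit
  per-variant sample sizes and ancestry structure.
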