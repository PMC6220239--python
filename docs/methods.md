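# Methods

This note documents the models implemented in `eduwas`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that affect results.

## Exposure scoring

Educational attainment is an ordinal 7-level variable. Analyses use its
ridit score: within a stratum with category proportions `p_1..p_7`,
category `k` receives `R_k = Σ_{j<k} p_j + p_k/2`. Scores are in (0, 1),
strictly increasing over represented categories, and have proportion-
weighted mean exactly 0.5 per stratum. Strata default to sex × birth-year
decades because educational opportunity changed strongly across birth
cohorts, differently for men and women; the decade width is configurable
and strata below 10 samples are merged with the adjacent birth bin (a
warning is emitted). Ridits are pooled across cohorts by default when a
combined table is supplied; per-cohort scoring is obtained by calling the
transform per cohort.

Smoking phenotypes: pack-years = (cigarettes/day ÷ 20) × years smoked;
plasma cotinine ≥ 15 ng/mL classifies active smoking, [1, 15) second-hand
exposure, < 1 unexposed (boundaries inclusive on the left); the
methylation smoking score is `Σ_k w_k m_ik` over externally supplied
per-CpG weights, on raw beta values by default (a z-scoring flag exists).
Maternal-smoking questionnaire answers are reconciled between co-twins:
a definite yes/no fills the co-twin's missing/unknown answer, a yes-vs-no
conflict sets both to missing.

## Site-wise models

Each CpG's beta value is regressed on the ridit exposure plus covariates.
Model 1: sex, age, array row and bisulphite plate (dummy-coded), white-
blood-cell percentages (the cell-column set is configurable per cohort,
e.g. monocytes + granulocytes where differentials are incomplete).
Model 2 adds smoking status (3 categories); model 3 adds BMI. Subsets:
never smokers, and never smokers with cotinine < 15 ng/mL ("cotinine-
clean"). Missing covariates are handled by listwise deletion; the minimum
complete-case count defaults to 30 (a repository choice — results at
smaller n would be dominated by a handful of samples). p-values use the
normal reference, which matches the downstream z-based correction; at the
cohort sizes the pipeline targets (≳ 600) the difference from the exact t
reference is negligible except in the extreme tail, which is why the
family-wise error simulations are run at full cohort sizes.

Family clustering: the default is a CR1 cluster-robust sandwich on the OLS
fit (point estimates identical to OLS); an exchangeable working-
correlation variance — `V = σ²A⁻¹(Σ_g X_g'R̂_g X_g)A⁻¹` with a moment
estimate of the common within-family residual correlation — is available
as an option. When every family has a single member, no within-family
correlation is estimable and both estimators deliberately return the
classical OLS standard error (a singleton-cluster sandwich would be an
HC-type heteroskedasticity-robust estimator instead, which is not what an
"independence model" means here).

The genome-wide path shares one design matrix across CpGs and solves the
normal equations for all sites at once; per-site fits are used only for
sites with missing beta values. Rank-deficient designs (e.g. constant
exposure within a subset) fail per site with a log entry and the run
continues.

## Bias and inflation of test statistics

Genome-wide z statistics are modelled as a three-component Gaussian
mixture; the centre component under the ordering constraint
`μ₁ ≤ μ₀ ≤ μ₂` is the null, and its posterior-median mean/sd are the bias
and inflation. Corrections: `z' = (z−μ₀)/σ₀`, `SE' = SE·σ₀`,
`effect' = effect − μ₀·SE`, p from the two-sided normal on `z'`.

The sampler is Gibbs with conjugate steps: Dirichlet on weights, normal
on means with truncation enforcing the ordering, inverse-gamma on
variances. Identification required two deliberate prior/structure
choices beyond the textbook defaults:

* **Dirichlet(90, 5, 5)** on the weights (null-dominant). With a flat
  Dirichlet the decomposition of a pure shifted/scaled Gaussian is weakly
  identified: a narrow outer component parked at ±1σ can absorb flank
  mass and bias (μ₀, σ₀) by up to ~0.1.
* **σ-ordering**: `σ₁, σ₂ ≥ σ₀`, sampled from truncated Gamma full
  conditionals on the precisions. True associations add spread on top of
  the null, so a signal component tighter than the null is implausible;
  the constraint removes the flank-stealing mode entirely. Outer means
  have priors N(∓4, 2²) truncated at μ₀.

With these defaults the recovery error over bias ∈ {0, 0.1, 0.3} ×
inflation ∈ {1, 1.2, 1.5} (50k statistics) is below 0.05 for both
parameters, while 10% true signal at |μ| = 4 still yields inflation ≈ 1
(genomic-control λ ≈ 1.26 in the same setting). All priors and the
ordering flag are configurable; chain length defaults to 5000 iterations
with 2000 burn-in, with shorter chains adequate at genome scale because
the posterior is extremely concentrated (the test suites use 400–800
iterations). Point estimates are posterior medians; a split-chain R̂ above
1.1 on μ₀ or σ₀ flags non-convergence in the returned fit.

The genomic-control diagnostic `λ = median(z²)/0.4549` is reported for
comparison only.

## Meta-analysis, multiple testing, power

Fixed-effects inverse-variance combination per CpG; Cochran's Q is
reported as a heterogeneity diagnostic (no random-effects model — the
design targets homogeneous Dutch cohorts). Bias/inflation correction is
applied per cohort before combining and re-estimated once more on the
meta statistics; both steps can be disabled. Significance is Bonferroni
at the realized number of tests.

Power for a single predictor explaining R² of the outcome variance uses
the noncentral-F distribution: `f² = R²/(1−R²)`, `λ = f²·N`, critical
value from F(1, N−2) at the two-sided α. The smallest N with power ≥
target is found by bisection; a Fisher-z approximation
(`N = ((z_{α/2}+z_{power})/atanh r)² + 3`) is available. For R² = 0.01,
α = 10⁻⁷, power 0.8 the noncentral-F answer is N = 3781; published
analyses of the same configuration quote values a percent or two lower
depending on the approximation used.

## Mediation

Difference-in-coefficients: total (model 1) minus direct (model 2) is the
smoking-mediated part; under linear no-interaction models this equals the
product-of-coefficients decomposition. The proportion mediated is
reported only when |total| ≥ 0.001 on the beta scale (ratio blow-up
guard) and flagged on sign reversal. Point estimates are deterministic;
percentile bootstrap CIs (default 500 seeded resamples of individuals,
refitting both models) are available on request.

## Twin design

Complete same-family pairs are formed with deterministic within-pair
ordering (by sample id) so difference signs are reproducible. The
within-pair regression of Δmethylation on Δridit includes an intercept by
default (allows birth-order-like asymmetries; a no-intercept variant
exists) and optionally adjusts for the Δ of a numeric smoking coding
(never = 0, former = 1, current = 2 — a repository convention).
Smoking-concordance strata: discordant (current vs never),
concordant-current, concordant-never; all other combinations are excluded
from stratified runs. The estimator is numerically identical to a
pair-fixed-effects regression on the stacked data and invariant to
flipping any pair's ordering.

## Cross-study comparison

Pearson correlation of effect sizes over CpGs matched by id, optionally
restricted to the external study's significant set; external effects are
used as supplied (no rescaling of group differences). Venn overlap counts
partition the union of significant sets. SNP proximity uses a symmetric
closed-interval rule |pos_CpG − pos_SNP| ≤ 500 kb on the same chromosome
after filtering SNPs at p < 10⁻⁴; the anchor/boundary convention is a
documented choice and is tested at the boundary.

## Cis eQTM

Transcript filtering is ordered: detection (a read in ≥ 1% of samples)
first, then removal of the bottom 1% by log-CPM variance (ceiling count;
ties broken by transcript id). log-CPM = log₂((count + 0.5)/(library + 1)
× 10⁶); the pseudocount is a documented choice. Pairs are CpG–transcript
combinations within 100 kb (closed interval) of the CpG, measured to the
transcript start by default (nearest-edge option). Per pair, log-CPM is
regressed on methylation plus observed covariates (age, sex, cell
percentages) — a simplification relative to latent-factor adjustment,
noted as a fidelity limitation. Cohorts are combined with the same
fixed-effects machinery; Bonferroni uses the realized pair count.

## Synthetic data: what it emulates and what it does not

Per cohort the generator draws demographics from profiles mirroring four
Dutch population biobanks (sample sizes 2199/668/608/704, sex ratios,
age and BMI distributions, birth-year ranges, smoking-status and
education distributions). Education→smoking dependence is a logistic
model on the ridit score whose intercept and slope are calibrated by
root-finding so that the marginal current-smoking fraction and the
education–smoking correlation (default −0.11) are matched exactly over
the discrete category distribution; infeasible targets raise an error
naming the achievable range.

Methylation is generated on the beta scale,
`m = clip(base + β_direct·ridit + β_smk·I(current) + covariates +
familial + ε, 0, 1)`, with base levels uniform in [0.1, 0.9] so clipping
stays below 1% of entries (the clipped fraction is reported). Causal
CpGs (default 200 of 10k) have total effects of 0.006–0.060 per ridit
unit, 76% positive; a configured fraction (default 0.28) of each total
effect is routed through current smoking by setting
`β_smk = mediated/γ`, where γ is the education→smoking path coefficient.
γ differs between cohorts (different marginals), so the generator holds
the *total and direct education effects* fixed across cohorts and lets
the smoking coefficient absorb the cohort difference — a simulator design
choice that makes the per-CpG ground truth cohort-invariant. Because the
smoking indicator is a finite random draw, the estimand of an unadjusted
education model is `β_direct + γ̂·β_smk` with γ̂ the realized projection;
the truth table therefore also records `beta_total_realized`, which is
the correct target for conditional-unbiasedness checks. Separate
smoking-only CpGs (default 300) carry current-vs-never effects uniform
in [−0.18, 0.07]. Former smokers carry no methylation effect by default.

Twin cohorts consist of complete MZ/DZ pairs; a pair-shared familial
factor and an additive genetic factor (shared fully in MZ, at half in DZ)
enter both the methylation residual (configurable variance shares, random
per-CpG loading signs) and, optionally, the latent education score —
turning on the latter creates exactly the shared-confounding scenario the
twin design is meant to remove. Expression counts are overdispersed
Poisson with log₂ mean linear in (centred) methylation for designated cis
pairs; centring keeps counts out of the low-count regime where log-CPM
saturates, so the configured slope is the estimand.

One seeded generator stream is used per cohort (spawn-key seeding), so
adding cohorts never changes earlier cohorts; a separate stream generates
the cohort-invariant per-CpG truth. Identical (config, seed) reproduce
byte-identical outputs.

Not emulated: array-level noise (probe chemistry, detection p-values,
normalization artefacts), realistic LD/meQTL structure, bimodal beta
distributions, cell-type interactions, and cohort-specific batch
pathologies. Passing tests on this generator therefore demonstrate the
statistical machinery (estimators, corrections, error control), not
robustness to array-specific artefacts; conclusions about real data
require the upstream QC/normalization the pipeline assumes as input.

Defaults that matter: noise sd 0.04 on the beta scale (residual sd after
covariates typical of whole-blood 450k data, giving per-cohort SEs of
~0.002–0.006 like published cohort EWAS); covariate loading scales (age
1.5e-4/year, sex 0.004, cells 3e-4/%, plate 0.002, row 0.001) chosen so
technical and biological covariates are present but do not dominate;
between-cohort effect jitter defaults to 0 (homogeneous effects — the
fixed-effects model's assumption; the dial exists for sensitivity
analyses).

## Problem sizes in the shipped suites

The end-to-end suites run the mixture-recovery grid at 50k statistics ×
10 replicates per cell with 400-iteration chains (the posterior sd at
that scale is ≪ the 0.05 tolerance), effect-recovery and family-wise
error checks on the full default dataset (4 cohorts, 10k CpGs, 20 null
replicates), mediation recovery at n = 5000, and the twin scenarios at
492 MZ + 247 DZ pairs × 20 replicates. These sizes keep the whole suite
in the tens of minutes on a single CPU while leaving Monte-Carlo error
well inside every stated tolerance.

## Known limitations

* The mixture's bias estimate absorbs directionally skewed weak signal
  (e.g. 76%-positive effects at small cohort sizes); the meta-level
  re-correction partly compensates, and both fits are reported so the
  effect is visible.
* The exchangeable variance option assumes a common within-family
  correlation across families and sites.
* The eQTM stage substitutes observed covariates for latent-factor
  adjustment.
* Bonferroni is the only multiplicity control (by design); external FDR
  lists are treated as inputs.
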