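# Methods

## Problem and model

`pleiopath` asks, for each candidate variant G, which causal structure
best explains its joint association with a continuous brain-imaging
mediator M (fractional anisotropy, FA, of a white-matter tract) and a
smoking phenotype Y (binary current-vs-never smoking status, SS, or
continuous cigarettes per day, CPD), adjusting for covariates Z:

* **model 0 — horizontal pleiotropy.** G affects M and Y through
  independent paths; M ⟂ Y | (G, Z).
  Pr(M, Y | G, Z) = Pr(M | G, Z) · Pr(Y | G, Z).
* **model 1 — vertical, G → M → Y.**
  Pr(M, Y | G, Z) = Pr(M | G, Z) · Pr(Y | M, G, Z).
* **model 2 — vertical, G → Y → M.**
  Pr(M, Y | G, Z) = Pr(Y | G, Z) · Pr(M | Y, G, Z).

All component regressions are generalized linear models with additive
dosage coding (G = 0, 1, 2 minor-allele copies): linear for M and for
continuous Y, logistic for binary Y. The covariate set at the pathway
stage is age and sex.

## The three-step discovery procedure

**Step 1 — pleiotropic-variant screen with overall FDR control.** Per
SNP we fit M ~ G + Z and Y ~ G + Z and form the composite-null p-value
p_max = max(p_M, p_Y). p_max is a valid, conservative p-value for the
null "G is associated with at most one of the traits". Benjamini–
Hochberg on the p_max list at target 0.15 controls the overall FDR of
the declared-pleiotropic set. An alternative mode applies BH per trait
and intersects the discovery sets; max-p is the default because its
composite-null guarantee is direct.

**Step 2 — horizontal vs vertical.** We regress Y on (G, M, Z) and read
the Wald p-value of the mediator coefficient. p > 0.05 means the
conditional independence demanded by model 0 is tenable (horizontal);
otherwise the SNP is classified vertical. Conditioning is on one SNP at
a time. A consequence worth knowing: when several causal variants act
on both traits, conditioning on a single SNP leaves the others as
shared causes of M and Y, so the test can find conditional dependence
even under purely horizontal architectures. The single-variant datasets
used in the operating-characteristic simulations avoid this; on real
multi-locus data the classification should be read as "horizontal given
this SNP alone".

**Step 3 — BIC selection between the vertical DAGs.** Each mediation
model's likelihood is the product of its two component fits at their
MLEs (model 1: [M | G, Z] × [Y | G, M, Z]; model 2: [Y | G, Z] ×
[M | G, Y, Z]), and BIC = −2 log L̂ + p log n. Counting intercepts,
slopes and, for every linear fit, its residual variance, the two joint
models have exactly the same parameter count, so the BIC comparison
reduces to comparing maximized likelihoods; the smaller BIC wins.
Linear log-likelihoods use the Gaussian profile likelihood with the MLE
variance (divisor n), so both joints are genuine maximized likelihoods.
|ΔBIC| below 1e-6 returns "indeterminate".

### Identifiability of the BIC comparison (important limitation)

When both components are linear-Gaussian — i.e. whenever Y is
continuous — the two factorizations parameterize the *same* saturated
conditional bivariate normal, one per Cholesky order. The two DAGs are
Markov equivalent, their maximized likelihoods are exactly equal, and
step 3 deterministically returns "indeterminate". This is not a
numerical artifact; it is the standard non-identifiability of edge
direction within a linear-Gaussian Markov equivalence class, and the
test suite freezes it as expected behaviour.

With a binary Y the logistic component breaks the equivalence, but only
weakly: at per-allele effects of ~0.3 and a mediator/outcome cross
effect of 0.5 on the log-odds scale, the Kullback–Leibler separation
between the true model and the best-fitting wrong-direction model
measures at roughly 1e-5 to 1e-7 per observation, so the expected
log-likelihood gap at n = 10,000 is of order 0.1 — selection accuracy
stays near chance at any desk-scale n, approaching certainty only for
cohorts of millions. On real data, decisive selection between the two
directions must therefore come from stronger effects, non-Gaussian
phenotype distributions (a capped, skewed CPD is far from normal), or
external identification assumptions; at these synthetic-Gaussian study
conditions the direction is close to undecidable, and the corresponding
operating-characteristic test documents the measured accuracy rather
than a guaranteed property.

## Mediation decomposition and inference

For the selected vertical model the genetic effect decomposes as
direct (the SNP coefficient of the conditional outcome regression),
indirect (product of the exposure-equation SNP coefficient and the
mediator coefficient of the conditional regression), and total (the SNP
coefficient of the marginal regression of the final outcome). For
all-linear fits with a shared covariate set, total = direct + indirect
is exact OLS algebra and is asserted at 1e-8. With a logistic component
the products live on the log-odds scale and additivity is only
approximate (non-collapsibility), so the identity is not asserted
there.

Indirect-effect inference: the default is a nonparametric subject-level
bootstrap (1000 resamples, percentile 95% interval, seed-reproducible;
resamples with a degenerate binary outcome are redrawn and counted).
The Sobel normal approximation, z = ab / sqrt(a²se_b² + b²se_a²), is
the fast alternative; under the product null it is conservative.
Mediation typing at two-sided 0.05: complementary (indirect and direct
significant, same sign), competitive (significant, opposite signs),
indirect-only (direct non-significant), none (indirect non-significant).

## Synthetic-data generator

The generator emulates the study design end to end so every stage is
testable without restricted data.

* **Genotypes.** Each of two haplotypes is a latent standard-normal
  AR(1) process across SNPs (lag-one correlation `ld_rho`); a haplotype
  carries the minor allele at SNP j when its latent value exceeds the
  (1 − MAF_j) quantile, and dosage is the haplotype sum. Marginally
  every SNP is Binomial(2, MAF) — exact Hardy–Weinberg proportions —
  while `ld_rho > 0` induces local LD. Defaults: MAF 0.2 (a common
  variant), `ld_rho` 0 (independent SNPs unless LD is the point of the
  experiment).
* **Covariates.** age ~ Uniform(40, 69) years (the emulated cohort's
  recruitment range), sex ~ Bernoulli(0.5); default structural effects
  −0.01 per year of age and +0.1 for sex on the mediator scale. Age is
  centred at its midpoint inside the structural equations so intercepts
  read as values at mean age.
* **Traits.** The mediator is Gaussian with σ_m = 1, so SNP effects
  read as SD per allele. Binary outcomes use the logistic link with
  default intercept logit(0.3) (≈ the current-smoker fraction among
  current + never smokers); continuous outcomes are Gaussian with
  σ_y = 1. Exactly one structural model generates each dataset, and
  effects inconsistent with that model are rejected at config
  validation. The non-null SNP burden is centred at its expected dosage
  sum so that adding non-null SNPs does not shift prevalence; an
  all-0/all-1 binary outcome raises a warning.
* **What it does not emulate.** Recombination maps, population
  structure and ancestry PCs, imputation uncertainty, genotyping batch
  effects, the skewed/zero-inflated distribution of real CPD, or
  measurement error in FA. Passing tests therefore certify the
  statistical machinery under clean GLM assumptions, not robustness to
  those real-data features.

## Quality control and phenotype derivation

SNP filters run first, on all subjects — call rate (≤ 5% missing), MAF
(≥ 0.01, minor allele re-identified from the sample), Hardy–Weinberg
equilibrium (1-df chi-square of observed genotype counts against
p²:2pq:q², p ≥ 0.001; an exact conditional mid-p variant is available
behind a flag for low minor-allele counts) — then subjects with > 2%
missing genotypes are dropped. The fixed order is part of the contract;
QC is idempotent. Smoking status maps current → 1, never → 0, past →
missing (rows are kept so the same table serves CPD analyses, which
instead exclude never smokers). CPD recodes values < 1 to 0 and > 60 to
60. The FA screen regresses each tract measure on the smoking phenotype
(age- and sex-adjusted by default; an unadjusted mode exists because
either reading of a univariate screen is defensible) and keeps measures
with a negative coefficient at p < 0.05.

## Association stage

Per-SNP GLM scans with covariates age, sex, and — when the columns
exist — BMI, chip and PC1..PC10, degrading gracefully with a logged
notice. Genome-wide-significant SNPs (p < 5e-8) define peaks; candidate
regions pad peaks by ±250 kb, clip at position 1 and merge overlaps per
chromosome. Coordinates are 1-based inclusive internally; BED exports
convert to 0-based half-open. Non-converged or separated logistic fits
are flagged and excluded from locus ranking.

## Numerical choices

* OLS by least squares with QR-based rank diagnosis; collinear columns
  are named in the error. Logistic fits by damped Newton–Raphson
  (step-halving, warm starts from the covariate-only fit in per-SNP
  scans); |coefficients| > 30 or a singular Hessian flags
  non-convergence/separation. Agreement with statsmodels is asserted in
  the tests at 1e-6 or tighter.
* Wald inference: Student-t for linear fits, normal for logistic.
* BIC ties: |ΔBIC| < 1e-6 → indeterminate. Component-fit failures
  propagate as indeterminate with diagnostics rather than a hard stop.
* All randomness flows from integer seeds through
  `numpy.random.Generator`; per-replicate streams are spawned from a
  master seed via `SeedSequence`, and every writer uses a fixed float
  format, so identical configs reproduce byte-identical bundles.

## Operating characteristics computed by this package

`scripts/acceptance.py` regenerates them from scratch (see README):
the 200-replicate empirical FDR of the step-1 screen at its default
0.15 target (500 SNPs, 50 truly pleiotropic at 0.3 SD/allele on both
traits, n = 2000 — max-p BH lands well under the target, as expected
for a conservative composite-null procedure), and the size of the
step-2 conditional-independence test over 2000 single-SNP model-0
replicates at n = 2000 (close to the nominal 0.05). Simulation sizes
throughout the suite (tens to a few hundred replicates; n from 500 to
10,000) were chosen so the whole suite runs in minutes on one CPU while
keeping Monte-Carlo error well inside the asserted bands.

## Known limitations

* Direction selection between the two vertical models is undecidable
  for continuous outcomes and weakly decidable for binary outcomes at
  realistic effect sizes (see above).
* Step-2 conditioning is per SNP, not on the joint SNP set or a
  polygenic score; with multiple causal variants the horizontal label
  is relative to the conditioning SNP.
* Binary-outcome mediation effects live on the log-odds scale and are
  non-collapsible; totals need not equal direct + indirect.
* The package does not separate causal variants from LD proxies inside
  a window, estimate Mendelian-randomization-style causal effects, or
  test for exposure–mediator interaction (the structural equations
  contain none).
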