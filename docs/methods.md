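# Methods

## The causal model and its assumptions

Two-sample MR treats genetic variants as instrumental variables for an
exposure. A variant i is a valid instrument when it (1) associates with
the exposure (relevance), (2) shares no confounder with the outcome
(independence), and (3) affects the outcome only through the exposure
(exclusion). Under a linear model the per-variant outcome association is

    Gamma_i = theta * gamma_i + alpha_i,

where theta is the causal effect and alpha_i the direct (pleiotropic)
effect that exclusion forbids. Summary statistics give noisy estimates
(gamma_hat_i, Gamma_hat_i) with known standard errors from two
non-overlapping samples. Every estimator in this package is a different
compromise about alpha_i:

- **IVW** assumes alpha_i = 0 for all i. It is the origin-constrained
  WLS slope with weights 1/se_out^2. Fixed-effects SE is
  1/sqrt(sum w gamma^2); the default multiplicative-random-effects SE
  multiplies it by max(1, sqrt(Q/(n-1))), never deflating below fixed
  effects. p-values use the normal reference.
- **MR-Egger** allows a constant mean pleiotropy: a free intercept after
  orienting each pair so gamma_hat_i >= 0. Its consistency needs InSIDE
  (alpha independent of gamma). The coefficient covariance scales with
  the residual dispersion RSS/(n-2) *without* a floor, so the intercept
  test is exactly t(n-2) under the no-pleiotropy null (a floored
  dispersion, as some MR software applies, makes the test conservative
  — measured at ~2.5% type-I here — so the unfloored plain-WLS form is
  used; IVW keeps its explicit floor because its role is to never
  under-report uncertainty).
- **Weighted median** is consistent while valid instruments carry >50%
  of the weight w_i = gamma_i^2/se_out_i^2. The estimate interpolates
  the weighted CDF of sorted ratios at 0.5 using cumulative-midpoint
  positions p_i = (cumsum(w) - w/2)/sum(w). The SE is a parametric
  bootstrap (default 1,000 replicates, seed mandatory — no global RNG
  state).
- **RAPS** models weak instruments and overdispersed pleiotropy:
  Gamma_hat_i ~ N(theta gamma_i, se_out^2 + theta^2 se_exp^2 + tau^2)
  with the n true gamma_i as nuisance parameters. A naive profile
  likelihood is Neyman-Scott biased; the estimator instead solves the
  adjusted profile-score equations (see the `raps` docstring), which
  have exactly zero mean at the truth. tau^2 is solved by monotone
  bracketing inside a 1-D root search for theta started at the IVW
  estimate with an expanding symmetric bracket; the SE is the sandwich
  from per-variant scores with a numerical Jacobian. The Huber variant
  (c = 1.345) replaces psi(t) = t by the clipped psi and uses the
  Gaussian consistency constant delta = E[psi(Z)Z].
- **MR-PRESSO** tests alpha_i = 0 per variant: leave-one-out IVW
  predictions give standardized residuals (expected variance
  se_out^2 + theta_loo^2 se_exp^2); the observed residual sum of squares
  is referred to parametric replicates drawn under the no-pleiotropy
  model (add-one p-values), per-variant residuals are Bonferroni-tested,
  and the distortion test compares the raw-vs-corrected shift against
  shifts from removing random subsets of the same size. Fewer than four
  variants: the result is marked inapplicable and reports print NA, as
  published MR tables do.

Cochran's Q is computed on the Wald-ratio scale with first-order
variances se_out^2/gamma^2 (the convention tied to the IVW estimate; a
second-order option adds theta^2 se_exp^2/gamma^2). Multivariable MR
regresses Gamma_hat on the k exposure columns jointly (no intercept for
IVW, intercept for Egger with t(n-k-1) inference); weights use the
outcome SE only — exposure measurement error is not corrected, a known
limitation of standard MVMR-IVW.

## Instrument selection and harmonization

The pipeline order is: p-value filter (p <= 5e-6, boundary inclusive) →
duplicate removal (smallest p, then smallest se, then first occurrence)
→ greedy LD clumping → harmonization (palindrome removal inside) →
F-filter (F = beta^2/se^2 >= 10, boundary inclusive). Clumping keeps the
smallest-p variant and removes neighbours with r^2 >= 0.001 within
±10,000 kb on the same chromosome; ties break by se then variant id for
determinism; variants absent from the LD reference count as unlinked.
Harmonization aligns outcome records to the exposure's effect allele:
swapped alleles negate the outcome beta, complement alleles are
strand-rescued once, anything else drops as a mismatch, and palindromic
(A/T, C/G) variants are always dropped — no frequency-based rescue,
since the A-vs-T ambiguity cannot be resolved from alleles alone and
outright removal is the simpler, safer rule.

## GSEA

Differential expression uses the empirical-Bayes moderated t: per-gene
pooled variances s_g^2 with d residual df are shrunk toward a prior
(d0, s0^2) fitted by method of moments on log s_g^2 (trigamma inversion;
exactly exchangeable variances shrink to themselves so the ordinary t is
recovered). Genes are ranked by signed moderated t by default — more
stable than log2FC at 3 samples per group — with log2FC selectable.
The enrichment score walks the ranked list: hits add |stat|^p (p = 1)
normalized over hit genes, misses subtract 1/(N - N_hit); the ES is the
signed maximal deviation. Significance comes from a gene-label
permutation null (random same-size sets): with 3 samples per group only
20 sample relabelings exist, far too coarse for p ~ 0.005, so gene
permutation is the only resolution-feasible null at this design size.
The p-value is one-sided within the same-sign side of the null with the
add-one rule, p = (1 + #{same-sign beyond observed})/(1 + #same-sign);
normalizing by all permutations instead would double the type-I rate
(~10% at the 5% level, verified by simulation here). NES divides the ES
by the mean same-sign permuted magnitude; FDR q uses the pooled-NES
tail-ratio procedure, with Benjamini-Hochberg as a selectable
alternative. Significant sets satisfy p < 0.05 AND q < 0.25, strict
inequalities. Reported sets lie within [10, 500] genes after
intersection with the ranked list.

## The synthetic-data generator

`simulate_mr_summary` draws true exposure effects |gamma| ~ U(0.05, 0.3)
(effect alleles oriented exposure-increasing, the biobank protein-GWAS
reporting convention — directional pleiotropy is only a directional
confound under a fixed orientation), exposure SEs ~ U(0.01, 0.02)
(single-variant F well above the =10 bar), and outcome noise at the same
scale unless `binary_outcome_scale` shrinks the outcome side 100-fold to
the ~1e-3 magnitude of linear-probability betas on binary biobank traits
(odds ratios within ~0.5% of 1 — the regime of the coronary-disease
outcomes this suite emulates; true theta is then given on that scale,
e.g. -0.003). Pleiotropy modes: `balanced` (zero-mean alpha),
`directional` (alpha ~ N(scale, (scale/4)^2), InSIDE holding), and
`inside_violating` (alpha correlated with |gamma| through a Gaussian
copula, the regime that breaks Egger). Default instrument count is 20,
typical of protein exposures at sub-genome-wide selection thresholds.
Statistics are generated directly at the summary level — no individual
genotypes — which is sufficient for estimators whose inputs are summary
statistics and orders of magnitude faster; consequently the generator
does not model allele-frequency spectra, population structure, sample
overlap, or LD between the generated effect sizes (LD enters only
through the separate block-diagonal `simulate_ld` used to exercise
clumping). Passing tests on these data therefore demonstrate estimator
correctness under the stated model, not robustness to those unmodeled
features of real GWAS.

`simulate_expression` plants signed log2 shifts for designated gene sets
in cases over an N(7, 1) baseline with noise sd 0.5 at 3 samples per
group — the design size of a small case/control microarray comparison.
It does not emulate probe-level artifacts or normalization; probe
collapse, when needed, is "max absolute statistic per gene".

## Numerical choices and degenerate inputs

- p-values of exactly 0 on input are clamped to the smallest positive
  double and flagged (downstream log transforms).
- Zero-variance genes are floored at 1e-8 and flagged; all-zero ranking
  weights fall back to unweighted hit increments.
- Wald-ratio SE is first-order (se_out/|gamma|); gamma = 0 variants are
  excluded with a log entry rather than propagating infinities.
- RAPS declares non-convergence (rather than returning a value) if the
  profile score has no sign change in an expanded bracket of ±2^60
  spans around the IVW start.
- Add-one rules bound every permutation/simulation p away from zero;
  PRESSO's global p resolution is 1/(n_sim + 1).
- All stochastic routines take explicit integer seeds; identical seeds
  reproduce byte-identical outputs across runs.

## Benchmark problem sizes

The acceptance battery uses 100 random instances for oracle-agreement
checks, 500 replicates for recovery/coverage and pleiotropy-bias
comparisons, 200 for outlier-detection and global-calibration rates,
1,000 for type-I calibration of Q and the Egger intercept, and 100
seeded matrices (600 genes, 10 sets, 500 permutations) for enrichment
power — sizes at which the binomial noise on each reported rate is well
inside the bands being checked.

## Known limitations

- No correlated-instrument (generalized) IVW; clumping is assumed to
  have removed LD.
- OR-scale reporting exponentiates whatever beta scale it is given; for
  linear-probability betas on binary traits the result is an
  approximation valid near the null (the regime simulated here).
- The distortion test reports a p-value but never overwrites the primary
  estimate.
- MVMR conditional F-statistics and Q-minimization estimators are out of
  scope, as are microarray normalization and gene-set retrieval (GMT
  files are inputs).
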