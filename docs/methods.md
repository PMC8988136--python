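# Methods

This note records the statistical models implemented in `mrlab`, the
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions that matter
for reproducing results.

## Two-sample MR

All estimators operate on harmonized per-variant effect pairs
(β_exp, se_exp, β_out, se_out) from non-overlapping cohorts. The
per-variant ratio estimate is θⱼ = β_out,j/β_exp,j with the first-order
delta-method SE se_out,j/|β_exp,j|. Second-order SEs (adding the
exposure-side term) are deliberately not the default: with the strong
instruments this package targets (per-instrument F well above 10) the
correction is negligible, and the first-order form is the dominant
convention.

**IVW.** β̂ = Σwθ/Σw with w = 1/se_θ². Cochran's Q = Σw(θ−β̂)² is
χ²(J−1) under homogeneity; the multiplicative random-effects SE
inflates the fixed SE by max(1, √(Q/(J−1))). The max(1,·) floor means
the test is never anti-conservative relative to the fixed-effect
model; under the null this makes rejection rates run a shade below
nominal (observed ≈ 0.042 at α = 0.05 in the calibration tests), which
we accept as the standard convention.

**Weighted median.** Ratios are ordered and the weighted empirical CDF
sⱼ = (cumsum(w)ⱼ − wⱼ/2)/Σw is linearly interpolated at 0.5. The SE is
a parametric bootstrap (θⱼ* ~ N(θⱼ, se_θⱼ²), 1000 replicates, seeded).

**MR-Egger.** Weighted regression of β_out on β_exp with a free
intercept, weights 1/se_out², after orienting each variant so
β_exp ≥ 0 (allele-coding invariant). Both SEs are inflated by
max(1, √(RSS_w/(J−2))); p-values are normal by default with a
t(J−2) option. The intercept tests directional pleiotropy.

**MR-RAPS.** Maximizes the profile likelihood with standardized
residuals tⱼ(θ, τ²) = (β_out,j − θβ_exp,j)/√(se_out,j² + θ²se_exp,j² + τ²)
under a squared or Huber (δ = 1.345) loss; θ is found by bounded scalar
minimization from three starts, τ² (when overdispersion is on) by the
moment condition mean(t²) = 1 floored at zero, alternated to
convergence; the SE is a sandwich estimate with a numerical derivative
of the total score. In the limit se_exp → 0, τ² = 0 the estimator
coincides with IVW (asserted to 1e-6 in the tests).

**PRESSO-style outlier search.** The observed residual sum of squares
uses leave-one-out IVW predictions, RSS = Σⱼ(β_out,j − θ̂₍₋ⱼ₎β_exp,j)².
The null distribution is simulated parametrically from the fitted
means and observed SEs; the global p is the Monte-Carlo exceedance
probability with the +1 correction, per-variant outlier p-values are
Bonferroni-corrected over J at α = 0.05, and the corrected estimate is
IVW on the non-flagged instruments (the raw IVW is reported alongside).
With n_sim null draws the smallest attainable Bonferroni-corrected
per-variant p is J/(n_sim+1); detection tests therefore use
n_sim ≥ 20·J.

**Steiger.** Per trait, instrument-explained variance is
Σⱼ zⱼ²/(zⱼ² + n − 2). The causal direction is accepted when the
exposure value exceeds the outcome value (ties are rejected); the
p-value compares Fisher-transformed √r² between the two independent
samples.

**Power.** For a binary outcome,
power = Φ(|log OR|·√(N·r²·K(1−K)) − z₀.₉₇₅) + Φ(−|log OR|·√(·) − z₀.₉₇₅).
The second (opposite-tail) term makes power exactly α at OR = 1 and is
numerically negligible at any realistic design point. The formula is a
linear-probability approximation to the logistic score test; the test
suite cross-checks it against an individual-level logistic simulation
at a mid-power design (n = 2000, where approximation error is visible
but below 0.05 absolute) rather than at the headline design point,
where power saturates at 1 and a simulation would be uninformative.

**Multiple testing.** The primary MR analyses use a Bonferroni gate of
0.05/6 (six trait-pair analyses); mediation uses 0.05/11 (eleven
candidate mediators).

## Instruments

Clumping is the PLINK greedy rule: repeatedly take the smallest-p
unassigned variant with p < p1 as an index and assign every unassigned
variant with p < p2, r² ≥ r2 with the index, and within kb kilobases on
the same chromosome. Ties in p break by (chrom, pos) ascending, making
results deterministic. Instrument selection is the strict special case
p1 = p2 = 5e-8 with pruning at r² ≥ 0.001; the distance window
defaults to 10 Mb so that LD, not distance, is the effective criterion
(no published window accompanies the r² < 0.001 convention; the value
is configurable). Variants not covered by the LD panel are dropped
from clumping rather than assumed independent.

Confounder filtering removes instruments annotated (in a user-supplied
variant→trait table standing in for a GWAS-catalog query) to any
blocklisted trait at p < 5e-8.

## Mediation

Indirect = a·b, direct = c − a·b, proportion = a·b/c; the decomposition
identity holds to machine precision because direct is defined by
subtraction. A mediator is significant only when both step p-values
pass the Bonferroni gate, and only significant mediators enter the
combined decomposition (sum of unrounded indirect effects).

Two proportion conventions are exposed: `proportion` (unrounded) and
`proportion_table` (indirect rounded to 3 decimals first, then divided
by the total — the arithmetic used when proportions are quoted next to
3-decimal tables). They can differ in the final digit; published
tables in this literature are not consistent about which is used, so
both are available and the table view uses the rounded convention.

## Cross-trait statistics

**S_Het.** With weights wᵢ = √nᵢ and trait-correlation matrix R, each
nonempty trait subset T scores S(T) = (w_Tᵀ R_T⁻¹ z_T)²/(w_Tᵀ R_T⁻¹ w_T)
with z sign-aligned within the subset (equivalently, |z| with the first
trait's sign), and S_Het is the maximum over subsets, enumerated
exhaustively (exact for the small trait counts this package targets;
feasible to ~10 traits). R defaults to the identity because the
intended use case is non-overlapping cohorts; estimation from null-SNP
z-products is a documented extension point. Because the maximum is not
χ² distributed, the p-value is Monte-Carlo (z* ~ MVN(0, R), +1
correction, seeded); beyond MC resolution an analytic union bound —
(2^K − 1)·χ²(1) tail, valid because each subset statistic is marginally
χ²(1) — is substituted. The genome-wide scan uses the analytic bound
throughout, so it is deterministic and conservative at the 2.5e-8
threshold (5e-8 halved for two meta-analyses). Exact replication of
published S_Het p-values is not claimed: reference implementations
differ in how R is estimated and in the tail approximation.

**LD-score regression.** Per trait, z² is regressed on n·ℓ/M with a
free intercept (weights 1/(ℓ·(1 + fitted)²) from a first OLS pass);
the genetic covariance regresses z_a·z_b on √(n_a n_b)·ℓ/M; rg =
cov/√(h²_a·h²_b). SEs are a delete-one-block jackknife over up to 200
contiguous variant blocks. Non-positive heritability estimates mark rg
undefined with diagnostics rather than producing a complex number.

**Colocalization.** Per-variant Wakefield log-ABFs
½[log(V/(V+W)) + W·z²/(V+W)] with V = se² and prior effect SD 0.15
(quantitative traits) or 0.2 (case-control), priors p1 = p2 = 1e-4,
p12 = 1e-5; hypothesis sums use log-sum-exp throughout and H3 is
computed as the stable difference exp(s1+s2) − exp(s12). PP4 > 0.9 is
the conventional colocalization call.

**TWAS.** z = (wᵀz)/√(wᵀΣw) for externally supplied expression weights
w and LD Σ; weight training is out of scope.

## Synthetic-data generator

The generator emulates: block-diagonal LD (AR(1) within blocks, blocks
1 Mb apart, 5 kb variant spacing) with per-block decay drawn uniformly
on (0, 0.95) — heterogeneous decay is essential, because a constant
decay yields nearly constant LD scores and leaves LD-score regression
with no leverage; dosage genotypes from two latent-Gaussian haplotypes
matching panel allele frequencies; disjoint cohorts per trait; shared
causal sets with bivariate-normal effects scaled so the realized
genetic variance equals h² exactly against the panel LD; and a
mediation DAG X → M → Y with structural coefficients (a, b, c′) and a
liability-threshold binary outcome at case fraction K.

Default design (the conditions under which all calibration and
recovery claims are tested): M = 2000 variants in 100 blocks of 20,
h² = 0.13 and 0.05, rg = 0.26, cohorts of 20 000, causal fraction 0.2,
a = 0.3, b = 0.6, c′ = 0.4, K = 26676/159208, one sixth of allele
pairs strand-ambiguous. The summary-level instrument generator
defaults to 127 instruments explaining 4.1% of the exposure with
cohort sizes 422 218 / 159 208 (per-instrument F ≈ 140), the
strong-instrument regime the estimators are intended for.

The binary-outcome GWAS is a linear-probability regression rescaled by
1/(K(1−K)) to an approximate logistic scale. The truth record carries
the analytic liability→observed scale factor φ(t)/(sd(L)·K(1−K)) so
that structural effects can be compared with MR estimates on the
analysis scale; the proportion mediated is invariant to this scale.
Exposure and mediator direct causal sets are drawn disjoint so that
mediator instruments tag mediator biology — with overlapping sets
two-step MR is inconsistent by construction, which is a property of
the method, not of this implementation.

Not emulated: demography and population structure, imputation error,
sample overlap, minor-allele-frequency-dependent architecture, real
logistic GWAS likelihoods, and genome-scale variant counts. Passing
calibration tests on this generator therefore demonstrates internal
consistency of the estimators under the stated model, not robustness
to the full messiness of real consortium data.

Determinism: one master seed; per-stage generators derive from fixed
`SeedSequence([seed, stage])` offsets, so identical configs reproduce
outputs bit-for-bit.

## Problem sizes used in the test suite

Simulation-backed tests use desk-scale designs chosen to keep the full
suite under a few minutes while leaving the tested contrasts
well-powered: 1000 replicates for type-I/intercept calibration, 2000
for S_Het calibration, 20 seeds for recovery/coverage claims, M = 2000
z-score-mode variants for LD-score regression, and 20 000-person
cohorts (M = 500) for the end-to-end mediation recovery run.

## Known limitations

- The S_Het scan's analytic bound is conservative; loci whose true
  p_meta sits just below the threshold can be missed relative to an
  exact tail.
- LD-score regression at M = 2000 has jackknife SEs an order of
  magnitude wider than genome-scale analyses; estimates are unbiased
  but individual runs are noisy.
- The Egger and IVW multiplicative SEs use the max(1,·) floor, trading
  a small amount of conservatism for never under-covering.
- Harmonization excludes rather than strand-flips non-palindromic
  allele-set mismatches (e.g. A/G vs T/C): without strand information
  a flip cannot be confirmed, so exclusion is the safe default.
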