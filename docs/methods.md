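# Methods

## Model

Two-sample Mendelian randomization treats each independent instrument
*j* as a natural experiment. The observed summary effects are modelled
as

    beta_x_j ~ N(xi_j, sigma_x_j^2)         (SNP -> exposure)
    beta_y_j ~ N(theta*xi_j + alpha_j, sigma_y_j^2)   (SNP -> outcome)

with xi_j the true instrument effect, theta the causal effect of the
exposure on the outcome (the estimand), and alpha_j a horizontal
pleiotropic effect (a path to the outcome not through the exposure).
Valid instruments have alpha_j = 0. All estimators assume a linear,
homogeneous exposure–outcome relationship and independent instruments
(enforced upstream by LD clumping).

## Standardisation and QC

Input files are reduced to the 8-column record model (rsID, effect
allele, other allele, EAF, beta, se, p, n). Missing standard errors are
derived from a confidence interval, se = (upper − lower)/(2 z), or from
the effect and p-value, se = |beta|/|Phi^-1(p/2)|; odds ratios are
converted to log odds ratios. QC removes non-biallelic or malformed
records and resolves duplicate rsIDs by keeping the smallest p-value
(ties: first occurrence) — deterministic, and it favours the stronger
signal. Input p-values of exactly zero (truncated exports) are coerced
to the smallest positive double rather than rejected.

## Harmonisation

The outcome side is always the side modified. Non-palindromic SNPs are
aligned by letters, complementing strands where needed; an allele swap
flips the outcome effect sign and complements its EAF. Palindromic SNPs
(A/T, G/C) cannot be aligned by letters alone. Three policies (`action`)
are offered: (1) assume both studies report the forward strand; (2)
infer orientation from effect-allele frequency — if the exposure and
outcome EAFs fall on opposite sides of 0.5 the strands are taken to
differ and the sign flips; (3) drop palindromic SNPs. Under action 2 a
SNP is unresolvable when either EAF lies within a band of 0.5; the
half-width defaults to **0.08**, a conventional choice exposed as
`eaf_ambiguity_band` (no principled universal value exists; the right
band depends on the EAF sampling error of the two studies). Alleles that
no combination of swap/complement can reconcile are excluded as
incompatible. All exclusions carry machine-readable reasons and are
conserved: kept + excluded = shared SNPs.

## Clumping and proxies

Clumping is the standard greedy procedure on a user-supplied r² matrix
with base-pair positions: repeatedly take the smallest-p unclaimed SNP
as index (p ties broken by rsID so the output is order-invariant) and
claim all unclaimed SNPs within `window_kb` (default 10,000 kb) with
r² > `r2_threshold` (default 0.001). Window distance is measured index
SNP to candidate. No reference genotype panel ships with the package;
LD matrices and proxy tables are inputs (the simulator generates
consistent ones for testing).

A proxy substitutes for an instrument absent from the outcome study.
Eligibility requires r² ≥ 0.6; candidates are ranked by r², then
distance, then rsID. The proxy table records allele phase (which proxy
allele rides on the haplotype carrying each target allele); the proxy's
effect is re-expressed on the target's effect allele, flipping the sign
when the observed effect allele is in phase with the target's other
allele. Proxy provenance is recorded in the run manifest.

## Estimators

* **Wald ratio** (1 SNP): theta_j = beta_y/beta_x, first-order
  se = sigma_y/|beta_x|. A delta-method second-order se (adding
  beta_y² sigma_x²/beta_x⁴) is available behind a flag; the first-order
  form is the default reported throughout.
* **IVW** (≥2 SNPs): weighted regression through the origin, weights
  sigma_y⁻². Fixed- and random-effects flavours share the slope; the
  multiplicative random-effects model scales the se by
  max(1, sqrt(Q/(L−1))). The default flavour is random unless the
  dispersion ratio Q/(L−1) < 1 (underdispersion), in which case fixed.
  Inference is normal.
* **Maximum likelihood** (≥2): the joint normal likelihood above with
  alpha ≡ 0. The per-SNP nuisance effects xi_j have a closed-form
  optimum given theta, so theta is found by 1-D maximisation of the
  profile −2 log L (Brent, with a bounded fallback); the se comes from
  the numerical curvature of the profile at the optimum. Unlike IVW,
  the model propagates sigma_x, so it resists regression-dilution
  attenuation when instruments are noisy.
* **MR-Egger** (≥3): weighted least squares of beta_y on beta_x *with*
  intercept (the mean directional pleiotropic effect), weights
  sigma_y⁻², after re-orienting SNPs so every beta_x ≥ 0 (the intercept
  is only meaningful under a fixed exposure-increasing orientation).
  SEs carry the same dispersion floor (max(1, sqrt(Q′/(L−2)))); because
  two parameters are estimated from few points, inference uses
  t(L−2). The statsmodels WLS machinery performs the fit.
* **Median** (≥2): weighted 50% quantile of the per-SNP ratios with
  linear interpolation on centred cumulative weights. `simple` uses
  equal weights; `weighted` uses sigma_y⁻², the inverse variance of the
  SNP–outcome association. SE by seeded parametric bootstrap
  (resampling beta_x and beta_y from normals with their reported SEs).
* **Mode** (≥3): argmax over a 512-point grid of a normal-kernel
  weighted density of the ratios. `weighted` uses the inverse variance
  of the first-order ratio se. Bandwidth h = phi · 0.9 ·
  min(SD, MAD/0.6745) · L^(−1/5) with phi (`bandwidth_factor`)
  defaulting to 1. SE by seeded parametric bootstrap of the argmax.

All p-values are two-sided. Median/mode require an explicit seed; the
seed and bootstrap size are recorded in the result metadata, so any
result table is reproducible bit-for-bit.

## Diagnostics

Cochran's Q for IVW is computed on the ratio scale, Q = Σ w_j
(ratio_j − b_IVW)² with w_j = (beta_x_j/sigma_y_j)², which is
algebraically identical to the weighted residual form; both scales are
exposed. Egger's Q′ is the weighted residual sum of squares of the
intercept model (df L−2). Leave-one-out re-estimates (IVW by default)
dropping each SNP in turn, plus an "All" row. The funnel table pairs
each Wald estimate with its precision 1/se. The Steiger test sums
per-SNP variance explained r² = Z²/(Z² + n − 2) on each side
(instruments are independent after clumping), flags the direction as
correct when r²_exposure strictly exceeds r²_outcome, and tests the
difference by Fisher-transforming the two multiple correlations as
independent correlations; for binary traits on the log-odds scale the
same formula with effective n is an acknowledged approximation. The
instrument-strength F statistic uses the multi-SNP ANOVA form
F = [r²/k]/[(1−r²)/(n−k−1)].

## Synthetic data

The generator emulates a two-sample design with standardised traits:
per-SNP standard errors follow sigma² = 1/(2·maf·(1−maf)·n), so sample
size and allele frequency control precision as in real GWAS. Defaults —
50 instruments, n = 200,000 per study (consortium scale), MAF uniform on
[0.05, 0.5], true effects |N(0, 0.05)| SD per allele — describe a
well-powered continuous-trait analysis. Pleiotropy regimes: `none`;
`balanced` (alpha mean 0); `directional_inside` (alpha mean ≠ 0,
independent of xi — InSIDE holds); `correlated` (alpha loads linearly on
xi plus independent noise — InSIDE violated); `clustered` (alpha =
(effect_c − theta)·xi within each cluster, so each invalid cluster
implies a common spurious causal effect). `invalid_fraction` restricts
alpha to a random subset. The raw-file generator additionally scrambles
outcome allele orientations (swaps and strand complements that
harmonisation must undo), plants palindromic SNPs at a configurable
fraction, pairs each instrument with a satellite SNP in strong LD
(r² = 0.95, deterministically weaker p) to exercise clumping, and emits
a consistent r² = 1 proxy table.

Two reduced-noise switches exist for verification: `noise_free` (both
observed effects set to their means — every valid ratio equals theta
exactly) and `noise_free_exposure` (beta_x = xi, beta_y noisy — the
regime in which the IVW/Egger regression models hold exactly, with
SNP-exposure effects as fixed regressors). The calibration checks of
IVW/Egger unbiasedness use the latter, because with realistic
exposure-side noise IVW exhibits the familiar regression-dilution
attenuation — a genuine property, demonstrated separately by the test
showing maximum likelihood is less biased than IVW under sizeable
sigma_x.

What the generator does **not** emulate: realistic LD structure (the
matrix is block-diagonal), linkage between instruments and unmodelled
causal variants, population stratification, winner's curse from
discovery selection, binary-outcome liability scales, or EAF estimation
error between studies. Passing tests therefore certify the arithmetic
and the estimators' behaviour under their stated models, not robustness
to those real-data complications.

## Numerical choices and edge cases

- Dispersion factors for random-effects IVW and Egger are floored at 1
  (underdispersion reverts to fixed weights), so SEs never deflate.
- The ML optimiser brackets around the IVW start; failure to converge or
  a non-positive curvature raises with diagnostics rather than returning
  a dubious estimate.
- Degenerate mode densities (all ratios identical, bandwidth 0) return
  the common ratio; bootstrap SEs of exactly constant replicates are
  reported as a floor value rather than 0.
- SNPs with beta_x = 0 are excluded from ratio-based estimators with a
  warning; a single-SNP IVW call directs to the Wald ratio.
- Weighted-quantile interpolation uses centred cumulative weights, so an
  even equal-weight sample reproduces the ordinary median.
- Clump p-ties and proxy r²-ties have documented deterministic
  tie-breaks (rsID; distance then rsID).

## Known limitations

- The Silverman bandwidth is computed on the full ratio sample; with
  widely separated clusters it oversmooths and can merge modes, so
  cluster-resolution analyses should reduce `bandwidth_factor` (the
  cluster-tracking checks use 0.5). This mirrors the published mode
  estimator's tunable phi.
- The weighted median/mode bootstrap uses first-order ratio SEs.
- Steiger r² for binary outcomes is an observed-scale approximation.
- Proxy search is not strand-aware across palindromic proxies; such
  proxies should be pre-filtered when building the table.
- No liftover, multi-allelic variants, or correlated-instrument IVW.
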