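# Methods

This note documents the statistical models, numerical choices and known
limitations of `crosstrait`, at the level of detail a user would need to
judge what the package's results do and do not show.

## Generative model (synthetic data)

The simulator produces GWAS summary statistics for two traits over a
genome template of `M` variants arranged in contiguous LD blocks with AR(1)
within-block correlation `r(i, j) = ρ_block^|i−j|` and zero cross-block LD.
Each variant independently receives one of four component labels with
probabilities `(π₀, π₁′, π₂′, π₁₂)`; nonzero effects are Gaussian in
standardized per-allele units, and the shared component draws
`(β₁, β₂)` bivariate normal with correlation `ρ₁₂`.  The observed z-score
for trait `t` is

    z_tj = √N_t · Σ_i r(i, j) · β_ti + ε_tj,

with the LD sum truncated at `|r| < 0.05` and noise `(ε₁, ε₂)` bivariate
normal with marginal scales `σ₀t` (genomic inflation; 1 = none) and
correlation `ρ₀` (sample overlap).  Replication draws reuse the same true
effects with a new sample size and fresh unit-scale noise.

Default conditions (used throughout the tests and the acceptance script):
`M = 100,000` (50,000 for fitting experiments), blocks of 50 variants with
`ρ_block = 0.8`, component weights `(0.90, 0.03, 0.03, 0.04)`,
`σ²β = 1.5·10⁻⁴` at `N = 100,000` and `ρ₁₂ = 0.6`.  With these values a
causal variant's median χ² is roughly 10 — a strongly powered GWAS — and
roughly 8% of variants carry signal for at least one trait.  For univariate
recovery experiments a sparser architecture (`π₁ = 0.01`, `σ²β = 2·10⁻⁴`)
is used.  Allele frequency is not modelled: every downstream statistic
consumes only `(z, p, N)`, so MAF-dependent architectures are out of scope.
All randomness flows from one seed through named substreams, so each stage
can be redrawn independently and identical configs give identical outputs.

What the simulator does *not* emulate: realistic MAF and LD-score
distributions, population stratification beyond a scalar inflation,
genome-wide LD leakage across blocks, and sample-size heterogeneity across
variants.  Passing recovery and calibration tests therefore demonstrate
correctness of the estimators under their own assumptions, not performance
on real cohorts.

## Causal-mixture likelihood and fitting

The mixture likelihood is evaluated per variant from the characteristic
function of the convolution over its LD neighborhood (truncated at the same
`|r| < 0.05` as the generator, keeping the two exactly conjugate):

    φ_j(t) = exp(−σ₀²t²/2) · Π_{i∈nbr(j)} [1 − π₁ + π₁ exp(−N σ²β r²ᵢⱼ t²/2)],

inverted by FFT on a symmetric grid of 2048 points spanning
`|z| ≤ max(20, max|z| + 5)`.  The bivariate model replaces the per-neighbor
factor with the four-component mixture (the shared component carrying the
`ρ₁₂` cross term, kept inside a single exponent of the positive
semi-definite quadratic form for overflow safety) and a correlated-noise
factor, inverted by 2-D FFT on 128 points per axis.  Log-densities are
interpolated to observed z-scores with cubic splines; doubling either grid
changes the log-likelihood by under 10⁻⁵ per variant on the standard
fixture (asserted at 10⁻⁴ in the tests), and the far-tail floor (densities
clipped at 10⁻³⁰⁰) is reached only for parameter values that are being
correctly rejected.  Variants are grouped by the multiset of r² values in
their neighborhood, so each distinct LD profile's density grid is computed
once — this is what makes template-scale likelihoods cheap.

Fitting follows the resampling estimator: 20 iterations, each subsampling
variants (20,000 by default; 5,000 in the standard experiments), randomly
pruning at r² > 0.8, and maximizing the likelihood by Nelder–Mead on
transformed scales (logit for proportions, log for variances, atanh for
correlations; `σ₀ = 0.5 + exp(x)` keeps the inflation scale above 0.5).
The first iteration uses three starting points (one moment-matched to the
excess z-variance, the rest perturbed — configurable); later iterations
warm-start from the previous optimum, which is cheaper than full
multi-start on every iteration and empirically converges to the same
estimates.  Reported values are iteration means with iteration SDs (the
resampling spread, not an asymptotic covariance).  The bivariate stage
holds each trait's univariate `(π_total, σ²β, σ₀)` fixed and fits only
`(π₁₂, ρ₁₂, ρ₀)`, with `π₁₂ = min(π₁,π₂)·sigmoid(x)` enforcing the
feasibility constraint by construction.  AIC is reported for the fitted
model against a minimal-overlap (`π₁₂ = 0`, 1 free parameter) and a
maximal-overlap (`π₁₂ = min` of totals, 2 free parameters) reference, each
re-optimized on the same reference subsample.

Derived quantities: variant counts are proportions times the template size;
`r_g = ρ₁₂ π₁₂ / √(π₁,tot π₂,tot)` (valid when the effect variance is
shared across components within a trait); the concordant fraction is the
orthant probability `½ + arcsin(ρ₁₂)/π`; n90 uses the χ²₁ truncated-mean
identity (the threshold solving `E[X·1{X>t}] = 0.9·E[X]` satisfies
`P(χ²₃ > t) = 0.9`), giving the constant ratio n90/(πM) ≈ 0.445
independent of `σ²β`.

## Conditional and conjunctional FDR

For each ordering of the pair, the lookup is built on a grid over
`(−log₁₀ p₁, −log₁₀ p₂) ∈ [0,10]` (101 × 41 nodes).  Per pruning iteration
(20 by default, clusters at r² > 0.1, one random variant kept per cluster)
and per conditioning stratum (`p₂ ≤ 1, 0.1, 0.01, 0.001`), the empirical
cdf of primary p-values is evaluated at the grid and
`condFDR = p₁ / F̂(p₁)` with the null proportion conservatively set to 1.
`F̂` is floored by the uniform cdf: cross-trait enrichment implies
`F(p) ≥ p`, and the floor makes grid nodes beyond the observed p-range
degrade to condFDR ≈ 1 instead of extrapolating the last observed rank.
Grids are averaged over pruning iterations, interpolated along the
conditioning axis between stratum coordinates, then monotonized: a running
minimum along increasing `−log₁₀ p₁` (the same adjustment
Benjamini–Hochberg applies in rank space) and along the conditioning axis
(sharper conditioning can only lower condFDR).  Queries interpolate
bilinearly and clamp to the grid edge.  conjFDR is the maximum of the two
mutual condFDR values; a single threshold (0.05) defines significance
everywhere downstream.

Long-range atypical-LD regions — extended MHC (chr6:25–34 Mb) and the 8p23
inversion (chr8:7–12 Mb) by default — are excluded from cdf construction
but still receive interpolated values.

Calibration under the default study conditions: among conjFDR < 0.05 calls
the share of variants with no LD-propagated signal for at least one trait
(`δ₁ = 0` or `δ₂ = 0` in the simulator's records) averages ≈ 0.01–0.02,
well inside the 0.075 acceptance bound.  "False" is defined through the
signal δ, not the causal label: a null-labelled variant in strong LD with a
shared causal variant genuinely carries association for both traits, which
is exactly what conjFDR claims to detect.  Under a complete-null
simulation the lookup stays near 1 in the populated region (≥ 0.85 for
p₁ ≥ 0.1) but can dip to ≈ 0.6 at deep quantiles of sparse strata, where
the running-minimum regularization accumulates sampling dips — a known
small-sample property of the estimator, bounded in the tests by the band
measured on a frozen fixture.

## Locus definition and transdiagnostic merging

Clumping is greedy by ascending conjFDR (ties: position, then variant id).
Independent significant SNPs: conjFDR < 0.05 and not in r² ≥ 0.6 with an
already chosen one.  Lead SNPs: greedy at mutual r² < 0.1.  Candidate
SNPs: conjFDR < 0.10 and r² ≥ 0.6 with an independent significant SNP
(locus bounds use candidates at the 0.10 threshold).  Independent SNPs
within 250 kb or r² ≥ 0.1 form one locus; a candidate tagged from several
loci is assigned to the one whose tagging SNP has the lowest conjFDR, so
every significant variant lands in exactly one locus.  Transdiagnostic
merging pairs loci from different analyses when their intervals physically
overlap (1-based inclusive) and at least one SNP that is a candidate in
both has conjFDR ≤ 0.05 in both; groups close transitively, so one
transdiagnostic locus can span analyses whose own interval bounds differ.
The transdiagnostic lead minimizes the maximum conjFDR across contributing
analyses (ties: position).  All orderings are deterministic and the merge
is invariant to analysis input order.

## Replication and enrichment

The en-masse sign-concordance test is a one-sided exact binomial of the
number of lead SNPs with matching discovery/replication z-signs against
1/2; leads missing from the replication table are dropped and counted, and
zero z-scores are excluded from `n`.  This choice reproduces the published
replication p-values from their printed counts to printed precision.
Positional gene mapping extends each gene span by a 10 kb window and
requires overlap with a candidate-SNP position.  Gene-set enrichment is a
hypergeometric tail test per set (sets intersected with the background
universe first) with Benjamini–Hochberg adjustment across sets within one
analysis; eQTL and chromatin-interaction mapping are out of scope, so
externally derived credible gene lists can be supplied directly.

## Numerical and design choices

- p-values are clamped to `[10⁻³⁰⁰, 1]` before log transforms; p/z
  consistency (`p = 2Φ(−|z|)`) is validated at 10⁻⁶ relative on
  construction and repaired (with counting) on file read.
- Strand-ambiguous variants (A/T, C/G) are dropped during harmonization by
  default because allele frequencies are not required inputs.
- Unknown LD pairs are exactly zero; the synthetic LD is block-diagonal, so
  zero-fill is exact there.
- The problem sizes in the tests and acceptance script (50k-variant
  templates for fitting with 20 × 5,000-variant iterations, 100k for FDR
  calibration) are the package's standard desk-scale study conditions;
  the estimator structure is unchanged at larger scale.

## Limitations

Real GWAS applications would additionally need reference-panel LD, MAF
stratification, and cross-cohort quality control that this package does not
provide.  The mixture model assumes a single effect-size variance per trait
across components; architectures with component-specific variances would
bias `r_g` derived from proportions.  The condFDR lookup is a conservative
stratified estimator, not a full 2-D density model, and inherits the usual
small-stratum variance at extreme quantiles.
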