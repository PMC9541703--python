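# crosstrait

Cross-trait GWAS analysis of polygenic overlap and shared genomic loci, for
statistical geneticists who work with summary statistics from pairs of
complex traits (for example a psychiatric disorder and a related
transdiagnostic trait such as mood instability).

Two traits can share most of their causal variants while showing almost no
genetic correlation, because shared variants with concordant and discordant
effect directions cancel.  `crosstrait` implements the two complementary
methods that make this overlap visible, plus everything needed to exercise
them end to end on synthetic data with known ground truth:

- **Bivariate causal mixture model.**  Each variant belongs to one of four
  components — influencing neither trait, only the first, only the second,
  or both — with proportions `(π₀, π₁′, π₂′, π₁₂)`.  Causal effects are
  Gaussian with variances `σ²β` (discoverability); shared effects have
  correlation `ρ₁₂`; null z-scores have scale `σ₀` (inflation) and
  cross-trait noise correlation `ρ₀` (sample overlap).  The likelihood of a
  z-score convolves the effects of its LD neighborhood via the
  characteristic function

  `φ_j(t) = exp(−σ₀²t²/2) · Π_{i∈nbr(j)} [1 − π₁ + π₁·exp(−N σ²β r²ᵢⱼ t²/2)]`

  (bivariate analogue for pairs), evaluated by inverse FFT.  Estimates and
  SDs come from 20 resampling iterations with random LD pruning at
  r² = 0.8.  Derived outputs: shared/unique variant counts, genetic
  correlation `r_g = ρ₁₂ π₁₂ / √(π₁ π₂)`, the concordant-effect fraction
  `½ + arcsin(ρ₁₂)/π`, n90 (variants explaining 90% of heritability) and
  AIC support against minimal/maximal-overlap references.

- **Conditional / conjunctional FDR.**  Cross-trait enrichment is captured
  in stratified empirical lookups `condFDR(p₁|p₂) = p₁ / F̂(p₁ | p₂ ≤ T)`,
  averaged over random LD-pruning iterations (r² > 0.1) and monotone
  regularized; the conjunctional FDR of a variant is the maximum of the two
  mutual conditional FDR values, with significance at conjFDR < 0.05.

Downstream stages follow the FUMA locus protocol (independent significant
SNPs at r² < 0.6, lead SNPs at r² < 0.1, candidate SNPs at conjFDR < 0.10
and r² ≥ 0.6, 250 kb merge), merge physically overlapping loci across
analyses into transdiagnostic loci, test replication by en-masse
sign-concordance (one-sided exact binomial against 0.5) and run
hypergeometric gene-set enrichment with Benjamini–Hochberg adjustment.

## Worked example

```python
from crosstrait import (
    SimulationConfig, simulate_pair, harmonize_pair,
    FitConfig, fit_univariate, fit_bivariate,
    FDRConfig, conjfdr_table, define_loci, directional_concordance,
)

# two traits, 50k variants: 3% unique to each, 4% shared (rho12 = 0.6)
config = SimulationConfig(m=50_000, seed=3)
_, ld, truth, t1, t2, deltas = simulate_pair(config)
pair = harmonize_pair(t1, t2)

fc = FitConfig(n_iterations=20, subsample=5000, seed=3)
f1 = fit_univariate(pair.trait(1), ld, m=50_000, config=fc)
f2 = fit_univariate(pair.trait(2), ld, m=50_000, config=fc)
fb = fit_bivariate(pair, ld, f1, f2, m=50_000, config=fc)
print(f"shared variants: {fb.derived['n_shared']:.0f} "
      f"(sd {fb.derived['n_shared_sd']:.0f}), rg = {fb.derived['rg']:.2f}, "
      f"concordant = {100 * fb.derived['concordant_fraction']:.0f}%")

table = conjfdr_table(pair, ld, config=FDRConfig(seed=3))
loci = define_loci(table, ld)
_, k, n, pct = directional_concordance(loci)
print(f"{(table['conjFDR'] < 0.05).sum()} variants at conjFDR < 0.05, "
      f"{len(loci)} loci, {k}/{n} concordant ({pct}%)")
```

Output (seed 3):

```
shared variants: 1869 (sd 161), rg = 0.37, concordant = 74%
4046 variants at conjFDR < 0.05, 380 loci, 316/380 concordant (83.2%)
```

The true shared count is 2,000 (π₁₂ = 0.04 of 50,000), the true `r_g` is
0.34 and the true concordant fraction at ρ₁₂ = 0.6 is 70% — the fitted
mixture recovers all three within the resampling spread.  The conjFDR calls
are dominated by variants carrying genuine LD-propagated signal for both
traits (see the acceptance output below for the measured false-discovery
share).

A command-line interface mirrors the library
(`crosstrait simulate|harmonize|fit-mixer|conjfdr|loci|transdiag|replicate|enrich|run-all`);
`run-all` drives a whole pair analysis from a YAML config and writes
deterministic TSV outputs plus a manifest with the master seed and
parameter hash.

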