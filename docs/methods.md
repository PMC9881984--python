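# Methods

## The conditional randomization test

Let **X** be offspring genotypes at *M* instrument SNPs, *O* the offspring
outcome, and **A** the family conditioning information (both parents in
trio mode; one parent plus the offspring in duo mode; the sibship in
sibling mode). Population structure, assortative mating, and dynastic
effects are "external" confounders in the sense **X** ⫫ **Z** | **A**:
they influence offspring genotypes only through the parental genotypes.
Under the MR null hypothesis (no exposure→outcome effect, no horizontal
pleiotropy) this gives **X** ⫫ *O* | **A**, which the package tests
directly by resampling.

Digital twins X̃ are drawn from the conditional law of **X** given **A**.
Because instruments are assumed independent (the normal situation after LD
pruning), inheritance factorizes per SNP and needs no phasing:

* **trio** — X̃ⱼ ~ Bern(P1ⱼ/2) + Bern(P2ⱼ/2). This is exactly the offspring
  law, so exchangeability is exact and the test is valid at any confounding
  strength.
* **duo** — the unobserved parent's contribution is fixed from the
  offspring genotype: if the observed parent is homozygous X̃ⱼ = Xⱼ,
  otherwise X̃ⱼ ~ Bern(1/2) + Bern(Xⱼ/2). Conditioning is partial, so
  calibration degrades under strong confounding.
* **sibling** — the twin's two alleles are independent uniform draws from
  the 2S pooled alleles of the S observed siblings ("shuffling"). This is a
  deliberate approximation of the true conditional law; an alternative that
  draws one allele from each of two distinct siblings is available via
  `distinct_siblings=True`. Like duo mode, not exactly calibrated under
  strong confounding.

The statistic scores the genetic prediction of the outcome with external
weights held fixed: t = −Σₙ(β̂ₑₒ Σⱼ β̂ₓₑ,ⱼXₙⱼ − Oₙ)². Both β̂ₓₑ (per-SNP
exposure effects) and β̂ₑₒ (IVW by default; Egger or single-instrument
ratio selectable) come from the external summary statistics only and are
*never* re-fit per twin replicate — offspring genotypes are independent of
the external estimates given the parents, which is what makes the ranking
exchangeable. The p-value counts ties toward the null, p = (1 + #{t_b ≥
t*})/(1 + B); this is the conservative permutation convention and makes
degenerate cases (e.g. β̂ₑₒ = 0, or families whose parents are all
homozygous so every twin equals the offspring) return p = 1 rather than a
spurious rejection. The test is one-sided by construction — a true effect
makes the offspring's prediction *better* than the twins' — and a
two-sided variant (doubling the smaller tail) exists but is off by
default.

Twin replicates are generated from per-replicate generators spawned from a
single seed sequence, so a batch is a deterministic function of (families,
B, seed) regardless of chunking or worker count.

## The simulator

The generator reproduces the two-population study conditions used to
benchmark family-based MR:

1. **Genotypes.** For each SNP an ancestral frequency is drawn uniformly
   from (0.05, 0.95) — a bounded uniform avoids near-monomorphic SNPs; the
   bound is configurable. Population-specific frequencies follow the
   Balding–Nichols Beta law with mean p and variance F·p(1−p)
   (point mass at p for F = 0). External individuals and trio parents are
   drawn binomially from the *same* frequency realization, matching the
   recommendation that external and family cohorts share their structure;
   both parents of a family belong to the same population, and offspring
   are produced by per-SNP Mendelian transmission (the same code path as
   trio twin sampling).
2. **Phenotypes.** E = Xβ + γ·pop + ε_E and O = β_EO·E + γ·pop + ε_O with
   pop ∈ {0,1}. Per-SNP effects are i.i.d. Gaussian on a random causal
   subset, rescaled so the genetic component explains h² of Var(E); noise
   variances are set so each trait has unit variance at γ = 0, which makes
   γ and β_EO comparable across runs. The same confounding weight γ applies
   to both traits by default (independent override available). β_EO² ≥ 1 is
   rejected as a negative-variance request.

Defaults mirror the benchmark conditions: F_ST = 0.01, h² = 0.2, half the
SNPs causal, even population split, confounding γ ∈ [0, 0.8]. Full scale is
50,000 external samples (null studies) or 100,000 (power studies), 1,000
trios, 100 SNPs; the package defaults are a reduced scale (2,000 external,
200 trios, 50 SNPs) chosen so a 500-replicate grid runs in tens of seconds
on one CPU.

What the generator does **not** emulate: linkage disequilibrium and
haplotype blocks (instruments are simulated independent — with structure
they still correlate through the population label, which is what inflates
IVW even at γ = 0 for large F_ST); assortative mating and dynastic effects
as generative mechanisms (the test's immunity to them is a conditional-
independence argument, not something these simulations exercise); binary
outcomes; genotyping error or missingness. Passing tests therefore
demonstrate calibration and power under stratification confounding with
independent instruments, not under LD misspecification or real-data
artifacts.

## External GWAS and estimators

The marginal scan is closed-form simple OLS per SNP (intercept included;
two-sided t p-values), vectorized across SNPs; optional covariates are
projected out of phenotype and genotypes first (Frisch–Waugh–Lovell), with
degrees of freedom adjusted. It is cross-checked against statsmodels in the
test suite. Monomorphic SNPs are excluded with a warning, never silently.

Instrument selection retains SNPs with exposure p < α/M (Bonferroni,
α = 0.05) and optionally requires the instrument-strength statistic
F = (β̂ₓₑ/se)² ≥ 10. Retention-below-threshold is the standard reading of
instrument filtering for limiting weak-instrument bias; both filters can be
disabled to reproduce the "unfiltered" regime. An empty selection is a hard
error — the CRT refuses to run without instruments.

Estimators: single-instrument ratio β̂ₓₒ/β̂ₓₑ with first-order delta-method
SE; fixed-effect IVW (weights (β̂ₓₑ/seₓₒ)²; J = 1 reduces exactly to the
ratio; normal p-values); MR-Egger as weighted least squares with intercept
after orienting instruments to β̂ₓₑ ≥ 0, with estimated residual dispersion
and t-based p-values. Fixed-effect IVW is the default weight inside the CRT
statistic because the statistic needs only a point estimate; any bias in it
affects offspring and twins identically and cannot break validity.
Weighted-median and mode-based comparators are accepted as pluggable
callables in the benchmark grid rather than implemented.

## Numerical and design choices

* p-values from the scan are clipped to the smallest positive float rather
  than reported as 0.
* Mendelian consistency of offspring with available parents is checked
  before testing; by default an inconsistency is a hard error, with an
  opt-in that drops affected SNPs family-wide (never imputes).
* Replicate seeds in benchmark grids are spawned deterministically from a
  master `SeedSequence`, so tables are bit-reproducible and independent of
  execution order; per-replicate failures (e.g. no instruments at a small
  sample size) are warned about and tabulated, and a grid cell is flagged
  when more than 5% of its replicates failed.
* B = 100 twins is the benchmarking default; B = 1000 is recommended for a
  one-off analysis. The Monte-Carlo dispersion of the p-value is
  binomial-like, sd ≈ √(p(1−p)/B), except near the 1/(B+1) floor where it
  truncates below that; the stability harness measures this directly.
* On-disk formats are plain TSV plus a minimal unphased VCF; SNPs are
  matched by identifier only (the method never needs positions), and
  effect-allele alignment between genotype coding and summary statistics is
  the user's responsibility.

## Problem sizes

The test suite validates calibration and uniformity on 500 null replicates
at the reduced scale with B = 100; estimator bias on 200 replicates at
n = 50,000; power on 150–200 replicates per grid cell; and the p-value
floor at 1,000 trios with B = 1000 — the family count at which a causal
effect of 0.5 saturates the floor reliably (at 200 families the within-
family signal gives a standardized exceedance of only ≈ 2.3, and the
observed statistic is then occasionally out-ranked by one of 1000 twins).

## Limitations

Only trio mode carries the exact-validity guarantee; duo and sibling modes
are approximations whose false positive rates drift upward under strong
confounding. Horizontal pleiotropy is *not* an external confounder — a
pleiotropic instrument breaks the null hypothesis being tested, and the CRT
offers no protection. The method is a test, not an estimator: it returns no
effect size or confidence interval. Continuous outcomes only.
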