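# Methods

## The model

The package analyses balanced expression panels from inbred line designs:
`n = L × m` samples (default 30 lines × 2 biological replicates) by `p`
expression traits.  After per-trait standardization (mean 0, SD 1), the
Bayesian sparse factor genetic model decomposes

```
Y = 1 b' + F Λ' + Z U_s + E
```

- `Λ` (p × k): sparse trait loadings on latent factors,
- `F` (n × k): sample-level latent factor values.  Each factor has unit
  variance split into a line-level genetic component (variance `h²_j`, the
  factor heritability) and a replicate-level component (variance `1 − h²_j`),
- `U_s` (L × p): trait-specific line effects; the trait-specific variance
  `ψ_t` splits the same way via the specific heritability,
- `E`: replicate residuals.

The implied covariances are `P = Λ Λ' + Ψ`,
`G = Λ diag(h²) Λ' + diag(h²_ψ ψ)`,
`R = Λ diag(1 − h²) Λ' + diag((1 − h²_ψ) ψ)`, with `G + R = P` exactly
(asserted at every retained draw in the tests).

### Priors and sampling

- Loadings carry a multiplicative gamma process on column precisions
  `τ_j = Π_{l≤j} δ_l`, `δ_1 ~ Ga(a1, 1)`, `δ_l ~ Ga(a2, 1)` with
  `a1 = 2.1`, `a2 = 3.1` (> 1 so trailing factor variances shrink
  stochastically), plus per-element local scales `φ_tj ~ Ga(ν/2, ν/2)`,
  `ν = 3`.  `k` is held fixed at `k_max`; surplus columns are shrunk, not
  deleted.
- Heritabilities (factor and trait-specific) take a discrete uniform prior
  on a 21-point grid over [0, 1].  The full conditional is enumerated
  exactly with the line effects integrated out, using the balanced-design
  eigenstructure (variance `1 + (m − 1) h²` along replicate means,
  `1 − h²` along within-line contrasts).  Grid sampling makes draws of
  exactly zero possible, which the sign-based significance tests rely on;
  `h² = 1` has zero likelihood whenever replicates differ.
- Specific variances `ψ_t` have an inverse-gamma prior (shape 3, rate 1).
- All remaining blocks (F, U_f, Λ, U_s, trait means) are conjugate
  normal updates; the Λ update solves one small Cholesky system per trait,
  batched.  Conditional variances are floored at 1e-10.

Initialization is a truncated SVD of the centered data.  Chain-length
defaults (`n_burn = 5000`, `n_samples = 5000`, `thin = 5`) are
conservative; all validation studies below use shorter, explicitly stated
chains that were checked to reproduce the same posterior summaries.

### Significance and classification

The local false sign rate (LFSR) of a loading is the fraction of posterior
draws that are zero or on the opposite side of zero from the posterior
median (a zero median gives 0.5); for the grid-sampled, non-negative
heritabilities it is the fraction of draws exactly zero.  LFSRs are
corrected within a family to average error rates: sort ascending, take
cumulative means, map back — `(0.04, 0, 0.02) → (0.02, 0, 0.01)`.

A factor is **statistically supported** when at least two traits load
significantly (corrected rate `s < 0.005`, within the factor's `p`
loadings) and **heritable** when additionally its `h²` error rate
(corrected across the `k` factors) is below 0.01.  Both thresholds are
strict inequalities.

### Outlier lines

A line is an outlier for a variable (an observed trait or a latent factor,
using posterior-mean per-replicate latent values) when, on that variable's
own median/IQR scales, (1) its replicate mean deviates more than 3 IQR
from the median of line means, (2) every replicate deviates more than
3 IQR from the pooled median, and (3) the replicates deviate in the same
direction.  All comparisons are strict; quartiles use linear
interpolation.  `n_ot` counts a factor's significantly loading traits that
have at least one outlier line.

### Permutation null and retention

Sampling error alone produces apparently heritable factors when `p >> n`.
The null permutes each trait's intact replicate pairs across line labels,
independently per trait: every per-trait marginal (including single-trait
heritability) is preserved exactly while between-trait genetic covariance
is destroyed.  Observed heritable factors are retained when (criterion 1)
their `n_tt` exceeds the maximum across null heritable factors, or
(criterion 2) their `n_ot` falls outside the central 95% of null `n_ot`
among null factors with matching `n_tt` (exact match when ≥ 20 null
factors support it, otherwise a ±2 window on `n_tt`; still-unsupported
cases are conservatively flagged indeterminate and not retained).  The
default is 20 permutations with a flag to raise it.

### Downstream analyses

Retained factors are given an imposed direction (sign of the mean trait
loading, ties kept positive), outlier deviations are tallied above/below
the median at factor and trait level, per-line outlier frequency is
related to latent line values by Spearman correlation, and heritable
factors with vs without outlier lines are compared on heritability,
direction bias, `n_tt` and mean |significant loading| with two-sided
Wilcoxon rank-sum tests (exact for group sizes ≤ 10 without ties).

### Population genetics

A variant observed in one line among 30 (each founded by two outbred
diploids, so ~120 founding genomes) implies allele frequency
`q ≈ 1/120`.  Under mutation–selection balance the selection coefficient
maintaining frequency `q` is `s = μ/q²` (recessive), `2μ/q` (additive) or
`μ/q` (dominant) — a recessive variant needs `1/q`-fold stronger selection
than a dominant one (100-fold at `q = 0.01`).  Chromosome distributions of
gene sets are tested against a background by chi-square, with a seeded
Monte-Carlo p-value whenever any expected count is below 5.

## What the generator emulates — and what it does not

`simulate_expression` draws data exactly from the model family above:
sparse Gaussian loadings (density and scale configurable), factor line
values `u ~ N(0, h²)`, replicate deviations `N(0, 1 − h²)`, uniform
trait-specific variances and specific heritabilities, Gaussian trait
means, and optional planted outlier lines (a shift of several latent-SD
units on one factor's line value) and Student-t tails on the
trait-specific residuals.  Defaults mirror the target study design
(30 × 2 × 3385).  It does **not** emulate: count-based measurement noise
or normalization artifacts, correlated specific effects between traits,
batch/technical covariates, unbalanced designs, or linkage between
outlier genotypes across factors.  Planted outliers shift only the
genetic (line-level) value, so both replicates move together by
construction.

## Numerical choices

- Per-trait scaling: SD scale (ddof = 1) for model fitting; median/IQR
  scale for extreme values and outlier detection.  Zero SD/IQR raises an
  error naming the trait.
- The `h²` grid likelihood is computed in one vectorized enumeration per
  iteration; categorical sampling uses the max-subtracted softmax.
- Adjusted ("factor-removed") data are `Y − F̄ Λ̄'` on the SD scale,
  mapped back to the raw scale and re-scaled on their own median/IQR
  before extreme-value counting, so before/after comparisons are
  like-for-like.
- Seeds: every pipeline derives independent sub-seeds from one root via
  `numpy` `SeedSequence`; derived seeds are truncated below 2³¹.

## Validation studies and their problem sizes

Validation uses simulation studies at desk scale (minutes on one CPU);
sizes are package choices, stated here and in the tests:

- **Parameter recovery** (`bsfg.validation.recovery_study`): 25 panels at
  p = 200, k_true = 3, h² ∈ {0.3, 0.6, 0.9}, loading density 0.5, loading
  scale 0.8, ψ ∈ [0.2, 0.5]; chains 1500 burn / 4000 kept / thin 8,
  k_max = 6.  Scored by (a) coverage of true h² by central 90% posterior
  intervals after one-to-one factor matching on absolute loading
  correlation, and (b) the largest principal angle between the spans of
  the true loadings and the top-3 posterior-mean loading columns,
  averaged over panels.  Observed (seed 0): coverage 60/75 = 0.80, mean
  max angle 15.0°.  Two caveats are documented deliberately: with only 30
  lines the *realized* between-line variance of a factor fluctuates
  around its nominal h² (SD ≈ h²√(2/29)), and chance correlation between
  true line-value vectors lets the model's orthogonalized basis
  redistribute between-line variance between factors; both cap attainable
  nominal-h² coverage regardless of sampler quality.  A single-factor
  check on data drawn exactly from the model (k_max = 1) covers the
  realized h² in 93% of intervals with bias ≈ −0.02, confirming the
  sampler itself is calibrated.  The angle criterion is summarized as the
  mean over panels of the per-panel largest principal angle.
- **Outlier detection**: 100 panels, one planted 6-latent-SD outlier at
  h² = 0.8, detection applied to the true per-replicate latent values
  (the detector is the unit under test, not the sampler).  Observed:
  sensitivity 0.92, zero false calls.
- **Permutation null**: exact preservation of per-trait marginals and
  line-mean multisets is asserted on structured p = 200 panels; the null
  median pairwise line-mean correlation is within ±0.02 of zero.
- **Retention calibration**: 20 end-to-end runs on k_true = 0 panels
  (p = 40, k_max = 4, 300/300/3 chains, 20 permutations each).  Observed:
  0 factors retained in 20/20 runs.
- **Extreme-value reduction**: a panel whose extremes are planted through
  factor outliers loses > 50% of its 3-IQR extreme values after factor
  adjustment (observed: 97% at observation level, 100% at line-mean
  level).

## Limitations and open decisions

- `k_max` is fixed during sampling; surplus factors are shrunk rather
  than removed, so factor-order statistics (e.g. τ) are interpretable
  only up to the shrinkage profile.
- Nominal-h² interval coverage at 30 lines is bounded by realized-variance
  fluctuation (see above); users should read h² intervals as statements
  about the panel's realized variance ratio.
- Latent-variable outlier detection uses the posterior mean of F; a
  per-draw majority vote is a documented alternative not implemented as a
  switch.
- The permutation null's criterion-2 matching tolerance (exact n_tt, then
  ±2 window, minimum 20 supporting null factors) is a package decision;
  indeterminate cases are conservatively not retained.
- Selection-coefficient estimates inherit the strong assumptions of
  mutation–selection balance (constant μ, equilibrium, no drift) and the
  founding-genome approximation `q = carriers / (4L)`.
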