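# Methods

## The model

White striping is recorded as an ordered trichotomy NORM < MOD < SEV.  We
model it through a latent Gaussian **liability** l: with m observed
categories there are m − 1 thresholds t₁ < … < t_{m−1}, and category c is
observed when l falls in [t_{c−1}, t_c).  The liability, and every
quantitative trait y analysed alongside it, follows the animal model

    y = μ + H_i + S_j + c_k + a_l + e

with fixed hatch (H) and sex (S) effects, a common maternal-environment
effect c (fitted for body weight only — one random level per dam,
c ~ N(0, σ²c)), breeding values a over the *entire* pedigree with
Var(a) = A ⊗ G (A the additive-relationship matrix, G the 2×2 genetic
covariance), and residuals with per-bird 2×2 blocks R.  Fits are bivariate —
the liability paired with one quantitative trait at a time — with univariate
special cases.  Hatch is deliberately confounded with generation (distinct
hatch labels per generation, no separate generation effect), reproducing the
design of the data this models.

**Identifiability.** The latent scale is anchored by t₁ = 0 and σ²e₁ = 1
(liability residual variance).  This is the standard threshold-model
parameterization; it is stated in the chain output header since other
software anchors differently and heritabilities — not raw variances — are
the comparable quantities.

**Derived quantities.** Per retained draw, h² = σ²g/(σ²g + σ²e), with σ²c
added to the denominator for the maternal trait (both conventions are
recomputable from the stored components), and r_g = σg12/√(σ²g1·σ²g2).
Posterior means are the estimates; posterior SDs are reported as their
standard errors, following the field's convention for Gibbs-based variance
component estimation.  "Significant" means the 95% equal-tail interval
excludes zero (an HDI option exists).

## The Gibbs sampler

Each iteration draws, in order:

1. **Liabilities** — truncated-normal draws (inverse-CDF, Wichura's AS 241
   quantile function) from N(m₁ + (R₁₂/R₂₂)e₂, R₁₁ − R₁₂²/R₂₂) restricted to
   the record's category interval.
2. **The free threshold t₂** — uniform on (max liability among MOD, min
   among SEV), the standard conditional.  A category with zero observations
   makes its threshold unidentifiable and aborts the fit.
3. **Missing co-trait records** — data-augmented from their residual
   conditional.  Augment-and-discard is the exact Monte-Carlo realization of
   marginalizing the missing trait; birds with no records at all contribute
   through A only.
4. **Fixed effects** — blocked per factor (the levels of one factor
   partition the records, so a joint draw of all its levels from scalar
   conditionals is an exact block update).  Corner constraints (first level
   = 0) keep the location part full rank; flat priors.
5. **Maternal effects** — same block update with prior precision 1/σ²c.
6. **Breeding values** — individual-wise sweep using the sparse A⁻¹
   neighborhood: animal i's conditional has precision A⁻¹ᵢᵢ·G⁻¹ + Z'R⁻¹Z and
   mean term −G⁻¹ Σ_{j≠i} A⁻¹ᵢⱼ aⱼ plus the data part.  Sequential
   (Gauss–Seidel-style) sweeps preserve the stationary distribution.
7. **G** — inverse-Wishart with df ν₀ + q and scale S₀ + Sₐ, where
   Sₐ = Σ uᵢuᵢᵀ/dᵢ over the q pedigree members, uᵢ the Mendelian-sampling
   residual aᵢ − ½(a_s + a_d) and dᵢ the inbreeding-corrected within-family
   coefficient (equivalently aᵀA⁻¹a).
8. **σ²c** — scaled inverse chi-squared.
9. **R** — under the σ²e₁ = 1 constraint, via the conditional decomposition:
   the regression b of e₂ on e₁ (normal conditional) and the conditional
   variance ψ (scaled inverse chi-squared), recomposed as σe₁₂ = b,
   σ²e₂ = ψ + b².  Both draws are automatically positive definite.  With two
   quantitative traits R is inverse-Wishart on the residual cross-products.

The hot loops (1, 4–6) are numba kernels; all randomness is pre-drawn from a
single seeded numpy Generator per chain, so runs are bit-reproducible and
the seed is recorded in the ChainStore.  Residuals are maintained
incrementally and refreshed from scratch every 1,000 iterations against
floating-point drift.

**Priors** (minimally informative; the reference threshold-model software
this emulates does not document its choices, so these are ours): flat for
fixed effects and thresholds; G ~ IW(dim + 1, 0.1·I); σ²c and the
conditional residual variance ~ scaled-inv-χ²(ν = 1, s² = 0.1).  At the
sample sizes used (n ≳ 500) their influence is negligible next to the data
cross-products.

**Starting values.** Liabilities start at the conditional means of the
category intervals; the free threshold starts at its probit-consistent
position √v₀·(z_{p₀+p₁} − z_{p₀}) computed from the observed category
frequencies (v₀ = 2, the initial total liability variance).  This matters:
the threshold conditional has support of width O(1/n) per iteration, so t₂
performs a slow random walk, and a cold start (e.g. t₂ = 1) costs tens of
thousands of iterations of burn-in at large n.  Variances start at half the
phenotypic variance; intercepts at trait means.

**Schedules.** The analysis default is 100,000 iterations, 20,000 burn-in,
thinning 20 → 4,000 retained draws.  Tests and desk runs use a documented
reduced schedule (20,000/4,000/10 → 1,600 draws), adequate at n ≈ 3,000; at
the full ~10,700-bird scale the reduced schedule leaves the liability-side
parameters visibly under-converged — which the Heidelberger–Welch
diagnostic flags — and the full schedule is the appropriate choice there.

## Pedigree machinery

A is built by the tabular method (dense; used for small oracles), A⁻¹ by
Henderson's rules with Meuwissen–Luo inbreeding-corrected Mendelian-sampling
variances dᵢ = 0.5 − 0.25(F_s + F_d).  Inbreeding **is** accounted for:
closed selected lines accumulate F over six generations.  Inbreeding
coefficients come from memoized recursive kinship, exact and identical to
the tabular method.  Unknown parents are unrelated, non-inbred base-
population founders; no genetic groups.  Pedigrees are topologically sorted
on load (min-heap Kahn, idempotent for already-sorted files) with hard
errors for cycles, missing parents, duplicate ids and parent-sex conflicts.

## The synthetic-data generator

The generator emulates the divergent-selection design that produced the
study data: a base of 1,640 unrelated founders split into two pools, then
six generations per line of truncation selection on own pHu phenotype
(high line / low line), 32 sires and 84 dams per line-generation, 9
offspring per dam, 3 hatches per generation (21 hatch levels) — ~10,700
birds, ~380 sires, ~1,000 dams.  Breeding values are parent average plus a
Mendelian-sampling deviation with covariance 0.5(1 − (F_s + F_d)/2)·G;
maternal environment is one draw per dam per generation applied to the
designated trait; the liability is thresholded into NORM/MOD/SEV.  Default
truth encodes the estimates this package is built to recover: liability
h² = 0.65 (σ²e₁ ≡ 1), pHu h² = 0.55 with phenotypic variance 0.02, genetic
correlation 0.21, thresholds (0, 1.855) placing base-generation incidences
near 49/37/14%.  Residual correlation (0.1) and fixed-effect magnitudes
(hatch SD 0.25, sex 0.3 phenotypic SDs) are unreported quantities set once
to realistic values.  A generation-restricted measurement mask reproduces
the traits recorded only at generation 6.

What the generator does **not** emulate: the real breeding scheme's
family-planned (BLUP-assisted) selection and overlapping-generation
demography; real-data features like scoring error, culling, non-normal
residuals, and genotype-by-environment structure.  Passing recovery tests
therefore demonstrate correctness of the estimator under the model's own
assumptions — not robustness to their violation.

Mass selection on own phenotype is used instead of the study's richer
scheme: it suffices to create the pHu-divergent, inbreeding-accumulating
structure the estimator must handle.  One consequence worth noting: a fit
that *excludes* the selection-criterion records of earlier generations is
biased by design (missing selection information), so recovery tests either
include those records or switch selection off.

## Validation design

- Closed-form oracles: truncated-normal moments; the 2×2 chi-squared
  statistic; Dempster–Lerner at p = 0.5 (factor exactly 2/π); textbook A
  identities and a path-counting kinship oracle; the trio A⁻¹ pattern.
- Dual-route checks: dense inverse of tabular A vs Henderson A⁻¹; Gibbs
  location-effect chain means vs a direct dense mixed-model-equations solve
  at fixed variances (and its σ²g → 0 limit vs OLS); LSMeans vs
  prediction-grid averages; the univariate inverse-Wishart vs scaled-inv-χ².
- Truth recovery at the study-like scale: n ≈ 3,000 birds over 4
  generations, h² ∈ {0.65, 0.20}, r_g ∈ {0.68, 0}, maternal c² = 0.10,
  reduced schedule, fixed seeds; posterior means within 2 posterior SDs.
- Diagnostic calibration: the Heidelberger–Welch stationarity test (Brownian
  bridge Cramér–von Mises with AR-estimated spectral density at zero, the
  boa/coda construction, including the four-term Bessel-series CvM CDF)
  passes ≥ 90% of iid chains and rejects ≥ 90% of chains with a 3-SD linear
  trend at α = 0.05.  At much stronger trends the AR spectral estimate
  saturates (near-unit-root fits inflate S(0)), reducing power — a known
  property of this estimator family, shared with the reference
  implementations.

## Numerical choices and degenerate inputs

Truncated-normal draws clamp CDF arguments to [1e−15, 1 − 1e−15] and pin
draws just inside interval bounds; intervals with numerically zero mass
return the nearer bound (midpoint if finite).  2×2 precision solves use
explicit Cholesky factors; a non-positive-definite covariance aborts with a
clear error.  Inverse-Wishart draws are symmetrized and re-drawn in the
(never observed in practice) non-PD case, with a counter in the ChainStore.
Empty WS categories, aliased fixed-effect designs beyond the intended
nesting (all-zero columns from empty line × WS cells are tolerated and the
cells excluded from LSMeans letters), cyclic or inconsistent pedigrees, and
invalid schedules are all hard errors.  The optional outlier filter
(|value − median| > k·MAD, default k = 5) is off by default and returns a
loggable mask rather than silently deleting records, because the original
cleaning criterion is not recoverable.

## Known limitations

- Single-site threshold/liability updates mix slowly in t₂; the full
  schedule (or a longer one) is needed at ~10,000-bird scale.
- Only bivariate (and univariate) fits; no > 2-trait models, maternal
  *genetic* effects, genomic relationships, or alternative samplers.
- The h² denominator for the maternal trait includes σ²c by default (the
  phenotypic-variance convention); the alternative excluding it can be
  recomputed from the stored draws.
- Significance via interval-excludes-zero is the field's operational rule,
  not a calibrated test.
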