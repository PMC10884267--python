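# Methods

This note documents the statistical model behind `comorbid`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not establish.

## Model overview

The package estimates the national prevalence of pairwise condition
combinations by combining two independently estimated ingredients per pair:
the marginal prevalences `Pᵢ, Pⱼ` of each condition (with 95% CIs), and an
odds ratio `θᵢⱼ` synthesised from heterogeneous studies. For two binary
conditions, `(Pᵢ, Pⱼ, θᵢⱼ)` pins down the full 2×2 joint distribution: the
joint prevalence `Pᵢⱼ` is the root of a quadratic (see README) lying inside
the Fréchet bounds `[max(0, Pᵢ+Pⱼ−1), min(Pᵢ, Pⱼ)]`. Everything downstream
— conditional comorbidity prevalences `Pᵢⱼ/Pᵢ`, expected comorbidity counts
`Mᵢ = Σⱼ Pᵢⱼ/Pᵢ` — is a deterministic function of these inputs.

Key modelling assumptions:

* The OR, not the joint prevalence, is the transportable quantity across
  study populations. ORs are unadjusted by construction — adjustment would
  break the algebraic link between the OR and the joint distribution — so
  they carry no causal interpretation.
* Marginal prevalence estimates are mutually independent, and independent
  of the ORs (they come from separate sources).
* Only pairwise structure is modelled; triple and higher combinations are
  out of scope.

## Evidence synthesis

**From tables to effects.** Per-study log ORs use the cross-product with
the Woolf variance `√(Σ 1/nₖ)`. When any cell is zero, 0.5 is added to all
four cells (Haldane–Anscombe). Both conventions are ours: they are the
field's defaults, and zero-free tables are left untouched. Study-level
prevalences are always taken from the table margins when a table is
available, which keeps the meta-regression moderator internally consistent
with the effect it moderates.

**Pooling rule.** Pairs with one or two estimates are pooled by
DerSimonian–Laird random effects (τ² floored at zero). With three or more
estimates a meta-regression of the log OR on the moderator `x = PᵢPⱼ` is
fitted instead. The threshold of three is the minimum at which a two-
parameter weighted line plus residual heterogeneity is identifiable at all;
users who distrust a k=3 regression can force pooling by calling
`pool_random_effects` directly.

**Why this moderator.** `x = PᵢPⱼ` is the expected prevalence of the
combination under independence. Sampling frames that under-represent
healthy individuals (clinics, insurance panels) mechanically inflate
cross-sectional associations; in the extreme all-patient frame the
association can invert. Down-weighting the no-condition cell of the
population 2×2 table by a retention factor φ multiplies the OR by exactly
φ — an algebraic identity the simulator reproduces and the tests assert —
and such frames also exhibit higher observed prevalences, so observed log
ORs decline in `x`. Regressing on `x` and predicting at the national
marginals standardises the OR to the national (full-population) frame.

**Estimation.** τ² for the meta-regression is estimated by REML, profiling
the restricted log-likelihood over τ² ∈ [0, max(10·var(y), 1)] with scalar
bounded minimisation (`xatol` 1e-10) and an explicit check of the τ²=0
boundary; if the profile optimisation fails the DerSimonian–Laird-type
moment estimator for weighted regression is used instead. The final
coefficients come from WLS at the selected τ², and their covariance is the
inverse information matrix `(XᵀWX)⁻¹` — exported whole because the
bootstrap samples `(m, c)` jointly. This matches `metafor::rma(method =
"REML")` to ~6 significant figures on simulated series (asserted in the
test suite). The Knapp–Hartung small-sample variance adjustment is
available (`knapp_hartung=True`, s² floored at 1) but off by default.

**Fixed external ORs.** A pair with no local evidence can be supplied an
externally pooled OR with a log-scale SE; it enters the pipeline as a
degenerate "pooled" association with τ² = 0.

## Numerical behaviour of the quadratic

* `|θ − 1| < 1e-8` branches to the exact independence limit `Pᵢⱼ = PᵢPⱼ`;
  the quadratic denominator `2(θ−1)` vanishes there. Continuity across the
  branch is asserted to 1e-8.
* The minus root is taken; it is the only root inside the Fréchet bounds
  for all θ > 0 (asserted against a bisection oracle on a
  7 × 20 × 20 grid to 1e-10, and by round-trip to relative 1e-8).
* A discriminant negative by at most 1e-12 is treated as zero; anything
  more negative raises rather than clipping silently.
* Results are clipped to the Fréchet interval to absorb float drift only.

## Parametric bootstrap

Defaults: 10,000 iterations, percentile 95% CIs, prevalence floor 1e-6.
Draw order per pair is fixed — `Pᵢ` block, `Pⱼ` block, association block —
from a single seeded generator, so runs are bit-reproducible given
`(seed, n_iter)`; the pipeline derives per-pair generators from the run
seed via `SeedSequence.spawn`. Marginal draws are *truncated* (clipped) to
`(floor, 1−floor)` rather than redrawn, preserving the iteration count and
draw order; redraws are reserved for iterations where the quadratic has no
real root (essentially impossible for valid inputs — any θ > 0 with
marginals in (0,1) admits a bivariate Bernoulli — and a >1% redraw rate is
an error, not a warning). SEs for marginals are derived from printed 95%
CIs as full width / (2·1.959964), including asymmetric CIs, for which no
published convention exists.

`var(Mᵢ)` sums the per-pair conditional variances, treating pairs as
independent; the reported CI for `Mᵢ` is the normal approximation
`Mᵢ ± 1.959964·√var`, with a percentile CI of the summed conditional
replicates alongside. The independence approximation ignores the common
`Pᵢ` draws across pairs only across *separate* pair bootstraps (each pair
has its own generator), which is exactly the assumption stated; the
percentile CI shares nothing either, by the same construction.

For the OR of a meta-regression pair, both the point prediction at the
national marginals and the bootstrap mean (with percentile CI) are
reported; they differ under coefficient uncertainty because the surface is
exponential in `(m, c)`.

## Synthetic-data generator

The generator emulates the statistical structure the synthesis assumes:
per study, `(Pᵢ, Pⱼ)` uniform on configurable ranges (defaults 0.05–0.3 —
the range spanned by common chronic conditions in adult populations),
`log θ = c + m·PᵢPⱼ + N(0, τ)`, cells via the quadratic, optional healthy
retention φ (scalar or per-study range), multinomial counts at the study
size. It is pairwise only: each study×pair draws its own multinomial, with
no attempt at a consistent 10-variate binary distribution, because the
analysis consumes only pairwise tables. It has no age/sex structure, no
shared-risk-factor confounding, and no measurement heterogeneity in
condition definitions. Passing recovery tests therefore show the estimator
chain is self-consistent under its own assumptions — not that real-world
definition heterogeneity is handled, which lands in τ² by design.

Problem sizes used in the recovery and coverage tests — 50 studies of
5,000 people, 100 outer replicates; 200 outer × 2,000 inner bootstrap
replicates — are the package's choice of a desk-scale experiment large
enough for the asserted rates to be stable.

One calibration note: a recovery experiment's "within 2 SE" rate using the
information-matrix SE runs near 93–94% rather than 95.4% under multinomial
sampling, because the moderator is estimated from the same table as the
effect; the SEs are nevertheless exactly metafor's. Knapp–Hartung barely
moves this (the residual scale is ≈ 1).

## Known limitations

* No publication-bias diagnostics, no moderators beyond the prevalence
  product, no network structure across pairs.
* Marginal-prevalence draws are independent across conditions; genuinely
  correlated national estimates (e.g. from one survey) would need a joint
  sampling model.
* The conditional matrix and `Mᵢ` inherit any bias in the marginal tables;
  self-reported prevalence sources understate true burden.
* Combinations of three or more conditions are out of scope; `Mᵢ` is an
  expectation over pairs, not a distribution over counts.
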