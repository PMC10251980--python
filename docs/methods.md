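# Methods

## Model

Each trait pair is analysed under the standard animal model

    y = X b + Z u + e,   u ~ N(0, G0 ⊗ A),   e ~ N(0, R0 ⊗ I),

where `y` stacks one record per phenotyped bird for k = 2 traits, `X`
encodes the fixed effects (intercept and sex; sex is the only systematic
environmental effect modelled, as the rearing design is otherwise
uniform), `Z` maps records to breeding-value slots for *all* pedigreed
animals (unphenotyped base parents keep their slot and are inferred from
relatives), and `A` is the numerator relationship matrix. Records with a
missing value for either trait of the pair are dropped listwise; data
augmentation for partial records is a possible extension, not
implemented.

Priors: flat on `b`; `G0 ~ IW(ν_A, V_A)` and `R0 ~ IW(ν_E, V_E)` in the
convention `p(S) ∝ |S|^{-(ν+k+1)/2} exp(-tr(S⁻¹V)/2)` (mean
`V/(ν-k-1)`). Defaults are weakly informative: ν = k+1 and scale equal
to half the sample phenotypic covariance for each block, i.e. a vague
prior centred on a 50:50 genetic:residual split. Both are overridable;
at the default flock size the data dominate (the prior scale enters the
full-conditional scale matrices at ~0.1% of the data cross-products).

## Gibbs sampler

A systematic scan draws, per iteration:

1. `b` from its multivariate-normal full conditional (precision
   `R0⁻¹ ⊗ X'X`);
2. each animal's k-variate breeding-value block from its normal full
   conditional. The conditional of animal *i* involves only the entries
   of row *i* of `A⁻¹` (parents, progeny, mates), so single-site
   Gauss–Seidel updates cost O(nnz(A⁻¹)·k²) per sweep and no dense
   system is ever factorized. The inner loop is compiled with numba; all
   random numbers come from a single `numpy` Generator seeded by the
   chain config, so chains are bit-reproducible.
3. `G0 ~ IW(ν_A + q, V_A + U'A⁻¹U)` with q the pedigree size;
4. `R0 ~ IW(ν_E + n, V_E + E'E)`.

Inverse-Wishart draws use the Bartlett decomposition. `A⁻¹` is built
directly by the Henderson/Quaas rules with inbreeding (Mendelian
variance `d_i = ½ − ¼(F_s + F_d)` etc.); `A` itself, needed only for
tests and small-problem oracles, uses the tabular method and is kept
dense (the design scale, ~10³ animals, makes this trivial).

Passing `a_inverse=None` drops the genetic term, leaving Bayesian
multivariate regression. This reduction exists because it admits an
*exact* closed-form check: with a flat prior on the mean, the marginal
posterior of the residual variance is scaled-inverse-χ²(ν+n−p), and the
test-suite verifies the sampler's marginal against it by KS distance.
With breeding values in the model there is no closed-form marginal, so
the sampler is instead validated against (a) brute-force grid
integration of the exact (σ²_a, σ²_e) posterior — marginalizing `b` and
`u` analytically — on a small single-trait flock, and (b) prior
recovery with zero records.

Chain defaults mirror the reference configuration: 110,000 iterations,
10,000 burn-in, thinning 50, retaining exactly 2,000 samples. The
recovery tests and the acceptance script use a scaled-down chain
(11,000 / 1,000 / 5, also 2,000 retained samples), which the grid and
multi-chain comparisons show is amply converged for this model: chains
started from different seeds agree to ±0.01 in posterior mean
heritability. Problem sizes were chosen so one recovery run takes a few
seconds.

## Posterior summaries

Heritability and correlations are computed **per retained sample** and
then summarized — never as ratios of posterior means (the two differ for
skewed posteriors; a regression test enforces the distinction). MCSE
uses non-overlapping batch means with ~√n batches. The 95% HPDI is the
shortest contiguous window containing ⌈0.95·n⌉ sorted samples, which
assumes a unimodal posterior; the summary carries a flag that fires if
the HPDI comes out wider than the equal-tailed interval, which cannot
happen for unimodal samples. Equation guide: heritability is the
diagonal ratio σ²_a/(σ²_a+σ²_e); the genetic correlation is
σ_a(i,i′)/√(σ²_a(i)σ²_a(i′)); phenotypic correlations come from
P0 = G0 + R0.

## Synthetic flock

The generator's defaults encode the study design it emulates: 40 sires
each mated to 3 dams (120 dams), 700 offspring (860 pedigreed animals),
near-balanced clutches of 5–6 chicks per dam (eggs are collected from
every dam over a fixed window, so family sizes differ by at most one),
a 1:1 offspring sex ratio, weekly weighings at 0–42 d, and feed
measured at group feeders of 4–8 birds.

Trait ground truth (means, phenotypic SDs, heritabilities, sex
contrasts, genetic/phenotypic correlation structure for the 11 traits
BW5–6, FI5–6, FCE5–6, β₀, β₁, β₂, IPT, IPW) lives in
`coturnix.presets`; these are values characteristic of an unselected
growing Japanese quail flock and define what "recovery" means in the
tests. Covariance blocks assembled from independently rounded pairwise
correlations can be marginally indefinite; they are repaired by
eigenvalue clipping with a warning.

Breeding values are simulated by Mendelian-sampling gene dropping:
founders ~ N(0, G0), offspring = parent average + deviation with
covariance `d_i·G0`. This yields Cov(u) = A ⊗ G0 exactly without ever
forming A ⊗ G0 (verified by Monte-Carlo against the tabular A). Two
generation modes exist: `direct` (traits drawn jointly from configured
G0/R0 — the clean generative model used for recovery testing) and
`mechanistic` (per-bird Gompertz curves simulated from a direct
(β₀,β₁,β₂) block, weekly weights with N(0, 2 g²) scale noise, and the
inflection-weight identity IPW = β₀/e plus small derivation noise).
A 2 g weighing SD reproduces the reference goodness-of-fit band
(R² ≥ 0.9978 for ≥95% of birds) and is consistent with a 0.01 g balance
plus handling variation.

`exact_variance=True` additionally whitens the founder, Mendelian and
residual standard-normal pools to identity sample covariance before
scaling, so the realized flock's variance components equal the nominal
truth instead of a finite-population draw. This is a standard
variance-reduction device for parameter-recovery studies: it makes
"truth" in a recovery experiment the stated parameter value rather than
whatever a particular founder sample realized. It is off by default.

Feed-intake residual variance includes a cage-level component: a
configurable fraction (default 0.2) of the FI residual variance is a
deviation shared by all birds on one feeder, leaving each bird's total
residual variance at R0. Because in practice the feeder total is the
measured quantity, `split_group_intake` offers equal and
weight-proportional redistribution rules alongside the latent
individual values; no single rule is canonical, so all are exposed.

What the generator does **not** emulate: selection or multiple
generations, mortality and culling, maternal or common-environment
effects beyond the feeder group, non-normal trait distributions, and
genotype–sex interaction (the sex effect is purely additive). Passing
recovery tests therefore demonstrates correctness of the estimation
machinery under the model's own assumptions, not robustness to
violations of them.

## Recovery experiments and their precision

With 700 phenotyped offspring in 40 sire families, the posterior SD of
a body-weight heritability is ≈0.09–0.10; the replicate-to-replicate
scatter of the posterior mean around a true h² of 0.61 is of the same
order (the exact-posterior grid oracle confirms the sampler adds no
avoidable error). Recovery assertions are therefore made at the
matching scale: posterior mean within ±0.10 of truth and 95% HPDI
covering truth in ≥90% of ten replicate seeds for heritability, ±0.05
for the genetic correlation between the two body weights, and the
acceptance script reports the average over five replicate recovery runs
so that the reported value estimates the method's expected posterior
mean under the study design rather than one noisy draw.

## Numerical choices

* Gompertz fitting: trust-region-reflective least squares, self-start
  (β₀ = 1.2·max weight; β₂ from the slope of the double-log
  linearization; β₁ from the hatch-weight ratio), lower bounds
  (1 g, 10⁻³, 10⁻⁴ /day) to exclude degenerate flat curves, SSE
  tolerance 10⁻¹⁰, ≤500 iterations. Non-convergence and
  at-bound solutions are flagged, never silently accepted. Hatch-day
  weight is included in fits; ages are in days throughout.
* Pedigree files code unknown parents as 0; pedigrees are
  topologically sorted (stable Kahn) before any matrix work, and
  duplicate ids, unknown parent references and cycles raise distinct
  error classes.
* IPT is reported as-is when β₁ < 1 (inflection before hatch), never
  clipped.
* The t-test for sex contrasts is pooled-variance by default (Welch
  behind a flag); the KS normality test estimates mean/SD from the
  sample and carries the usual Lilliefors caveat.
* Whether the reported spread of a genetic correlation is a posterior
  SD or an MCSE is ambiguous in common reporting practice; both are
  computed and emitted.
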