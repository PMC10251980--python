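# coturnix

Pedigree-based Bayesian estimation of genetic parameters for growth-curve
and feed-efficiency traits in Japanese quail (*Coturnix coturnix
japonica*), built for quantitative geneticists designing multi-trait
selection programmes in poultry.

## What it does

Breeding programmes need heritabilities and genetic correlations for the
traits under selection. This package implements the full analysis chain
for a quail growing flock:

1. **Per-bird growth curves.** Weekly body weights from hatch to 42 d are
   fitted with the Gompertz model

   $$y_t = \beta_0\, e^{-\beta_1 e^{-\beta_2 t}},$$

   with asymptotic weight $\beta_0$ (g), scaling constant $\beta_1$ and
   instantaneous growth rate $\beta_2$ (/day). The curve inflects at age
   $\mathrm{IPT} = \ln\beta_1/\beta_2$ days and weight
   $\mathrm{IPW} = \beta_0/e$ g.

2. **Variance components by a bivariate animal model.** For a trait pair,

   $$\mathbf{y} = \mathbf{X\beta} + \mathbf{Zu} + \mathbf{e}, \qquad
     \mathbf{u} \sim N(\mathbf{0}, G_0 \otimes A), \qquad
     \mathbf{e} \sim N(\mathbf{0}, R_0 \otimes I),$$

   with $A$ the numerator relationship matrix over all pedigreed animals,
   a flat prior on the fixed effects (intercept + sex) and conjugate
   inverse-Wishart priors on $G_0$ and $R_0$. Estimation is by a
   systematic-scan Gibbs sampler written here from scratch: fixed effects
   and each animal's breeding-value block are drawn from their normal
   full conditionals (single-site updates exploiting $A^{-1}$ sparsity),
   and the covariance blocks from their inverse-Wishart full
   conditionals.

3. **Posterior genetic parameters.** Per retained sample,
   $h_i^2 = \sigma^2_{ia}/(\sigma^2_{ia}+\sigma^2_{ie})$ and
   $r_{g,ii'} = \sigma_{ii'a}/\sqrt{\sigma^2_{ia}\sigma^2_{i'a}}$,
   summarized by mean, median, SD, batch-means MCSE, equal-tailed 95%
   credible interval and 95% highest-posterior-density interval.

4. **Synthetic flock generator.** Because individual quail records of
   this kind are rarely public, a generator simulates flocks with exactly
   the structure the model assumes — 40 sires × 120 dams (nested) → 700
   phenotyped offspring (860 pedigreed animals), multivariate breeding
   values via Mendelian-sampling gene dropping, a sex effect, shared
   feeder-group deviations on feed intake, and per-bird Gompertz
   trajectories — so every stage is testable and recovery of known truth
   can be demonstrated end to end.

## Worked example

```python
from coturnix import (FlockConfig, simulate_flock, ModelSpec, ChainConfig,
                      build_design, gibbs_sample, a_inverse, heritability,
                      genetic_correlation, summarize_chain)

data = simulate_flock(FlockConfig(seed=11, exact_variance=True))
spec = ModelSpec(traits=("BW5", "BW6"))
design = build_design(data.phenotypes, data.pedigree, spec)
post = gibbs_sample(design, a_inverse(data.pedigree), spec,
                    ChainConfig(n_iterations=11_000, burn_in=1_000,
                                thin=5, seed=1))
h2 = summarize_chain(heritability(post.g0, post.r0, 1), name="h2_BW6")
rg = summarize_chain(genetic_correlation(post.g0, 0, 1), name="rg_BW5_BW6")
```

which prints, via the summaries:

```
retained samples : 2000
h2(BW6)  mean 0.64  sd 0.09  95% HPDI (0.49, 0.82)
rg(BW5,BW6) mean 0.92  sd 0.03  95% HPDI (0.87, 0.97)
```

The flock was simulated with a true 6-week body-weight heritability of
0.61 and a true genetic correlation of 0.92 between 5- and 6-week body
weight; the posterior recovers both within one posterior SD. A complete
report bundle (descriptive table with sex-contrast *t*-tests, growth
fits, heritability and correlation tables, Markdown report) comes from
the CLI:

```sh
coturnix report --seed 11 --out run/
```

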