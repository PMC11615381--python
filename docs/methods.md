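# Methods

## Liability-threshold correlations by FIML

A binary diagnosis is modelled as `Y = 1{Z > τ}` with `Z` standard normal.
For a pair of family members the latent `(Z₁, Z₂)` are bivariate normal with
correlation `r`; the four cell probabilities of the observed 2×2 table are
upper-orthant probabilities

```
P(Z₁ > τ₁, Z₂ > τ₂ ; r),
```

and sign flips turn every cell into an orthant of the same family. The
likelihood is maximized jointly over the thresholds (with covariate slopes)
and `atanh r`. Mixed pairs use the polyserial decomposition — normal density
of the continuous member times the conditional probit probability
`Φ((r z_x − τ)/√(1−r²))` of the binary member — and continuous pairs use the
bivariate-normal density. Each record contributes the likelihood of its
observed subset: singletons add a marginal probit or normal term, fully
missing rows add nothing. With complete continuous data the Pearson fit is
taken in closed form (per-variable least-squares residualization, sample
correlation of residuals), which coincides with the FIML maximum.

Covariates ("definition variables") enter linearly on thresholds (binary) and
means (continuous) only; the correlation itself carries no covariate effects.
Adjusting a partner correlation for *both* partners' education puts both
education values in both members' models, so the estimate is the conditional
(partial) correlation of the liabilities given the education pair — under
joint normality a constant, which is what the estimator returns.

### Numerical choices

- Optimizer: L-BFGS-B on the unbounded parameterization (`atanh r`, log sd),
  objective tolerance 1e-12 relative (`ftol`), gradient tolerance 1e-7.
- Bivariate orthant probabilities are exact (Owen's-T decomposition of the
  bivariate normal CDF, vectorized); 3- and 4-dimensional orthants use
  sequential conditioning: Gauss–Legendre quadrature (32 nodes by default in
  the kernel, 20 in the quad model) over the leading one or two coordinates
  with the exact bivariate CDF of the conditional remainder. This is fully
  deterministic — identical inputs give identical log-likelihoods — and
  agrees with randomized integrators to ~5e-6.
- Standard errors come from the observed information (central-difference
  Hessian); confidence intervals are delta-method intervals on the `atanh`
  scale, transformed back. A two-stage mode (thresholds from probit-inverted
  margins, 1-D profile of `r`) is available; joint FIML is the default.
- Estimates with `|r| > 0.999` are flagged (`converged = False`,
  `boundary = True`) because threshold likelihoods flatten near ±1; values
  are clipped to ±0.9999 so downstream `atanh` stays finite.
- Tetrachoric fits group records by (covariate pattern × cell), so the cost
  per objective evaluation is the number of distinct patterns, not n.
- Degenerate inputs raise `EstimationError`: no complete pairs, a single
  occupied cell, zero variance, or fewer than three continuous pairs.

## The four-person model and the direct-assortment test

The quad (index, partner, index's sibling, partner's sibling) has the
correlation structure

|            | partner | sib_index | sib_partner |
|------------|---------|-----------|-------------|
| index      | r_p     | r_s       | r_i         |
| partner    |         | r_i       | r_s         |
| sib_index  |         |           | r_c         |

with one shared sibling correlation, one shared in-law correlation, and a
free co-sibling-in-law correlation `r_c`. Continuous traits are fit by
multivariate-normal FIML on per-group sufficient statistics, where a group is
a (missingness pattern × covariate pattern); this makes each objective
evaluation O(groups) independent of sample size. Binary traits use the
orthant machinery above in up to four dimensions, with records grouped by
(pattern × cell × covariate) configuration. Quads missing members contribute
their marginal sub-model (trivariate, bivariate, or univariate), which is how
couples without observed siblings enter the likelihood. Sex adjustment enters
thresholds/means only, with one shared slope per trait.

The constrained model sets `r_i = r_p · r_s` by reparameterization, so
nesting is exact, and positive semidefiniteness is enforced with an
eigenvalue barrier during optimization (a non-PSD proposal is never
returned). The direct-assortment test is the 1-df chi-square on
`2(llfree − llconstrained)`, clipped at zero; a constrained log-likelihood
exceeding the free one beyond 1e-4 raises a refit signal instead of reporting
a negative statistic. p-values across traits are FDR-adjusted
(Benjamini–Hochberg, via statsmodels, with local input validation).

The equality test between two sets of correlations (e.g. prospective vs
cross-sectional windows) is the sum over traits of squared standardized
differences on the `atanh` scale, chi-square with df = number of constraints.
This Wald form is asymptotically equivalent to the likelihood-ratio version
and needs only the estimates and their standard errors; that trade-off was
made deliberately because the natural interface passes estimate sets, not raw
data.

## Mechanism generators

All mechanisms are expressed in one latent-factor representation. Each
member's phenotype is `A = a·M + √(1−a²)·U`; the four members' factors `M`
follow the chain "index — (copath μ) — partner", with each sibling attached
at `r_m`, giving the factor correlation matrix with entries `μ`, `r_m`,
`μ r_m`, and `μ r_m²`. Sibling residuals correlate `r_e`. Direct assortment
is `a = 1, μ = m, r_m = r_s`; stratification is `a = q` with a single shared
stratum (`μ = r_m = 1`). The population is drawn as one joint
multivariate-normal sample via Cholesky — mathematically identical to
sequential conditional ("mate formation") sampling, and exact for the
path-traced expectations:

- direct: `(m, r_s, m r_s)`, IIF = 1 (and `r_c = r_s m r_s`);
- indirect: `(a²μ, a²r_m + E, a²μr_m)` with `E = (1−a²) r_e`,
  IIF = `1/(a² + E/r_m)` — equal to `1/a²` when `r_e = 0` and exactly 1 when
  `r_e = r_m`;
- stratification: all `q²`, IIF = `1/q²`.

Because the chain construction is realizable for any parameters strictly
inside (−1, 1), range validation *is* the admissibility check; multitrait
loading vectors are additionally checked for positive semidefiniteness of the
implied covariance.

Binary traits are dichotomized at the empirical upper-tail quantile of the
liability at the stated prevalence (for Gaussian liabilities this is the
probit threshold up to sampling noise; the empirical form also covers skewed
liabilities). Default design values are fixed once as the study conditions
the generator emulates: 83.2% sibling availability (the registry's sibling
coverage), no extra missingness, opposite-sex couples with random index sex,
birth years uniform on 1970–1990, and no sex effect on liabilities unless
requested.

**Convergence overlay.** A couple-shared Gaussian component of variance `n2`
is added to both partners, then simultaneous mutual influence mixes them:
`A″ = (A + x·partner(A))/(1−x²)`, followed by re-standardization so
correlations stay on the unit-variance scale. The closed-form expectations
(e.g. `r_partner = (m+n2)/(1+n2)` at `x = 0`, in-law and sibling correlations
shrunk by `√var`) are implemented alongside and verified against simulation;
the overlay always deflates the IIF. The simultaneous-linear reading of
mutual influence is one consistent interpretation of a mechanism the source
material leaves underspecified.

**Skewed liabilities.** The robustness experiment applies one common
monotone sinh–arcsinh transform `z ↦ sinh(asinh(z) + γ)` (γ < 0 for left
skew) to the correlated Gaussian draw, then standardizes. Because the
transform is monotone, dichotomizing the skewed liability at a prevalence
quantile is the same cut as on the underlying Gaussian, so the dichotomized
tetrachorics recover the Gaussian-copula correlations — the chain product
identity survives exactly — while each tetrachoric overstates the Pearson
correlation of the skewed variables. An additive-skewed-innovations
construction was considered and rejected: it breaks the copula and leaves a
small systematic residual in the product identity, which is not the
phenomenon the robustness claim describes.

## What the generator does and does not emulate

It reproduces: the quad sampling frame with partial sibling coverage,
liability-scale correlation structures of the four mechanisms and their
combinations, multitrait structure through a single mating factor with an
education-like continuous trait, realistic prevalences (e.g. 1.60% substance
use, 9.09% depressive disorder), covariate effects on thresholds/means, and
missingness by independent thinning.

It does not emulate: finite mating markets or preference heterogeneity,
age/cohort structure in assortment strength, diagnosis-code measurement
error, informative (non-random) missingness, more than one sibling per side,
or same-sex couples. Passing tests therefore demonstrate correctness of the
estimators and tests under the stated generative models, not that any
particular registry estimate is right; the registry correlations themselves
are not reproducible from synthetic data, and only the printed worked
examples (IIF arithmetic) are anchored to published numbers.

## Descriptives and the logistic check

Conditional prevalences ("prevalence among partners of affected") pool both
directions of each relative pair, with Wilson confidence intervals and a
small-cell disclosure rule (counts below 10 suppressed, configurable). The
logistic check regresses the index diagnosis on the partner's and the
sibling-in-law's phenotypes jointly (IRLS via statsmodels, relative tolerance
1e-10, 50 iterations max, separation flagged by error or a coefficient
monitor at |β| > 15). Under assortment on the observed binary phenotype the
in-law odds ratio is null once the partner is adjusted for. Under assortment
on the *liability*, the binary partner phenotype is an incomplete proxy for
the matched score, and a residual in-law association remains — the package's
tests cover both regimes, and the distinction is worth keeping in mind when
reading adjusted odds ratios for dichotomized traits.

## Pipeline

`run_pipeline` sequences simulation/loading, per-arm correlation matrices,
quad fits with the direct-assortment LRT and FDR adjustment, category
medians, and percent-reduction summaries, and embeds provenance (config
hash, seed, version) so a report regenerates identically from its stored
config. One trait failing to fit warns and continues rather than aborting
the run. Percent reduction is `100·(1 − r_adj/r_unadj)`, undefined (missing)
at `r_unadj = 0`; note that computing it from rounded printed correlations
can differ by a few points from the value obtained from unrounded estimates
(e.g. 0.14 → 0.10 gives 28.6% rounded but can be ~31% unrounded).

## Problem sizes

Defaults used by the shipped analyses: 200,000 quads for the mechanism
identity runs (Monte-Carlo SE of a correlation ≈ 0.002), 100 replicates of
20,000 quads for the LRT level check, 50,000 pairs for the estimator
recovery grid, and 120,000–150,000 quads for the adjustment and skewness
experiments. These sizes put three Monte-Carlo standard errors well inside
the scientific tolerances being asserted while keeping any single run in
seconds.

## Known limitations

- Orthant probabilities (and hence binary quad fits) are implemented to
  dimension 4; chained in-law networks beyond the quad are out of scope.
- Polychoric ladders with more than two categories, survey weights, and
  rank-based correlations are not implemented.
- The quad model's covariates should be categorical (sex); continuous
  covariates like birth year are supported in the pairwise estimators, where
  likelihood grouping is by covariate pattern.
- Indirect assortment and social stratification both inflate the IIF and are
  not distinguishable from quad data alone; the package reports the
  inflation, not its source.
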