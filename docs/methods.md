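# Methods

## Model family

The package fits hierarchical count models for an areal panel `Y_it`
(`i = 1..n` tracts, `t = 1..T` periods) with known exposure `P_i`:

    Y_it ~ Poisson(P_i λ_it)        or NB(mean P_i λ_it, dispersion θ)

with `log λ_it` decomposed into fixed effects (intercept, tract-year
covariates, temporal indicators) and Gaussian random effects: the BYM pair
`s_i` (intrinsic CAR) + `v_i` (iid), and for the random-walk models
`γ_t` (RW1) + `φ_t` (iid), optionally plus an iid space–time interaction
`δ_it` (Knorr-Held Type I). The negative-binomial parameterization is
mean `μ`, variance `μ + μ²/θ`, so θ → ∞ recovers the Poisson.

Assumptions worth stating: populations are constant over the study window;
covariates step at calendar-year boundaries (a monthly cell takes its
year's value, so fitted tract curves may cross only at year ends in the
additive model); the ICAR field uses binary contiguity weights; the data
are an ecological panel — area-level associations carry no individual-level
interpretation.

## Priors and identifiability

Defaults: intercept flat (`prec = 0`), slopes `N(0, prec 0.001)`, every
precision `τ ~ gamma(shape 1, rate 0.00005)` (exponential, mean 20,000),
and for NB a vague normal on `log θ` (`prec 0.001`). All are overridable
through `PriorConfig`; the prior-sensitivity grid ships alternatives
(intercept `N(0, prec 0.001)`, slopes `N(0, prec 0.1)`, precisions
`gamma(0.5, 0.0005)`).

The intrinsic CAR prior is improper (rank `n − c` for `c` connected
components); identifiability is restored by the hard sum-to-zero
constraint on `s`. The random walk is pinned at `γ_0 = 0` so its level is
absorbed by the intercept. `γ_t` and `φ_t` (and `v_i` vs. `s_i`) are
separated only by their priors, as is standard in BYM-type models; their
individual precisions are therefore weakly identified, while their sums —
and everything reported about rates — are well identified.

## Posterior computation

Inference is Markov chain Monte Carlo (Metropolis-within-Gibbs), chosen
because the estimand — posterior means and 2.5/97.5% quantiles of all
parameters plus fitted rates — is testable against closed forms and
simulation, whatever the approximation engine. Design of the sampler
(`stcar.mcmc`):

* **Fixed effects.** Covariate fields are internally mean-centered
  (removing the dominant intercept–slope correlation; the intercept is
  mapped back on output). Coordinate-wise adaptive random-walk Metropolis
  is augmented, once warmup has accumulated history, by a joint
  Haario-style update whose proposal covariance is the empirical
  covariance of warmup draws (scaled `2.38²/p`, adapted to ~0.23
  acceptance).
* **ICAR field.** The lattice is greedily colored; sites within a color
  class have mutually independent full conditionals and are updated as a
  vectorized batch. After each sweep the field is recentered with the
  shift absorbed into the intercept — under the flat intercept prior this
  is an exact invariance of the posterior; under an informative intercept
  prior it introduces an error of order (intercept precision × per-sweep
  shift), negligible at the vague settings shipped.
* **Slope–field ridge moves.** Spatially smooth covariates are partially
  confounded with the ICAR field. A dedicated move proposes a slope change
  together with the compensating change of `s` along the covariate's
  centered tract pattern (a symmetric, Jacobian-1 proposal): the
  likelihood barely moves and the ICAR prior governs acceptance. Analogous
  likelihood-invariant location swaps exchange level between the intercept
  and `v`, `γ`, and `φ`. Without these moves the slope effective sample
  size at n = 25 is an order of magnitude smaller.
* **iid fields and interaction.** `v`, `φ` and `δ` have independent full
  conditionals and are updated in fully vectorized batches; `γ` uses
  even/odd coloring of the time chain.
* **Precisions.** Conjugate gamma Gibbs draws; the ICAR quadratic form is
  `s'(D − W)s` with rank `n − c`.
* **NB dispersion.** Metropolis on `log θ` with the full likelihood.

All single-site proposal scales adapt toward 0.44 acceptance
(Robbins-Monro on the log scale) during warmup and are then frozen.
η is clipped at ±60 inside exponentials so unidentified directions (e.g.
fully masked cells) cannot overflow; rates beyond e⁶⁰ are unreachable for
any data of this kind. Chains are seeded via `numpy.random.SeedSequence`,
making every fit bit-reproducible; summaries report split-chain R-hat and
bulk ESS (via arviz), and a fit is flagged `converged = False` when any
reported parameter has R-hat ≥ 1.05 or ESS ≤ 100.

Validation: a flat-prior intercept-only fit reproduces the conjugate
Gamma(y, P) posterior of the rate (mean within 1%, interval endpoints
within 2%); on panels simulated from the year-indicator model at n = 25,
T = 4, k = 2, the 95% credible intervals for the slopes cover the truth at
an empirical rate of ~0.92 over 50 replicates.

## DIC

`Dbar` is the posterior mean of the unsaturated deviance `−2 log L`;
the plug-in deviance is evaluated at the posterior-mean cell rates
`λ̄_it = E[exp η_it]` (and posterior-mean θ for NB); `pD = Dbar − D(λ̄)`
and `DIC = Dbar + pD`. The plug-in choice follows the classical
definition and is applied identically across compared models, which is
all a DIC ranking requires. Differences ≤ 2 are reported as "similar".

## Moran's I

`I = (N/S0) Σ_ij w_ij (x_i − x̄)(x_j − x̄) / Σ_i (x_i − x̄)²` over
per-tract rates `Y_i/P_i` (counts are also accepted), with binary weights
by default (row-standardized optional) and null expectation `−1/(N−1)`.
Inference is a one-sided "greater" permutation test, default 999
permutations, with ties counted toward the numerator and the conservative
`(1 + #{I* ≥ I}) / (1 + n_perm)` p-value. Rates, binary weights and the
one-sided test are the epidemiological convention; all are configurable.

## VIF and effect translation

VIF pools tract-year rows and regresses each predictor on the others
(with intercept), optionally including calendar year as a single numeric
term; `VIF = 1/(1 − R²)`, with 5–10 flagged moderate and ≥ 10 strong, and
perfect collinearity reported as infinite rather than an error. Quartiles
use linear interpolation (the common statistical default; configurable in
that the effect translator accepts any externally computed quartiles), and
the Q1→Q3 effect is `exp(β̂ (Q3 − Q1))` — the ratio of expected counts at
the third vs. first quartile of one covariate, all else fixed.

## Synthetic data

The generator mirrors the model family exactly — ICAR fields drawn in the
Laplacian eigenbasis restricted to the sum-to-zero subspace (exact at desk
scale, O(n³)), RW1 by cumulated Gaussian increments, iid effects, Poisson
or NB counts — so recovery tests are internally consistent. Default
conditions emulate an urban tract system: ~100 contiguous tracts (10×10
grid; any rows×cols works), years 2018–2021 (T = 4 yearly, 48 monthly),
populations log-uniform on [200, 3000] (tract counts of reproductive-age
women), and five covariates with realistic levels and spatial smoothness
(% private insurance ≈ 55, % public insurance ≈ 30, median age ≈ 36,
median income ≈ 45 in thousands of dollars, % high-school diploma ≈ 85;
percentages clipped to [0, 100]). Income is carried in thousands of
dollars so its slope is O(0.01) like the other covariates; the unit is a
declared convention, not a constraint. Year-to-year covariate drift is
N(0, 1) by default — "usually small" relative to between-tract spread.
Default fixed effects (`β0 = −4`, slopes ≈ 0.0006/0.0117/0.0134/−0.0046/
0.0073, year effects 0.07/−0.18/−0.28) give tract-year cell counts of a
few dozen, the magnitude seen in urban mental-health ED surveillance.
Default precisions (τ_s = 10, τ_v = 25, τ_γ = 100, τ_φ = 400,
τ_δ = 100) put the spatial field's variation at roughly the scale of the
covariate effects.

What the generator does **not** emulate: real tract geography (grids have
more regular neighbor structure than census tracts), population change
over time, visit-level covariate measurement error, seasonality beyond
what RW1 can absorb, and patient-level repeat-visit dependence. Passing
recovery tests therefore demonstrates correctness of the machinery under
the stated generative assumptions, not robustness to their violation.

## Numerical and design choices

* Tract order is lexicographic, fixed when a lattice is built; all arrays
  follow it. Queen contiguity (shared point suffices) is the default when
  deriving adjacency from polygons; rook is available.
* Edge lists may list each undirected edge once or in both directions; a
  mixture is ambiguous and rejected unless `symmetrize=True`.
* The ICD-10 substance-use entries F10–F19 are three-character stems and
  are matched by prefix; all other entries match exactly. Records with no
  mappable code are excluded from panels but counted in a log summary.
  Undotted and symptom-code entries (F32A, R45.7, R46.81) are carried
  verbatim as published; the intended code-system dialect is not stated
  in the source, so no normalization is attempted.
* Periods are half-open calendar bins assigned by visit date; the
  pre/during-pandemic split is at 1 January 2020.
* Yearly indicator models use the panel's first calendar year as the
  reference category.
* Zero-variance rate vectors make Moran's I undefined and raise.
* Monte-Carlo test scales (replicate counts, chain lengths, lattice
  sizes) were chosen to make each check decisive at desk scale: e.g. 50
  recovery replicates at n = 25 with 3,500 iterations per chain, and 25
  DIC comparisons with a year pattern far from any pandemic-indicator
  fit, where selection is essentially deterministic.

## Known limitations

* The sampler is exact-in-the-limit MCMC, not a deterministic
  approximation: short chains on weakly identified models (notably τ_γ
  vs. τ_φ) can be flagged unconverged and should be re-run longer.
* DIC uses the plug-in at posterior-mean rates; alternatives (posterior
  mean of θ vs. median, WAIC) are not implemented.
* Type II–IV space–time interactions and distance-based spatial
  covariances are out of scope by design.
* GeoJSON contiguity does polygon-pair intersection tests in O(n²);
  adequate for thousands of tracts, not for national maps.
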