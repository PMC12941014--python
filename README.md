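# stcar

Hierarchical Bayesian spatio-temporal models for areal count panels —
disease-mapping infrastructure for small-area emergency-department (ED)
surveillance, built for studies of mental-health ED visits at census-tract
level where the raw discharge records are confidential and methods must be
developed and validated on synthetic data with known parameters.

## Who it is for

Epidemiologists and biostatisticians analyzing counts `Y_it` of events
(here: ED visits with a mental-health diagnosis) in areal unit `i` during
period `t`, with a known population at risk `P_i` per unit, who want to

* quantify spatial autocorrelation (Moran's I with permutation inference),
* fit Poisson / negative-binomial rate models with spatially structured
  (BYM/ICAR) and unstructured random effects and several temporal
  structures, on counts offset by `log P_i`,
* compare temporal structures by DIC,
* translate fitted slopes into interpretable Q1→Q3 rate ratios,
* and exercise all of the above end-to-end on simulated data whose latent
  parameters are known.

## The models

All five models assume `Y_it ~ Poisson(P_i λ_it)` (or negative binomial
with the same mean and dispersion θ) and differ in `log λ_it`:

| # | temporal structure | `log λ_it` |
|---|---|---|
| 1 | year indicators (ref. 2018) | `β0 + x'β + α19 x_{1,19} + α20 x_{1,20} + α21 x_{1,21} + s_i + v_i` |
| 2 | pandemic indicator (2020–21) | `β0 + x'β + αCOVID x_COVID + s_i + v_i` |
| 3 | RW1 over years | `β0 + x'β + s_i + v_i + γ_t + φ_t` |
| 4 | RW1 over months (T = 48) | same as 3, monthly |
| 5 | 4 + Type I space–time interaction | `... + δ_it`, `δ_it ~ iid N(0, 1/τ_δ)` |

`v_i ~ iid N(0, 1/τ_v)` is unstructured heterogeneity; `s_i` is an
intrinsic CAR (ICAR) field — conditionally `s_i | s_neighbors ~
N(s̄_i, 1/(τ_s m_i))` with `m_i` the neighbor count — constrained to sum to
zero; `γ_t ~ N(γ_{t-1}, 1/τ_γ)` is a first-order random walk and
`φ_t ~ iid N(0, 1/τ_φ)`. Default priors: flat intercept, `N(0, prec 0.001)`
slopes, `gamma(1, 0.00005)` on every precision (an exponential with mean
20,000). Posteriors come from a validated Metropolis-within-Gibbs sampler
(see `docs/methods.md`); fits report split-chain R-hat, effective sample
sizes and `DIC = Dbar + pD`.

The package also ships the surrounding epidemiology: ICD-10 categorization
of visits into eight mental-health groups (multi-diagnosis visits count in
every matching category), pre/during-pandemic summary tables, VIF
multicollinearity screening, an eight-combination prior-sensitivity grid,
and readers/writers for plain-CSV adjacency, visit, panel and covariate
files (plus queen/rook contiguity from GeoJSON polygons).

## Worked example

`examples/02_fit_yearly_models.py` simulates a 36-tract, four-year panel
from the year-indicator model (with a year pattern a single pandemic
indicator cannot express) and fits Models 1–3:

```
Model 1 posterior summaries (truth in brackets):
  beta0                  -3.8964 (-4.7646, -3.0965)  [-4.0000]
  pct_public_insurance   +0.0161 (+0.0067, +0.0249)  [+0.0117]
  median_age             +0.0075 (-0.0139, +0.0304)  [+0.0134]
  year_2019              +0.2382 (+0.1794, +0.2991)  [+0.2500]
  year_2020              -0.1428 (-0.2081, -0.0737)  [-0.1500]
  year_2021              -0.4840 (-0.5582, -0.4104)  [-0.4500]

DIC comparison (lower is better; within 2 units = similar fit):
  model         DIC        Dbar        pD  similar_to_best
model_1  929.975051  895.050539 34.924512             True
model_2 1072.965342 1039.977643 32.987699            False
model_3  930.551555  895.288005 35.263550             True
```

Every 95% credible interval covers its generating value; the misspecified
pandemic-indicator model is ~143 DIC units worse, while the random walk
fits the smooth year pattern almost as well as the generating model. The
other examples cover Moran's I (`01`), VIF and Q1→Q3 effects (`03`),
monthly models with and without space–time interaction (`04`), ICD-10
categorization (`05`) and prior sensitivity (`06`). A thin CLI mirrors the
library (`stcar simulate|moran|fit|compare|effects|vif|timeseries|demo|pipeline`);
`stcar demo --out DIR` runs a small end-to-end pipeline.

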