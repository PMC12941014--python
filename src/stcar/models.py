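"""Model specifications and design construction for Models 1-5.

All five models share the count likelihood ``Y_it ~ Poisson(P_i * lambda_it)``
(or negative binomial with the same mean) and the BYM pair of tract-level
random effects: a spatially structured ICAR field ``s`` and an unstructured
i.i.d. field ``v``.  They differ in the temporal structure of
``log lambda_it``:

* ``YEAR_INDICATORS``   - fixed effect per year (reference = first year).
* ``COVID_INDICATOR``   - single indicator for the pandemic years (>= 2020).
* ``RW1_YEAR``          - first-order random walk over years + i.i.d. year
  effects ``phi_t``.
* ``RW1_MONTH``         - the same structure over months (T = 48 for a
  four-year window).
* ``RW1_MONTH_TYPE1``   - adds an i.i.d. space-time interaction ``delta_it``
  for every (tract, month) cell (Knorr-Held Type I).

Covariates step at calendar-year boundaries: a monthly cell takes its
calendar year's covariate value.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .panel import CountPanel, CovariateTable

__all__ = [
    "Temporal",
    "Likelihood",
    "PriorConfig",
    "ModelSpec",
    "Design",
    "build_design",
    "parameter_count",
]


class Temporal(str, enum.Enum):
    YEAR_INDICATORS = "year_indicators"
    COVID_INDICATOR = "covid_indicator"
    RW1_YEAR = "rw1_year"
    RW1_MONTH = "rw1_month"
    RW1_MONTH_TYPE1 = "rw1_month_type1"
    NONE = "none"  # intercept-only temporal structure (oracle/debug use)


class Likelihood(str, enum.Enum):
    POISSON = "poisson"
    NEGBIN = "negbin"


_MODEL_NUMBERS = {
    1: Temporal.YEAR_INDICATORS,
    2: Temporal.COVID_INDICATOR,
    3: Temporal.RW1_YEAR,
    4: Temporal.RW1_MONTH,
    5: Temporal.RW1_MONTH_TYPE1,
}


@dataclass(frozen=True)
class PriorConfig:
    """Priors for fixed effects and precision hyperparameters.

    Defaults follow the common disease-mapping convention: a flat improper
    prior on the intercept (precision 0), vague normal slopes
    ``N(0, prec=0.001)``, and ``gamma(shape=1, rate=0.00005)`` on every
    precision (an exponential with mean 20,000).  The negative-binomial
    dispersion gets a vague normal prior on its logarithm.
    """

    intercept_mean: float = 0.0
    intercept_precision: float = 0.0
    slope_precision: float = 0.001
    tau_shape: float = 1.0
    tau_rate: float = 0.00005
    nb_logdisp_mean: float = 0.0
    nb_logdisp_precision: float = 0.001


@dataclass(frozen=True)
class ModelSpec:
    """Which model to fit: temporal structure, likelihood, covariates, priors.

    ``spatial_effects=False`` drops both BYM fields (used by the conjugate
    oracle and available for degenerate lattices with n = 1).
    """

    temporal: Temporal
    likelihood: Likelihood = Likelihood.POISSON
    covariate_names: tuple[str, ...] = ()
    priors: PriorConfig = field(default_factory=PriorConfig)
    spatial_effects: bool = True

    @classmethod
    def model(cls, number: int, **kwargs) -> "ModelSpec":
        """Spec for the numbered model (1-5)."""
        if number not in _MODEL_NUMBERS:
            raise ValueError("model number must be 1..5")
        return cls(temporal=_MODEL_NUMBERS[number], **kwargs)

    @property
    def model_number(self) -> int | None:
        for k, v in _MODEL_NUMBERS.items():
            if v is self.temporal:
                return k
        return None

    def with_priors(self, priors: PriorConfig) -> "ModelSpec":
        return replace(self, priors=priors)

    @property
    def has_rw(self) -> bool:
        return self.temporal in (
            Temporal.RW1_YEAR, Temporal.RW1_MONTH, Temporal.RW1_MONTH_TYPE1
        )

    @property
    def has_interaction(self) -> bool:
        return self.temporal is Temporal.RW1_MONTH_TYPE1


@dataclass(frozen=True)
class Design:
    """Per-cell decomposition of the linear predictor.

    ``F`` stacks one (n, T) field per fixed effect (intercept first, then
    covariates, then temporal indicators); random-effect structure is carried
    by flags plus the period->year map used for covariate stepping.
    """

    fixed_names: tuple[str, ...]
    F: np.ndarray  # (p, n, T)
    has_rw: bool
    has_phi: bool
    has_interaction: bool
    period_years: np.ndarray

    @property
    def p(self) -> int:
        return self.F.shape[0]

    def linear_predictor(self, beta: np.ndarray) -> np.ndarray:
        """Fixed-effect part of ``log lambda`` as an (n, T) array."""
        return np.tensordot(np.asarray(beta, dtype=float), self.F, axes=1)


def build_design(
    spec: ModelSpec, panel: CountPanel, covars: CovariateTable | None
) -> Design:
    """Build the fixed-effect fields for ``spec`` on ``panel``.

    Raises if the temporal structure does not match the panel granularity
    (indicator models need yearly panels; RW1 month models need monthly
    panels) or if the covariate table does not cover every calendar year the
    panel touches.
    """
    yearly = panel.granularity == "year"
    t = spec.temporal
    if t in (Temporal.YEAR_INDICATORS, Temporal.COVID_INDICATOR, Temporal.RW1_YEAR):
        if not yearly:
            raise ValueError(f"{t.value} requires a yearly panel")
    if t in (Temporal.RW1_MONTH, Temporal.RW1_MONTH_TYPE1) and yearly:
        raise ValueError(f"{t.value} requires a monthly panel")

    n, T = panel.n, panel.T
    years = panel.period_years()
    uniq_years = sorted(set(years.tolist()))

    names: list[str] = ["(Intercept)"]
    fields: list[np.ndarray] = [np.ones((n, T))]

    if spec.covariate_names:
        if covars is None:
            raise ValueError("spec names covariates but no covariate table given")
        missing = set(uniq_years) - set(covars.years())
        if missing:
            raise ValueError(f"covariate table missing years {sorted(missing)}")
        X = covars.matrix(panel.tract_ids, uniq_years, spec.covariate_names)
        year_col = {y: j for j, y in enumerate(uniq_years)}
        cols = np.array([year_col[y] for y in years])
        for j, name in enumerate(spec.covariate_names):
            names.append(name)
            fields.append(X[:, cols, j])

    if t is Temporal.YEAR_INDICATORS:
        if len(uniq_years) < 2:
            raise ValueError("year indicators need at least two years")
        # first calendar year is the reference category
        for y in uniq_years[1:]:
            names.append(f"year_{y}")
            fields.append(np.broadcast_to((years == y).astype(float), (n, T)).copy())
    elif t is Temporal.COVID_INDICATOR:
        names.append("covid")
        fields.append(
            np.broadcast_to((years >= 2020).astype(float), (n, T)).copy()
        )

    return Design(
        fixed_names=tuple(names),
        F=np.stack(fields),
        has_rw=spec.has_rw,
        has_phi=spec.has_rw,
        has_interaction=spec.has_interaction,
        period_years=years,
    )


def parameter_count(spec: ModelSpec, k: int, n: int, T: int) -> dict[str, int]:
    """Parameter enumeration for the five models.

    Totals: Model 1 = k+2n+6, Model 2 = k+2n+4, Model 3 = k+2n+14 (T=4),
    Model 4 = k+2n+2T+6, Model 5 = k+2n+(n+2)T+7.  The random-walk models
    count the walk's starting value among the fixed effects.
    """
    if k < 0 or n < 1 or T < 1:
        raise ValueError("need k >= 0, n >= 1, T >= 1")
    t = spec.temporal
    if t is Temporal.YEAR_INDICATORS:
        if T != 4:
            raise ValueError("the year-indicator model is defined for T = 4 years")
        fixed, random, hyper = k + 4, 2 * n, 2
    elif t is Temporal.COVID_INDICATOR:
        if T != 4:
            raise ValueError("the COVID-indicator model is defined for T = 4 years")
        fixed, random, hyper = k + 2, 2 * n, 2
    elif t is Temporal.RW1_YEAR:
        if T != 4:
            raise ValueError("the yearly random-walk model is defined for T = 4")
        fixed, random, hyper = k + 2, 2 * n + 2 * T, 4
    elif t is Temporal.RW1_MONTH:
        fixed, random, hyper = k + 2, 2 * n + 2 * T, 4
    elif t is Temporal.RW1_MONTH_TYPE1:
        fixed, random, hyper = k + 2, 2 * n + (n + 2) * T, 5
    else:
        raise ValueError(f"no parameter enumeration for {t.value}")
    return {
        "fixed": fixed,
        "random": random,
        "hyper": hyper,
        "total": fixed + random + hyper,
    }
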