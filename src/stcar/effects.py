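"""Multicollinearity screening, Q1-to-Q3 effect translation, prior grid.

``vif`` screens the tract-year covariate rows for multicollinearity before
modelling; ``q1q3_effect`` translates a fitted log-rate slope into the
multiplicative change in expected visits as the predictor moves from its
first to its third quartile, ``exp(beta_hat * (Q3 - Q1))``; and
``prior_sensitivity`` refits a model under the 2x2x2 grid of
{default, alternative} priors for the intercept, the slopes and the
precision hyperparameters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fit import fit
from .lattice import TractLattice
from .mcmc import SamplerConfig
from .models import ModelSpec, PriorConfig
from .panel import CountPanel, CovariateTable

__all__ = ["EffectEstimate", "vif", "quartiles", "q1q3_effect",
           "effects_table", "prior_sensitivity", "ALTERNATIVE_PRIORS"]

VIF_INFINITE_R2 = 1.0 - 1e-10


@dataclass(frozen=True)
class EffectEstimate:
    """Multiplicative Q1-to-Q3 effect of one predictor on the visit rate."""

    predictor: str
    beta_hat: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if self.q3 < self.q1:
            raise ValueError("q3 must be >= q1")

    @property
    def effect(self) -> float:
        return float(np.exp(self.beta_hat * (self.q3 - self.q1)))


def quartiles(values: Sequence[float]) -> tuple[float, float]:
    """First and third quartiles by linear interpolation.

    Requires at least four values; invariant to input order.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need at least four values for quartiles")
    q1, q3 = np.percentile(x, [25.0, 75.0], method="linear")
    return float(q1), float(q3)


def q1q3_effect(beta_hat: float, q1: float, q3: float,
                predictor: str = "") -> EffectEstimate:
    """Effect of moving a predictor from Q1 to Q3: ``exp(beta*(q3-q1))``.

    A value of 1.5 means a 50% increase in the expected number of visits.
    """
    return EffectEstimate(predictor=predictor, beta_hat=float(beta_hat),
                          q1=float(q1), q3=float(q3))


def _vif_frame(
    covars: CovariateTable | pd.DataFrame,
    predictors: Sequence[str] | None,
    include_year: bool,
) -> tuple[pd.DataFrame, list[str]]:
    if isinstance(covars, CovariateTable):
        df = covars.long_frame()
    else:
        df = covars.copy()
        if include_year and "Year" not in df.columns and "year" in df.columns:
            df = df.rename(columns={"year": "Year"})
    if predictors is None:
        predictors = [c for c in df.columns if c not in ("tract_id",)]
        if not include_year:
            predictors = [c for c in predictors if c != "Year"]
        elif "Year" in df.columns and "Year" not in predictors:
            predictors.append("Year")
    else:
        predictors = list(predictors)
    if include_year and "Year" not in predictors and "Year" in df.columns:
        predictors = ["Year", *predictors]
    return df, predictors


def vif(
    covars: CovariateTable | pd.DataFrame,
    predictors: Sequence[str] | None = None,
    include_year: bool = True,
) -> pd.DataFrame:
    """Variance inflation factors over pooled tract-year rows.

    ``VIF_j = 1 / (1 - R^2_j)`` where ``R^2_j`` comes from an OLS regression
    (with intercept) of predictor ``j`` on all the others.  Calendar year
    enters as a single numeric ``Year`` term, the screening convention for
    yearly-stepping covariates.  Perfectly collinear predictors are reported
    as infinite with ``flag = "infinite"``; bands follow the usual rule of
    thumb (5-10 moderate, >= 10 strong).
    """
    df, predictors = _vif_frame(covars, predictors, include_year)
    if len(predictors) < 2:
        raise ValueError("VIF needs at least two predictors")
    X = df[predictors].to_numpy(dtype=float)
    nrows = X.shape[0]
    rows = []
    for j, name in enumerate(predictors):
        y = X[:, j]
        if np.allclose(y, y[0]):
            raise ValueError(f"predictor {name!r} is constant")
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(nrows), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / ss_tot
        if r2 >= VIF_INFINITE_R2:
            value, flag = np.inf, "infinite"
        else:
            value = 1.0 / (1.0 - r2)
            flag = ("strong" if value >= 10 else
                    "moderate" if value >= 5 else "low")
        rows.append({"predictor": name, "vif": value, "flag": flag})
    return pd.DataFrame(rows)


def effects_table(
    slopes: Mapping[str, float], covars: CovariateTable,
) -> pd.DataFrame:
    """Q1-to-Q3 effect table for fitted slopes over the covariate rows.

    Quartiles are taken over pooled tract-year values of each predictor.
    """
    rows = []
    for name, beta_hat in slopes.items():
        if name not in covars.covariate_names:
            raise ValueError(f"unknown covariate {name!r}")
        q1, q3 = quartiles(covars.values[name].to_numpy())
        est = q1q3_effect(beta_hat, q1, q3, predictor=name)
        rows.append(
            {"predictor": name, "slope": beta_hat, "q1": q1, "q3": q3,
             "effect_q1_to_q3": est.effect}
        )
    return pd.DataFrame(rows)


# shipped alternative priors for the sensitivity grid (overridable)
ALTERNATIVE_PRIORS = {
    "intercept": {"intercept_mean": 0.0, "intercept_precision": 0.001},
    "slope": {"slope_precision": 0.1},
    "precision": {"tau_shape": 0.5, "tau_rate": 0.0005},
}


def prior_sensitivity(
    spec: ModelSpec,
    panel: CountPanel,
    covars: CovariateTable | None,
    lattice: TractLattice | None,
    config: SamplerConfig = SamplerConfig(),
    alternatives: Mapping[str, Mapping[str, float]] | None = None,
) -> pd.DataFrame:
    """Fit the model under all 2^3 = 8 prior combinations.

    Each of the three prior blocks (intercept, slopes, precisions) switches
    between the spec's default and an alternative.  Returns one row per
    combination with every fixed-effect posterior mean and interval, plus
    ``max_abs_dev``: the largest absolute deviation of that combination's
    fixed-effect means from the all-default row.  Small deviations (relative
    to the posterior sd) indicate prior robustness.
    """
    alts = dict(ALTERNATIVE_PRIORS)
    if alternatives:
        unknown = set(alternatives) - {"intercept", "slope", "precision"}
        if unknown:
            raise ValueError(f"unknown prior blocks {sorted(unknown)}")
        alts.update({k: dict(v) for k, v in alternatives.items()})
    base = spec.priors
    rows = []
    fixed_cols: list[str] | None = None
    default_means: np.ndarray | None = None
    for use_alt in itertools.product((False, True), repeat=3):
        pri = base
        for flag, block in zip(use_alt, ("intercept", "slope", "precision")):
            if flag:
                pri = replace(pri, **alts[block])
        res = fit(spec.with_priors(pri), panel, covars, lattice, config)
        tab = res.summary.params
        if fixed_cols is None:
            # fixed effects = everything before the hyperparameters
            fixed_cols = [c for c in tab.index
                          if not c.startswith("tau_") and c != "nb_dispersion"]
        means = tab.loc[fixed_cols, "mean"].to_numpy()
        if default_means is None:
            default_means = means
        row: dict = {
            "intercept_prior": "alt" if use_alt[0] else "default",
            "slope_prior": "alt" if use_alt[1] else "default",
            "precision_prior": "alt" if use_alt[2] else "default",
        }
        for c in fixed_cols:
            row[f"{c}_mean"] = float(tab.loc[c, "mean"])
            row[f"{c}_q2.5"] = float(tab.loc[c, "q2.5"])
            row[f"{c}_q97.5"] = float(tab.loc[c, "q97.5"])
        row["max_abs_dev"] = float(np.abs(means - default_means).max())
        rows.append(row)
    return pd.DataFrame(rows)
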