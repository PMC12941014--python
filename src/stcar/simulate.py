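"""Synthetic data with the exact generative structure of Models 1-5.

Everything needed for parameter-recovery and calibration experiments when
the real discharge data are confidential: grid lattices, intrinsic-CAR
spatial fields, first-order random walks, yearly-stepping covariates,
log-uniform tract populations, and Poisson / negative-binomial count panels
whose latent parameters (:class:`SimulationTruth`) are known.

Defaults emulate the study conditions: ~100 contiguous tracts, four years
(2018-2021, 48 months), five ACS-style covariates on their natural scales,
and populations of a few hundred to a few thousand women per tract.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lattice import TractLattice, make_grid_lattice
from .models import Design, Likelihood, ModelSpec, Temporal, build_design
from .panel import CountPanel, CovariateTable, month_labels, year_labels

__all__ = [
    "SimulationTruth",
    "make_grid_lattice",
    "sample_icar",
    "sample_rw1",
    "simulate_covariates",
    "simulate_populations",
    "make_truth",
    "simulate_panel",
    "DEFAULT_COVARIATES",
]

# name, mean level, spatial sd, i.i.d. sd, is-percentage
DEFAULT_COVARIATES = (
    ("pct_private_insurance", 55.0, 12.0, 3.0, True),
    ("pct_public_insurance", 30.0, 10.0, 3.0, True),
    ("median_age", 36.0, 4.0, 1.5, False),
    ("median_income", 45.0, 12.0, 4.0, False),  # thousands of dollars
    ("pct_hs_diploma", 85.0, 6.0, 2.0, True),
)


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_icar(
    lattice: TractLattice,
    tau_s: float,
    seed: int | np.random.Generator,
    per_component_centering: bool = False,
) -> np.ndarray:
    """Draw from the intrinsic CAR distribution on the lattice.

    The ICAR field has (improper) precision ``tau_s * (D - W)``; the draw is
    taken exactly in the rank-(n-1) eigenspace of the graph Laplacian that
    is orthogonal to the constant vector, which enforces the sum-to-zero
    constraint.  Disconnected lattices are rejected unless
    ``per_component_centering`` is set, in which case each component's field
    sums to zero separately.
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be positive")
    if lattice.n < 2:
        raise ValueError("ICAR requires at least two units")
    ncomp = lattice.n_components()
    if ncomp > 1 and not per_component_centering:
        raise ValueError(
            f"lattice has {ncomp} components; pass per_component_centering=True"
        )
    rng = _rng(seed)
    Q = lattice.laplacian()
    evals, evecs = np.linalg.eigh(Q)
    keep = evals > 1e-9 * max(evals.max(), 1.0)
    lam = evals[keep]
    V = evecs[:, keep]
    z = rng.standard_normal(lam.size) / np.sqrt(tau_s * lam)
    return V @ z


def sample_rw1(
    T: int,
    tau_gamma: float,
    seed: int | np.random.Generator,
    gamma0: float = 0.0,
) -> np.ndarray:
    """First-order random walk: ``gamma_t ~ N(gamma_{t-1}, 1/tau_gamma)``.

    Returns ``gamma_1 .. gamma_T`` started from ``gamma0`` (the starting
    value itself is not returned).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if tau_gamma <= 0:
        raise ValueError("tau_gamma must be positive")
    rng = _rng(seed)
    steps = rng.standard_normal(T) / np.sqrt(tau_gamma)
    return gamma0 + np.cumsum(steps)


def simulate_covariates(
    lattice: TractLattice,
    years: Sequence[int],
    spatial_smoothness: float = 2.0,
    seed: int | np.random.Generator = 0,
    year_step_sd: float = 1.0,
    specs: Sequence[tuple[str, float, float, float, bool]] = DEFAULT_COVARIATES,
) -> CovariateTable:
    """Simulate tract-level covariates that step at calendar years.

    Each covariate's first-year surface is its mean level plus a smooth
    ICAR component (precision ``spatial_smoothness``, scaled to the stated
    spatial sd) plus i.i.d. tract noise; subsequent years add small
    ``N(0, year_step_sd^2)`` perturbations, emulating ACS estimates whose
    year-to-year change is usually small.  Percentages are clipped to
    [0, 100].
    """
    if not years:
        raise ValueError("years must be non-empty")
    rng = _rng(seed)
    years = sorted(years)
    n = lattice.n
    frames = {}
    for name, level, sp_sd, iid_sd, is_pct in specs:
        if n >= 2:
            raw = sample_icar(lattice, spatial_smoothness, rng,
                              per_component_centering=True)
            sd = raw.std()
            spatial = sp_sd * raw / sd if sd > 0 else np.zeros(n)
        else:
            spatial = np.zeros(n)
        base = level + spatial + iid_sd * rng.standard_normal(n)
        vals = np.empty((n, len(years)))
        vals[:, 0] = base
        for j in range(1, len(years)):
            vals[:, j] = vals[:, j - 1] + year_step_sd * rng.standard_normal(n)
        if is_pct:
            vals = np.clip(vals, 0.0, 100.0)
        frames[name] = vals
    idx = pd.MultiIndex.from_product(
        [list(lattice.tract_ids), years], names=["tract_id", "year"]
    )
    data = {
        name: vals.reshape(-1) for name, vals in frames.items()
    }
    return CovariateTable(values=pd.DataFrame(data, index=idx))


def simulate_populations(
    lattice: TractLattice,
    seed: int | np.random.Generator = 0,
    low: int = 200,
    high: int = 3000,
) -> np.ndarray:
    """Log-uniform tract populations at risk, mimicking counts of women
    aged 15-49 per census tract."""
    rng = _rng(seed)
    u = rng.uniform(np.log(low), np.log(high), size=lattice.n)
    return np.exp(u).round().astype(np.int64)


@dataclass(frozen=True)
class SimulationTruth:
    """Known latent parameters behind a simulated panel.

    Fields not used by the selected model are ``None``.  ``s`` sums to zero
    (ICAR constraint); all precisions are positive.
    """

    beta0: float
    beta: tuple[float, ...] = ()
    alpha_year: tuple[float, ...] | None = None  # one per non-reference year
    alpha_covid: float | None = None
    s: np.ndarray | None = None
    v: np.ndarray | None = None
    gamma: np.ndarray | None = None
    phi: np.ndarray | None = None
    delta: np.ndarray | None = None
    tau_s: float | None = None
    tau_v: float | None = None
    tau_gamma: float | None = None
    tau_phi: float | None = None
    tau_delta: float | None = None
    nb_dispersion: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("tau_s", "tau_v", "tau_gamma", "tau_phi", "tau_delta"):
            val = getattr(self, name)
            if val is not None and val <= 0:
                raise ValueError(f"{name} must be positive")
        if self.s is not None and abs(np.sum(self.s)) > 1e-6 * max(
            1.0, float(np.abs(self.s).max())
        ):
            raise ValueError("spatial field s must sum to zero")

    def to_json(self, path) -> None:
        def enc(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            return x

        payload = {k: enc(v) for k, v in dataclasses.asdict(self).items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            payload = json.load(fh)
        arrays = {"s", "v", "gamma", "phi", "delta"}
        kwargs = {}
        for k, v in payload.items():
            if v is None:
                kwargs[k] = None
            elif k in arrays:
                kwargs[k] = np.asarray(v, dtype=float)
            elif k in ("beta", "alpha_year"):
                kwargs[k] = tuple(v)
            else:
                kwargs[k] = v
        return cls(**kwargs)


# default hyperparameters for the generator (chosen once; see docs/methods.md)
_DEFAULT_TAUS = dict(tau_s=10.0, tau_v=25.0, tau_gamma=100.0,
                     tau_phi=400.0, tau_delta=100.0)
# yearly effects echoing the observed pattern: small rise in 2019, pandemic drop
_DEFAULT_ALPHA_YEAR = (0.07, -0.18, -0.28)
_DEFAULT_ALPHA_COVID = -0.26
_DEFAULT_BETA = {
    "pct_private_insurance": 0.0006,
    "pct_public_insurance": 0.0117,
    "median_age": 0.0134,
    "median_income": -0.0046,
    "pct_hs_diploma": 0.0073,
}


def make_truth(
    spec: ModelSpec,
    lattice: TractLattice,
    T: int,
    seed: int | np.random.Generator,
    beta0: float = -4.0,
    beta: Sequence[float] | None = None,
    alpha_year: Sequence[float] | None = None,
    alpha_covid: float | None = None,
    taus: Mapping[str, float] | None = None,
    nb_dispersion: float | None = None,
) -> SimulationTruth:
    """Draw a full set of latent effects for ``spec`` with known parameters.

    Fixed effects default to values of realistic magnitude for ED visit
    rates (baseline rate ``e^beta0`` per person-period with ``beta0 = -4``);
    random effects are drawn from their own priors at the default precisions.
    """
    rng = _rng(seed)
    tau = dict(_DEFAULT_TAUS)
    if taus:
        tau.update(taus)
    if beta is None:
        beta = tuple(_DEFAULT_BETA.get(c, 0.01) for c in spec.covariate_names)
    beta = tuple(float(b) for b in beta)
    if len(beta) != len(spec.covariate_names):
        raise ValueError("beta length must match spec.covariate_names")

    kwargs: dict = dict(beta0=float(beta0), beta=beta)
    if spec.spatial_effects:
        kwargs["s"] = sample_icar(lattice, tau["tau_s"], rng)
        kwargs["v"] = rng.standard_normal(lattice.n) / np.sqrt(tau["tau_v"])
        kwargs["tau_s"], kwargs["tau_v"] = tau["tau_s"], tau["tau_v"]
    t = spec.temporal
    if t is Temporal.YEAR_INDICATORS:
        kwargs["alpha_year"] = (
            tuple(alpha_year) if alpha_year is not None else
            _DEFAULT_ALPHA_YEAR[: T - 1]
        )
    elif t is Temporal.COVID_INDICATOR:
        kwargs["alpha_covid"] = (
            float(alpha_covid) if alpha_covid is not None else _DEFAULT_ALPHA_COVID
        )
    elif spec.has_rw:
        kwargs["gamma"] = sample_rw1(T, tau["tau_gamma"], rng)
        kwargs["phi"] = rng.standard_normal(T) / np.sqrt(tau["tau_phi"])
        kwargs["tau_gamma"], kwargs["tau_phi"] = tau["tau_gamma"], tau["tau_phi"]
        if spec.has_interaction:
            kwargs["delta"] = rng.standard_normal(
                (lattice.n, T)
            ) / np.sqrt(tau["tau_delta"])
            kwargs["tau_delta"] = tau["tau_delta"]
    if spec.likelihood is Likelihood.NEGBIN:
        kwargs["nb_dispersion"] = (
            float(nb_dispersion) if nb_dispersion is not None else 10.0
        )
    return SimulationTruth(**kwargs)


def _truth_eta(
    spec: ModelSpec, truth: SimulationTruth, design: Design, n: int, T: int
) -> np.ndarray:
    """Assemble ``log lambda`` from a truth object on a built design."""
    coefs = [truth.beta0, *truth.beta]
    t = spec.temporal
    if t is Temporal.YEAR_INDICATORS:
        if truth.alpha_year is None:
            raise ValueError("model needs alpha_year (year-indicator effects)")
        coefs.extend(truth.alpha_year)
    elif t is Temporal.COVID_INDICATOR:
        if truth.alpha_covid is None:
            raise ValueError("model needs alpha_covid (pandemic indicator effect)")
        coefs.append(truth.alpha_covid)
    if len(coefs) != design.p:
        raise ValueError(
            f"truth provides {len(coefs)} fixed effects, design needs {design.p}"
        )
    eta = design.linear_predictor(np.array(coefs))
    if spec.spatial_effects:
        if truth.s is None or truth.v is None:
            raise ValueError("model needs spatial fields s and v")
        eta = eta + truth.s[:, None] + truth.v[:, None]
    if spec.has_rw:
        if truth.gamma is None or truth.phi is None:
            raise ValueError("model needs temporal fields gamma and phi")
        if len(truth.gamma) != T or len(truth.phi) != T:
            raise ValueError("gamma/phi length must equal T")
        eta = eta + truth.gamma[None, :] + truth.phi[None, :]
    if spec.has_interaction:
        if truth.delta is None:
            raise ValueError("model needs the interaction field delta")
        if truth.delta.shape != (n, T):
            raise ValueError("delta must have shape (n, T)")
        eta = eta + truth.delta
    return eta


def simulate_panel(
    spec: ModelSpec,
    truth: SimulationTruth,
    lattice: TractLattice,
    covars: CovariateTable | None,
    populations: Sequence[int] | np.ndarray,
    seed: int | np.random.Generator,
    years: Sequence[int] = (2018, 2019, 2020, 2021),
) -> CountPanel:
    """Draw a count panel ``Y_it ~ Poisson(P_i * lambda_it)`` (or NB).

    ``log lambda_it`` follows the selected model's equation exactly, using
    the latent fields in ``truth``.  Deterministic given the seed.
    """
    rng = _rng(seed)
    yearly = spec.temporal in (
        Temporal.YEAR_INDICATORS, Temporal.COVID_INDICATOR,
        Temporal.RW1_YEAR, Temporal.NONE,
    )
    labels = year_labels(years) if yearly else month_labels(years)
    n, T = lattice.n, len(labels)
    P = np.asarray(populations, dtype=np.int64)
    if P.shape != (n,) or (P <= 0).any():
        raise ValueError("populations must be positive, one per tract")
    shell = CountPanel(
        Y=np.zeros((n, T), dtype=np.int64), P=P,
        tract_ids=lattice.tract_ids, period_labels=tuple(labels),
        granularity="year" if yearly else "month",
    )
    design = build_design(spec, shell, covars)
    eta = _truth_eta(spec, truth, design, n, T)
    mu = P[:, None] * np.exp(eta)
    if spec.likelihood is Likelihood.NEGBIN:
        theta = truth.nb_dispersion
        if theta is None:
            raise ValueError("negative-binomial model needs nb_dispersion")
        Y = rng.negative_binomial(theta, theta / (theta + mu))
    else:
        Y = rng.poisson(mu)
    return CountPanel(
        Y=Y, P=P, tract_ids=lattice.tract_ids, period_labels=tuple(labels),
        granularity=shell.granularity,
    )


def expected_panel_mean(
    spec: ModelSpec,
    truth: SimulationTruth,
    lattice: TractLattice,
    covars: CovariateTable | None,
    populations: Sequence[int] | np.ndarray,
    years: Sequence[int] = (2018, 2019, 2020, 2021),
) -> np.ndarray:
    """Cell means ``P_i * lambda_it`` implied by a truth object (no noise)."""
    yearly = spec.temporal in (
        Temporal.YEAR_INDICATORS, Temporal.COVID_INDICATOR,
        Temporal.RW1_YEAR, Temporal.NONE,
    )
    labels = year_labels(years) if yearly else month_labels(years)
    n, T = lattice.n, len(labels)
    P = np.asarray(populations, dtype=np.int64)
    shell = CountPanel(
        Y=np.zeros((n, T), dtype=np.int64), P=P,
        tract_ids=lattice.tract_ids, period_labels=tuple(labels),
        granularity="year" if yearly else "month",
    )
    design = build_design(spec, shell, covars)
    return P[:, None] * np.exp(_truth_eta(spec, truth, design, n, T))
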