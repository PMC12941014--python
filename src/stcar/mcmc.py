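"""Metropolis-within-Gibbs sampler for the hierarchical count models.

The posterior is explored with vectorized single-site random-walk Metropolis
updates for all latent Gaussian fields and conjugate Gibbs draws for the
precision hyperparameters:

* fixed effects: coordinate-wise adaptive Metropolis on an internally
  centered design (covariate fields are mean-centered, which removes the
  dominant intercept/slope posterior correlation; the intercept is mapped
  back to the original scale on output);
* ICAR field ``s``: the lattice is greedily colored; all sites of one color
  are conditionally independent given the rest and are updated
  simultaneously; after each sweep the field is recentered to sum to zero
  with the shift absorbed into the intercept, which leaves the likelihood
  and the intrinsic prior invariant;
* i.i.d. fields ``v``, ``phi``, ``delta``: fully parallel single-site
  updates (their full conditionals are mutually independent);
* RW1 field ``gamma``: even/odd coloring of the time chain, with the walk
  pinned at ``gamma_0 = 0``;
* precisions: conjugate gamma Gibbs draws;
* negative-binomial dispersion: Metropolis on its logarithm.

Proposal scales adapt toward a 0.44 single-site acceptance rate during
warmup (Robbins-Monro on the log scale) and are frozen afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln

from .lattice import TractLattice
from .models import Design, Likelihood, ModelSpec, build_design
from .panel import CountPanel, CovariateTable

__all__ = ["SamplerConfig", "ModelData", "ChainDraws", "prepare_model_data",
           "run_chain"]

_TARGET_ACC = 0.44
_ETA_CLIP = 60.0  # rates beyond e^60 are unreachable for real data; the clip
                  # keeps masked/unidentified directions from overflowing exp


def _exp_eta(eta: np.ndarray) -> np.ndarray:
    return np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC run settings: ``draws`` retained per chain after ``warmup``."""

    draws: int = 1000
    warmup: int = 1000
    chains: int = 2
    thin: int = 1
    seed: int = 0
    rhat_threshold: float = 1.05
    ess_threshold: float = 100.0

    def __post_init__(self) -> None:
        if self.draws < 1 or self.warmup < 0 or self.chains < 1 or self.thin < 1:
            raise ValueError("invalid sampler configuration")


@dataclass
class ModelData:
    """Preprocessed inputs for one model fit."""

    spec: ModelSpec
    design: Design
    Y: np.ndarray          # (n, T) float
    P: np.ndarray          # (n,) float
    obs: np.ndarray        # (n, T) float 0/1
    Fc: np.ndarray         # (p, n, T) centered fixed-effect fields
    cmeans: np.ndarray     # (p,) field means subtracted (cmeans[0] = 0)
    # spatial structure (present when spec.spatial_effects)
    W: np.ndarray | None = None
    m: np.ndarray | None = None
    colors: list[np.ndarray] = field(default_factory=list)
    n_components: int = 1

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def T(self) -> int:
        return self.Y.shape[1]

    @property
    def p(self) -> int:
        return self.Fc.shape[0]


def prepare_model_data(
    spec: ModelSpec,
    panel: CountPanel,
    covars: CovariateTable | None,
    lattice: TractLattice | None,
) -> ModelData:
    """Validate inputs and assemble the centered design and lattice structure."""
    design = build_design(spec, panel, covars)
    Y = panel.Y.astype(float)
    P = panel.P.astype(float)
    obs = panel.obs_mask().astype(float)
    F = design.F
    cmeans = np.zeros(F.shape[0])
    Fc = F.copy()
    for j in range(1, F.shape[0]):
        cmeans[j] = F[j].mean()
        Fc[j] = F[j] - cmeans[j]
    data = ModelData(spec=spec, design=design, Y=Y, P=P, obs=obs, Fc=Fc,
                     cmeans=cmeans)
    if spec.spatial_effects:
        if lattice is None:
            raise ValueError("spatial model requires a lattice")
        if lattice.n != panel.n:
            raise ValueError("lattice and panel disagree on n")
        if lattice.n < 2:
            raise ValueError("ICAR spatial effects need at least two tracts")
        data.W = lattice.adjacency_matrix()
        data.m = lattice.m.astype(float)
        data.colors = lattice.coloring()
        data.n_components = lattice.n_components()
    return data


@dataclass
class ChainDraws:
    """Raw output of one chain."""

    scalar_names: list[str]
    scalars: np.ndarray        # (draws, n_scalars)
    deviance: np.ndarray       # (draws,)
    lam_mean: np.ndarray       # (n, T) posterior mean of exp(eta)
    eta_mean: np.ndarray       # (n, T) posterior mean of eta
    s_mean: np.ndarray | None
    v_mean: np.ndarray | None
    gamma_mean: np.ndarray | None
    phi_mean: np.ndarray | None
    delta_mean: np.ndarray | None
    max_abs_s_sum: float       # largest |sum(s)| over retained draws


# -- likelihood kernels ----------------------------------------------------

def _ll_fast(data: ModelData, eta: np.ndarray, theta: float | None) -> np.ndarray:
    """Per-cell log-likelihood up to terms constant in eta (vector MH use)."""
    mu = data.P[:, None] * _exp_eta(eta)
    if data.spec.likelihood is Likelihood.POISSON:
        return data.obs * (data.Y * eta - mu)
    return data.obs * (data.Y * eta - (data.Y + theta) * np.log(theta + mu))


def full_loglik(data: ModelData, eta: np.ndarray, theta: float | None) -> float:
    """Exact observed-data log-likelihood (used for the deviance)."""
    mu = data.P[:, None] * _exp_eta(eta)
    Y = data.Y
    if data.spec.likelihood is Likelihood.POISSON:
        ll = Y * np.log(mu) - mu - gammaln(Y + 1)
        ll = np.where(Y > 0, ll, -mu)  # avoid log(mu)*0 edge cases at mu->0
    else:
        ll = (gammaln(Y + theta) - gammaln(theta) - gammaln(Y + 1)
              + theta * np.log(theta / (theta + mu))
              + Y * np.log(mu / (theta + mu)))
        ll = np.where(Y > 0, ll, theta * np.log(theta / (theta + mu)))
    return float((data.obs * ll).sum())


def deviance(data: ModelData, mu: np.ndarray, theta: float | None) -> float:
    """Unsaturated deviance -2 log L at the given cell means."""
    Y = data.Y
    if data.spec.likelihood is Likelihood.POISSON:
        ll = np.where(Y > 0, Y * np.log(mu) - mu - gammaln(Y + 1), -mu)
    else:
        base = theta * np.log(theta / (theta + mu))
        ll = np.where(
            Y > 0,
            gammaln(Y + theta) - gammaln(theta) - gammaln(Y + 1)
            + base + Y * np.log(mu / (theta + mu)),
            base,
        )
    return float(-2.0 * (data.obs * ll).sum())


# -- the sampler -----------------------------------------------------------

class _Adapt:
    """Per-site log-scale Robbins-Monro step-size adaptation."""

    def __init__(self, size: int, init: float = 0.5):
        self.logstep = np.full(size, np.log(init))
        self.t = 0

    def scales(self) -> np.ndarray:
        return np.exp(self.logstep)

    def update(self, accepted: np.ndarray) -> None:
        self.t += 1
        rate = 1.0 / (10.0 + self.t) ** 0.6
        self.logstep += rate * (np.asarray(accepted, dtype=float) - _TARGET_ACC)
        np.clip(self.logstep, np.log(1e-4), np.log(50.0), out=self.logstep)


def _implied_beta0(b: np.ndarray, cmeans: np.ndarray) -> float:
    return float(b[0] - b[1:] @ cmeans[1:])


def run_chain(
    data: ModelData, config: SamplerConfig, seed: int
) -> ChainDraws:
    """Run one MCMC chain; deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    spec, pri = data.spec, data.spec.priors
    n, T, p = data.n, data.T, data.p
    spatial = spec.spatial_effects
    has_rw, has_delta = spec.has_rw, spec.has_interaction
    negbin = spec.likelihood is Likelihood.NEGBIN

    # --- initial state
    tot_y = float((data.obs * data.Y).sum())
    tot_e = float((data.obs * data.P[:, None]).sum())
    b = np.zeros(p)
    b[0] = np.log(max(tot_y, 0.5) / max(tot_e, 1.0))
    s = np.zeros(n)
    v = 0.01 * rng.standard_normal(n) if spatial else np.zeros(n)
    if spatial:
        s = 0.01 * rng.standard_normal(n)
        s -= s.mean()
    gamma = np.zeros(T)
    phi = np.zeros(T)
    delta = np.zeros((n, T))
    tau = dict.fromkeys(("s", "v", "gamma", "phi", "delta"), 10.0)
    theta = 10.0 if negbin else None
    log_theta = np.log(theta) if negbin else None

    eta = np.tensordot(b, data.Fc, axes=1)
    if spatial:
        eta += (s + v)[:, None]
    # gamma/phi/delta start at zero

    a_fix = _Adapt(p, init=0.1)
    # joint adaptive-Metropolis state for the fixed effects (Haario-style):
    # empirical covariance of warmup draws drives a correlated proposal that
    # handles slope/intercept posterior correlation far better than
    # coordinate-wise moves alone
    b_hist: list[np.ndarray] = []
    joint_chol: np.ndarray | None = None
    joint_logscale = 0.0
    joint_t = 0
    a_ridge = _Adapt(p, init=0.3)
    a_loc = _Adapt(1, init=0.5)
    a_loc_rw = _Adapt(2, init=0.5)
    # centered per-tract pattern of each fixed-effect field (ridge moves)
    ridge_g: list[np.ndarray | None] = [None] * p
    ridge_field: list[np.ndarray | None] = [None] * p
    if spatial:
        for j in range(1, p):
            g = data.Fc[j].mean(axis=1)
            if np.abs(g).max() > 1e-10:
                ridge_g[j] = g
                ridge_field[j] = data.Fc[j] - g[:, None]
    a_v = _Adapt(n, init=0.5)
    a_s = _Adapt(n, init=0.5)
    a_g = _Adapt(T, init=0.3)
    a_ph = _Adapt(T, init=0.3)
    a_d = _Adapt(n * T, init=0.5)
    a_th = _Adapt(1, init=0.3)

    a_tau, b_tau = pri.tau_shape, pri.tau_rate

    def intercept_logprior(beta0: float) -> float:
        if pri.intercept_precision <= 0:
            return 0.0
        return -0.5 * pri.intercept_precision * (beta0 - pri.intercept_mean) ** 2

    n_iter = config.warmup + config.draws * config.thin
    n_keep = config.draws
    scalar_names = ["beta0"] + list(data.design.fixed_names[1:])
    if spatial:
        scalar_names += ["tau_s", "tau_v"]
    if has_rw:
        scalar_names += ["tau_gamma", "tau_phi"]
    if has_delta:
        scalar_names += ["tau_delta"]
    if negbin:
        scalar_names += ["nb_dispersion"]
    scalars = np.empty((n_keep, len(scalar_names)))
    dev = np.empty(n_keep)
    lam_sum = np.zeros((n, T))
    eta_sum = np.zeros((n, T))
    s_sum = np.zeros(n) if spatial else None
    v_sum = np.zeros(n) if spatial else None
    g_sum = np.zeros(T) if has_rw else None
    ph_sum = np.zeros(T) if has_rw else None
    d_sum = np.zeros((n, T)) if has_delta else None
    max_s_sum = 0.0
    kept = 0

    ll_cells = _ll_fast(data, eta, theta)

    for it in range(n_iter):
        warm = it < config.warmup

        # ---- fixed effects (coordinate-wise)
        steps = a_fix.scales()
        acc_fix = np.zeros(p)
        for j in range(p):
            d = steps[j] * rng.standard_normal()
            eta_new = eta + d * data.Fc[j]
            ll_new = _ll_fast(data, eta_new, theta)
            dlp = float(ll_new.sum() - ll_cells.sum())
            if j == 0:
                dlp += (intercept_logprior(_implied_beta0(b, data.cmeans) + d)
                        - intercept_logprior(_implied_beta0(b, data.cmeans)))
            else:
                dlp += -0.5 * pri.slope_precision * (
                    (b[j] + d) ** 2 - b[j] ** 2
                )
                db0 = -data.cmeans[j] * d
                dlp += (intercept_logprior(_implied_beta0(b, data.cmeans) + db0)
                        - intercept_logprior(_implied_beta0(b, data.cmeans)))
            if np.log(rng.uniform()) < dlp:
                b[j] += d
                eta = eta_new
                ll_cells = ll_new
                acc_fix[j] = 1.0
        if warm:
            a_fix.update(acc_fix)
            b_hist.append(b.copy())
            # refresh the joint proposal from the warmup history periodically
            if it >= max(50, config.warmup // 4) and it % 25 == 0 and len(b_hist) > 2 * p + 10:
                H = np.asarray(b_hist[len(b_hist) // 2:])
                cov = np.cov(H.T).reshape(p, p) + 1e-12 * np.eye(p)
                try:
                    joint_chol = np.linalg.cholesky((2.38**2 / p) * cov)
                except np.linalg.LinAlgError:
                    joint_chol = None

        # ---- joint fixed-effect update (correlated proposal)
        if joint_chol is not None:
            for _ in range(2):
                d = np.exp(joint_logscale) * (joint_chol @ rng.standard_normal(p))
                eta_new = eta + np.tensordot(d, data.Fc, axes=1)
                ll_new = _ll_fast(data, eta_new, theta)
                dlp = float(ll_new.sum() - ll_cells.sum())
                dlp += -0.5 * pri.slope_precision * float(
                    ((b[1:] + d[1:]) ** 2 - b[1:] ** 2).sum()
                )
                b0_old = _implied_beta0(b, data.cmeans)
                b0_new = _implied_beta0(b + d, data.cmeans)
                dlp += intercept_logprior(b0_new) - intercept_logprior(b0_old)
                acc_j = np.log(rng.uniform()) < dlp
                if acc_j:
                    b += d
                    eta = eta_new
                    ll_cells = ll_new
                if warm:
                    joint_t += 1
                    joint_logscale += (float(acc_j) - 0.23) / (10.0 + joint_t) ** 0.6
                    joint_logscale = float(np.clip(joint_logscale, -5.0, 3.0))

        # ---- ridge moves: slope +d with compensating spatial-field shift
        # (travels along the slope/ICAR-field posterior ridge created by
        # spatially smooth covariates; eta barely changes, the ICAR prior
        # governs acceptance)
        if spatial:
            steps_r = a_ridge.scales()
            acc_r = np.zeros(p)
            for j in range(1, p):
                g = ridge_g[j]
                if g is None:
                    continue
                d = steps_r[j] * rng.standard_normal()
                eta_new = eta + d * ridge_field[j]
                ll_new = _ll_fast(data, eta_new, theta)
                dlp = float(ll_new.sum() - ll_cells.sum())
                dlp += -0.5 * pri.slope_precision * ((b[j] + d) ** 2 - b[j] ** 2)
                Qg = data.m * g - data.W @ g
                dlp += -0.5 * tau["s"] * (
                    -2.0 * d * float(Qg @ s) + d * d * float(Qg @ g)
                )
                db0 = -data.cmeans[j] * d
                dlp += (intercept_logprior(_implied_beta0(b, data.cmeans) + db0)
                        - intercept_logprior(_implied_beta0(b, data.cmeans)))
                if np.log(rng.uniform()) < dlp:
                    b[j] += d
                    s -= d * g
                    eta = eta_new
                    ll_cells = ll_new
                    acc_r[j] = 1.0
            if warm:
                a_ridge.update(acc_r)

            # intercept <-> mean(v) location swap (likelihood-invariant)
            d = float(a_loc.scales()[0]) * rng.standard_normal()
            dlp = -0.5 * tau["v"] * float(((v - d) ** 2 - v**2).sum())
            b0_old = _implied_beta0(b, data.cmeans)
            dlp += intercept_logprior(b0_old + d) - intercept_logprior(b0_old)
            acc0 = np.log(rng.uniform()) < dlp
            if acc0:
                b[0] += d
                v -= d
            if warm:
                a_loc.update(np.array([acc0]))

        if has_rw:
            # intercept <-> level(gamma) and intercept <-> mean(phi) swaps
            d = float(a_loc_rw.scales()[0]) * rng.standard_normal()
            dlp = -0.5 * tau["gamma"] * ((gamma[0] - d) ** 2 - gamma[0] ** 2)
            b0_old = _implied_beta0(b, data.cmeans)
            dlp += intercept_logprior(b0_old + d) - intercept_logprior(b0_old)
            acc1 = np.log(rng.uniform()) < dlp
            if acc1:
                b[0] += d
                gamma -= d
            d = float(a_loc_rw.scales()[1]) * rng.standard_normal()
            dlp = -0.5 * tau["phi"] * float(((phi - d) ** 2 - phi**2).sum())
            b0_old = _implied_beta0(b, data.cmeans)
            dlp += intercept_logprior(b0_old + d) - intercept_logprior(b0_old)
            acc2 = np.log(rng.uniform()) < dlp
            if acc2:
                b[0] += d
                phi -= d
            if warm:
                a_loc_rw.update(np.array([acc1, acc2]))

        # ---- i.i.d. tract effects v (all sites in parallel)
        if spatial:
            dv = a_v.scales() * rng.standard_normal(n)
            eta_new = eta + dv[:, None]
            ll_new = _ll_fast(data, eta_new, theta)
            row_dll = (ll_new - ll_cells).sum(axis=1)
            dlp = row_dll - 0.5 * tau["v"] * ((v + dv) ** 2 - v**2)
            acc = np.log(rng.uniform(size=n)) < dlp
            v[acc] += dv[acc]
            eta[acc] = eta_new[acc]
            ll_cells[acc] = ll_new[acc]
            if warm:
                a_v.update(acc)

            # ---- ICAR field s (color classes in parallel)
            steps_s = a_s.scales()
            acc_s = np.zeros(n)
            for cls in data.colors:
                nbr_sum = data.W[cls] @ s
                ds = steps_s[cls] * rng.standard_normal(cls.size)
                eta_new_rows = eta[cls] + ds[:, None]
                # per-row likelihood delta
                mu_old = data.P[cls, None] * _exp_eta(eta[cls])
                if negbin:
                    dll = (data.obs[cls] * (
                        data.Y[cls] * ds[:, None]
                        - (data.Y[cls] + theta) * (
                            np.log(theta + data.P[cls, None] * _exp_eta(eta_new_rows))
                            - np.log(theta + mu_old))
                    )).sum(axis=1)
                else:
                    dll = (data.obs[cls] * (
                        data.Y[cls] * ds[:, None]
                        - mu_old * (np.exp(ds)[:, None] - 1.0)
                    )).sum(axis=1)
                s_old = s[cls]
                s_new = s_old + ds
                dpr = -0.5 * tau["s"] * (
                    data.m[cls] * (s_new**2 - s_old**2)
                    - 2.0 * nbr_sum * (s_new - s_old)
                )
                acc = np.log(rng.uniform(size=cls.size)) < dll + dpr
                idx = cls[acc]
                s[idx] += ds[acc]
                eta[idx] += ds[acc, None]
                acc_s[cls] = acc
            # recenter: shift absorbed by the intercept, eta unchanged
            c = s.mean()
            if c != 0.0:
                s -= c
                b[0] += c
            ll_cells = _ll_fast(data, eta, theta)
            if warm:
                a_s.update(acc_s)

        # ---- RW1 gamma (even/odd time coloring), pinned at gamma_0 = 0
        if has_rw:
            steps_g = a_g.scales()
            acc_g = np.zeros(T)
            for par in (0, 1):
                ts = np.arange(par, T, 2)
                dg = steps_g[ts] * rng.standard_normal(ts.size)
                eta_new_cols = eta[:, ts] + dg[None, :]
                ll_new_cols = _ll_col(data, eta_new_cols, ts, theta)
                dll = (ll_new_cols - ll_cells[:, ts]).sum(axis=0)
                g_old = gamma[ts]
                g_new = g_old + dg
                left = np.where(ts > 0, gamma[np.maximum(ts - 1, 0)], 0.0)
                dpr = -0.5 * tau["gamma"] * (
                    (g_new - left) ** 2 - (g_old - left) ** 2
                )
                has_right = ts < T - 1
                right = gamma[np.minimum(ts + 1, T - 1)]
                dpr -= np.where(
                    has_right,
                    0.5 * tau["gamma"] * ((right - g_new) ** 2 - (right - g_old) ** 2),
                    0.0,
                )
                acc = np.log(rng.uniform(size=ts.size)) < dll + dpr
                cols = ts[acc]
                gamma[cols] += dg[acc]
                eta[:, cols] += dg[acc][None, :]
                ll_cells[:, cols] = ll_new_cols[:, acc]
                acc_g[ts] = acc
            if warm:
                a_g.update(acc_g)

            # ---- i.i.d. time effects phi (all columns in parallel)
            dphi = a_ph.scales() * rng.standard_normal(T)
            eta_new = eta + dphi[None, :]
            ll_new = _ll_fast(data, eta_new, theta)
            col_dll = (ll_new - ll_cells).sum(axis=0)
            dlp = col_dll - 0.5 * tau["phi"] * ((phi + dphi) ** 2 - phi**2)
            acc = np.log(rng.uniform(size=T)) < dlp
            phi[acc] += dphi[acc]
            eta[:, acc] = eta_new[:, acc]
            ll_cells[:, acc] = ll_new[:, acc]
            if warm:
                a_ph.update(acc)

        # ---- space-time interaction delta (all cells in parallel)
        if has_delta:
            dd = a_d.scales().reshape(n, T) * rng.standard_normal((n, T))
            eta_new = eta + dd
            ll_new = _ll_fast(data, eta_new, theta)
            dlp = (ll_new - ll_cells) - 0.5 * tau["delta"] * (
                (delta + dd) ** 2 - delta**2
            )
            acc = np.log(rng.uniform(size=(n, T))) < dlp
            delta[acc] += dd[acc]
            eta[acc] = eta_new[acc]
            ll_cells[acc] = ll_new[acc]
            if warm:
                a_d.update(acc.reshape(-1))

        # ---- conjugate gamma Gibbs for the precisions
        if spatial:
            quad = float(s @ (data.m * s) - s @ (data.W @ s))  # s' (D - W) s
            rank = n - data.n_components
            tau["s"] = rng.gamma(a_tau + 0.5 * rank, 1.0 / (b_tau + 0.5 * quad))
            tau["v"] = rng.gamma(a_tau + 0.5 * n, 1.0 / (b_tau + 0.5 * float(v @ v)))
        if has_rw:
            inc = np.diff(np.concatenate(([0.0], gamma)))
            tau["gamma"] = rng.gamma(
                a_tau + 0.5 * T, 1.0 / (b_tau + 0.5 * float(inc @ inc))
            )
            tau["phi"] = rng.gamma(
                a_tau + 0.5 * T, 1.0 / (b_tau + 0.5 * float(phi @ phi))
            )
        if has_delta:
            tau["delta"] = rng.gamma(
                a_tau + 0.5 * n * T,
                1.0 / (b_tau + 0.5 * float((delta**2).sum())),
            )

        # ---- negative-binomial dispersion (Metropolis on log theta)
        if negbin:
            step = float(a_th.scales()[0])
            lt_new = log_theta + step * rng.standard_normal()
            th_new = float(np.exp(lt_new))
            cur = full_loglik(data, eta, theta)
            prop = full_loglik(data, eta, th_new)
            dlp = (prop - cur) - 0.5 * pri.nb_logdisp_precision * (
                (lt_new - pri.nb_logdisp_mean) ** 2
                - (log_theta - pri.nb_logdisp_mean) ** 2
            )
            acc_t = np.log(rng.uniform()) < dlp
            if acc_t:
                log_theta, theta = lt_new, th_new
                ll_cells = _ll_fast(data, eta, theta)
            if warm:
                a_th.update(np.array([acc_t]))

        # ---- store
        if not warm and (it - config.warmup) % config.thin == 0:
            row = [_implied_beta0(b, data.cmeans)] + [float(x) for x in b[1:]]
            if spatial:
                row += [tau["s"], tau["v"]]
            if has_rw:
                row += [tau["gamma"], tau["phi"]]
            if has_delta:
                row += [tau["delta"]]
            if negbin:
                row += [theta]
            scalars[kept] = row
            dev[kept] = -2.0 * full_loglik(data, eta, theta)
            lam_sum += _exp_eta(eta)
            eta_sum += eta
            if spatial:
                s_sum += s
                v_sum += v
                max_s_sum = max(max_s_sum, abs(float(s.sum())))
            if has_rw:
                g_sum += gamma
                ph_sum += phi
            if has_delta:
                d_sum += delta
            kept += 1

    inv = 1.0 / kept
    return ChainDraws(
        scalar_names=scalar_names,
        scalars=scalars,
        deviance=dev,
        lam_mean=lam_sum * inv,
        eta_mean=eta_sum * inv,
        s_mean=None if s_sum is None else s_sum * inv,
        v_mean=None if v_sum is None else v_sum * inv,
        gamma_mean=None if g_sum is None else g_sum * inv,
        phi_mean=None if ph_sum is None else ph_sum * inv,
        delta_mean=None if d_sum is None else d_sum * inv,
        max_abs_s_sum=max_s_sum,
    )


def _ll_col(
    data: ModelData, eta_cols: np.ndarray, ts: np.ndarray, theta: float | None
) -> np.ndarray:
    """Fast per-cell log-likelihood restricted to the given columns."""
    mu = data.P[:, None] * _exp_eta(eta_cols)
    Y = data.Y[:, ts]
    obs = data.obs[:, ts]
    if data.spec.likelihood is Likelihood.POISSON:
        return obs * (Y * eta_cols - mu)
    return obs * (Y * eta_cols - (Y + theta) * np.log(theta + mu))
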