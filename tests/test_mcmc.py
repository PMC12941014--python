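"""Sampler correctness: likelihood kernels, priors, determinism, DIC."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.stats as st

from stcar import (CountPanel, Likelihood, ModelSpec, PriorConfig,
                   SamplerConfig, Temporal, compare_models, dic, dic_compare,
                   fit)
from stcar.mcmc import deviance, full_loglik, prepare_model_data


def _data_for(panel, spec, lattice=None, covars=None):
    return prepare_model_data(spec, panel, covars, lattice)


class TestLikelihoodKernels:
    def test_poisson_loglik_matches_scipy(self, tiny_panel, grid33):
        spec = ModelSpec.model(1)
        lat = __import__("stcar").make_grid_lattice(2, 2)
        data = _data_for(tiny_panel, spec, lat)
        rng = np.random.default_rng(0)
        for _ in range(5):
            eta = rng.normal(-3, 0.5, size=tiny_panel.Y.shape)
            mu = tiny_panel.P[:, None] * np.exp(eta)
            expect = st.poisson(mu).logpmf(tiny_panel.Y).sum()
            assert full_loglik(data, eta, None) == pytest.approx(expect,
                                                                 abs=1e-10)

    def test_negbin_loglik_matches_scipy(self, tiny_panel):
        lat = __import__("stcar").make_grid_lattice(2, 2)
        spec = ModelSpec.model(1, likelihood=Likelihood.NEGBIN)
        data = _data_for(tiny_panel, spec, lat)
        rng = np.random.default_rng(1)
        for theta in (0.5, 3.0, 20.0):
            eta = rng.normal(-3, 0.5, size=tiny_panel.Y.shape)
            mu = tiny_panel.P[:, None] * np.exp(eta)
            expect = st.nbinom(theta, theta / (theta + mu)).logpmf(
                tiny_panel.Y).sum()
            assert full_loglik(data, eta, theta) == pytest.approx(expect,
                                                                  rel=1e-10)

    def test_negbin_approaches_poisson_at_large_dispersion(self, tiny_panel):
        lat = __import__("stcar").make_grid_lattice(2, 2)
        pdata = _data_for(tiny_panel, ModelSpec.model(1), lat)
        ndata = _data_for(tiny_panel,
                          ModelSpec.model(1, likelihood=Likelihood.NEGBIN),
                          lat)
        eta = np.full(tiny_panel.Y.shape, -3.2)
        n_cells = tiny_panel.Y.size
        diff = abs(full_loglik(ndata, eta, 1e8) - full_loglik(pdata, eta, None))
        assert diff / n_cells < 1e-4


class TestConjugateOracle:
    def test_single_cell_posterior_matches_gamma(self):
        """Flat-prior intercept-only Poisson model: the rate posterior is
        Gamma(y, P) in closed form."""
        panel = CountPanel(Y=np.array([[30]]), P=np.array([100]),
                           tract_ids=("a",), period_labels=("2018",),
                           granularity="year")
        spec = ModelSpec(temporal=Temporal.NONE, spatial_effects=False)
        res = fit(spec, panel, None, None,
                  SamplerConfig(draws=2000, warmup=500, chains=2, seed=5))
        lam = np.exp(res.scalar_draws["beta0"].to_numpy())
        g = st.gamma(30, scale=1 / 100)
        assert lam.mean() == pytest.approx(g.mean(), rel=0.02)
        assert np.quantile(lam, 0.5) == pytest.approx(g.ppf(0.5), rel=0.03)


class TestPriorReproduction:
    def test_masked_panel_returns_tau_prior(self):
        """With every cell masked out of the likelihood, the precision
        posterior is its gamma(1, 5e-5) prior (mean 20,000)."""
        lat = __import__("stcar").make_grid_lattice(2, 2)
        panel = CountPanel(
            Y=np.zeros((4, 4), dtype=int), P=np.full(4, 100),
            tract_ids=lat.tract_ids,
            period_labels=("2018", "2019", "2020", "2021"),
            granularity="year", observed=np.zeros((4, 4), dtype=bool),
        )
        spec = ModelSpec.model(2)
        res = fit(spec, panel, None, lat,
                  SamplerConfig(draws=4000, warmup=500, chains=1, seed=9))
        tau_v = res.scalar_draws["tau_v"].to_numpy()
        assert tau_v.mean() == pytest.approx(20000, rel=0.2)


class TestDeterminismAndDiagnostics:
    def test_same_seed_identical_draws(self, yearly_dataset):
        d = yearly_dataset
        cfg = SamplerConfig(draws=150, warmup=150, chains=1, seed=42)
        a = fit(d["spec"], d["panel"], d["covars"], d["lattice"], cfg)
        b = fit(d["spec"], d["panel"], d["covars"], d["lattice"], cfg)
        assert a.scalar_draws.equals(b.scalar_draws)
        assert a.diagnostics.DIC == b.diagnostics.DIC

    def test_different_seeds_differ(self, yearly_dataset):
        d = yearly_dataset
        a = fit(d["spec"], d["panel"], d["covars"], d["lattice"],
                SamplerConfig(draws=150, warmup=150, chains=1, seed=1))
        b = fit(d["spec"], d["panel"], d["covars"], d["lattice"],
                SamplerConfig(draws=150, warmup=150, chains=1, seed=2))
        assert not a.scalar_draws.equals(b.scalar_draws)

    def test_summary_quantile_ordering_and_positive_rates(self, model1_fit):
        tab = model1_fit.summary.params
        assert (tab["q2.5"] <= tab["mean"] + 1e-12).all()
        assert (tab["mean"] <= tab["q97.5"] + 1e-12).all()
        assert (model1_fit.summary.lambda_mean > 0).all()

    def test_icar_sum_to_zero_every_draw(self, model1_fit):
        assert model1_fit.diagnostics.max_abs_s_sum < 1e-9

    def test_short_run_flagged_unconverged(self, yearly_dataset):
        d = yearly_dataset
        res = fit(d["spec"], d["panel"], d["covars"], d["lattice"],
                  SamplerConfig(draws=40, warmup=40, chains=2, seed=3))
        assert not res.diagnostics.converged

    def test_posterior_icar_field_smoother_than_iid(self, model1_fit,
                                                    yearly_dataset):
        """The ICAR field's posterior mean shows more positive spatial
        autocorrelation than the i.i.d. field's."""
        from stcar import morans_i

        lat = yearly_dataset["lattice"]
        s_hat = model1_fit.summary.s_mean
        v_hat = model1_fit.summary.v_mean
        assert morans_i(s_hat, lat) > morans_i(v_hat, lat)


class TestDIC:
    def test_dic_identity_and_recompute(self, model1_fit, yearly_dataset):
        d = yearly_dataset
        diag = model1_fit.diagnostics
        assert diag.DIC == pytest.approx(diag.Dbar + diag.pD, abs=1e-9)
        re = dic(model1_fit, d["panel"], d["covars"], d["lattice"])
        assert re.DIC == pytest.approx(diag.DIC, abs=1e-9)

    def test_degenerate_posterior_zero_pd(self, tiny_panel):
        """If the 'posterior' is a point mass, Dbar equals the plug-in
        deviance and pD = 0."""
        lat = __import__("stcar").make_grid_lattice(2, 2)
        data = _data_for(tiny_panel, ModelSpec.model(1), lat)
        mu = tiny_panel.Y + 0.5
        d_point = deviance(data, mu, None)
        assert d_point == pytest.approx(
            -2 * st.poisson(mu).logpmf(tiny_panel.Y).sum(), abs=1e-9)
        dev_draws = np.full(100, d_point)  # point-mass posterior
        pd_eff = dev_draws.mean() - d_point
        assert pd_eff == pytest.approx(0.0, abs=1e-9)

    def test_dic_compare_bands(self):
        assert dic_compare(100.0, 101.5) == "similar"
        assert dic_compare(100.0, 110.0) == "better"
        assert dic_compare(110.0, 100.0) == "worse"

    def test_compare_models_identical_specs_same_dic(self, yearly_dataset):
        d = yearly_dataset
        cfg = SamplerConfig(draws=150, warmup=150, chains=1, seed=11)
        df = compare_models([d["spec"], d["spec"]], d["panel"], d["covars"],
                            d["lattice"], cfg)
        assert df["DIC"].iloc[0] == pytest.approx(df["DIC"].iloc[1], abs=1e-9)
        assert df["similar_to_best"].all()

    def test_compare_models_order_invariant(self, yearly_dataset):
        d = yearly_dataset
        cfg = SamplerConfig(draws=150, warmup=150, chains=1, seed=11)
        s2 = ModelSpec.model(2, covariate_names=d["spec"].covariate_names)
        ab = compare_models([d["spec"], s2], d["panel"], d["covars"],
                            d["lattice"], cfg)
        ba = compare_models([s2, d["spec"]], d["panel"], d["covars"],
                            d["lattice"], cfg)
        assert ab.set_index("model")["DIC"].to_dict() == \
            ba.set_index("model")["DIC"].to_dict()


class TestErrors:
    def test_spatial_fit_requires_lattice(self, tiny_panel):
        with pytest.raises(ValueError, match="lattice"):
            fit(ModelSpec.model(1), tiny_panel, None, None,
                SamplerConfig(draws=10, warmup=10, chains=1, seed=0))

    def test_prior_defaults_match_convention(self):
        pri = PriorConfig()
        assert pri.intercept_precision == 0.0
        assert pri.slope_precision == 0.001
        assert pri.tau_shape == 1.0 and pri.tau_rate == 0.00005
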