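"""Generator correctness: ICAR, RW1, covariates, count panels."""

from __future__ import annotations

import numpy as np
import pytest

from stcar import (Likelihood, ModelSpec, SimulationTruth, make_grid_lattice,
                   make_truth, sample_icar, sample_rw1, simulate_covariates,
                   simulate_panel, simulate_populations)
from stcar.simulate import expected_panel_mean


class TestICAR:
    def test_sums_to_zero(self, grid33):
        s = sample_icar(grid33, tau_s=2.0, seed=1)
        assert abs(s.sum()) < 1e-9

    def test_deterministic_given_seed(self, grid33):
        a = sample_icar(grid33, 2.0, seed=5)
        b = sample_icar(grid33, 2.0, seed=5)
        c = sample_icar(grid33, 2.0, seed=6)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_disconnected_needs_flag(self):
        from stcar import TractLattice

        lat = TractLattice.from_edges(["a", "b", "c", "d"],
                                      [("a", "b"), ("c", "d")])
        with pytest.raises(ValueError, match="components"):
            sample_icar(lat, 1.0, seed=0)
        s = sample_icar(lat, 1.0, seed=0, per_component_centering=True)
        assert abs(s.sum()) < 1e-9

    def test_single_unit_rejected(self):
        with pytest.raises(ValueError):
            sample_icar(make_grid_lattice(1, 1), 1.0, seed=0)

    def test_covariance_matches_laplacian_pseudoinverse(self, grid33):
        """Empirical covariance of many draws equals pinv(tau*(D-W))."""
        tau = 3.0
        rng = np.random.default_rng(42)
        draws = np.stack([sample_icar(grid33, tau, rng) for _ in range(20000)])
        emp = np.cov(draws.T)
        target = np.linalg.pinv(tau * grid33.laplacian())
        scale = np.abs(target).max()
        assert np.abs(emp - target).max() < 0.05 * scale

    def test_conditional_mean_slope_is_one(self):
        """Regressing s_i on its neighbor mean across draws gives slope ~1
        (the intrinsic CAR conditional expectation).  The sum-to-zero
        constraint perturbs the conditional by O(1/n), so the check uses a
        lattice large enough for that distortion to be small."""
        lat = make_grid_lattice(8, 8)
        rng = np.random.default_rng(3)
        i = lat.index("r4c4")
        xs, ys = [], []
        for _ in range(3000):
            s = sample_icar(lat, 2.0, rng)
            xs.append(s[lat.neighbors[i]].mean())
            ys.append(s[i])
        slope = np.polyfit(xs, ys, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.08)


class TestRW1:
    def test_high_precision_limit_stays_at_start(self):
        g = sample_rw1(10, tau_gamma=1e12, seed=0, gamma0=2.5)
        assert np.allclose(g, 2.5, atol=1e-4)

    def test_increment_variance(self):
        rng = np.random.default_rng(1)
        tau = 4.0
        incs = []
        for _ in range(10000):
            g = sample_rw1(5, tau, rng)
            incs.extend(np.diff(np.concatenate(([0.0], g))))
        assert np.var(incs) == pytest.approx(1 / tau, rel=0.05)

    def test_t1_single_gaussian(self):
        rng = np.random.default_rng(2)
        draws = np.array([sample_rw1(1, 2.0, rng, gamma0=1.0)[0]
                          for _ in range(5000)])
        assert draws.mean() == pytest.approx(1.0, abs=0.05)
        assert draws.var() == pytest.approx(0.5, rel=0.1)

    def test_invalid_precision(self):
        with pytest.raises(ValueError):
            sample_rw1(4, 0.0, seed=0)


class TestCovariates:
    def test_zero_step_sd_constant_over_years(self, grid33):
        tab = simulate_covariates(grid33, [2018, 2019, 2020], seed=0,
                                  year_step_sd=0.0)
        wide = tab.values.unstack("year")
        for name in tab.covariate_names:
            block = wide[name].to_numpy()
            assert np.allclose(block, block[:, [0]])

    def test_percentages_clipped(self, grid33):
        tab = simulate_covariates(grid33, [2018, 2019], seed=1,
                                  year_step_sd=50.0)
        for c in tab.percentage_covariates():
            col = tab.values[c]
            assert col.between(0, 100).all()

    def test_deterministic(self, grid33):
        a = simulate_covariates(grid33, [2018], seed=9)
        b = simulate_covariates(grid33, [2018], seed=9)
        assert a.values.equals(b.values)

    def test_five_default_covariates(self, grid33):
        tab = simulate_covariates(grid33, [2018], seed=0)
        assert tab.k == 5


class TestPopulations:
    def test_within_bounds_and_deterministic(self, grid5):
        p = simulate_populations(grid5, seed=4)
        q = simulate_populations(grid5, seed=4)
        assert np.array_equal(p, q)
        assert p.min() >= 199 and p.max() <= 3001


class TestSimulatePanel:
    def test_null_effects_poisson_mean(self):
        """With all effects zero and beta0 = log(0.01), P = 1000, every cell
        mean is 10; the grand sample mean is within 3 s.e."""
        lat = make_grid_lattice(5, 10)
        spec = ModelSpec.model(1)
        truth = SimulationTruth(beta0=np.log(0.01), alpha_year=(0.0, 0.0, 0.0),
                                s=np.zeros(50), v=np.zeros(50))
        panel = simulate_panel(spec, truth, lat, None,
                               np.full(50, 1000), seed=11)
        n_cells = panel.Y.size
        se = np.sqrt(10.0 / n_cells)
        assert panel.Y.mean() == pytest.approx(10.0, abs=3 * se)

    def test_model1_covid_pattern_equals_model2_means(self, grid33):
        """alpha = (0, a, a) in the year-indicator model gives exactly the
        COVID-indicator model's cell means."""
        pops = np.full(9, 500)
        a = -0.3
        s = sample_icar(grid33, 5.0, seed=1)
        v = np.zeros(9)
        m1 = expected_panel_mean(
            ModelSpec.model(1),
            SimulationTruth(beta0=-3.0, alpha_year=(0.0, a, a), s=s, v=v),
            grid33, None, pops)
        m2 = expected_panel_mean(
            ModelSpec.model(2),
            SimulationTruth(beta0=-3.0, alpha_covid=a, s=s, v=v),
            grid33, None, pops)
        assert np.array_equal(m1, m2)

    def test_interaction_inflates_cell_variance(self, grid33):
        """Model 5 with small tau_delta has larger per-cell variance than
        Model 4 at equal means."""
        pops = np.full(9, 1000)
        spec4 = ModelSpec.model(4)
        spec5 = ModelSpec.model(5)
        base = dict(beta0=-3.0, s=np.zeros(9), v=np.zeros(9),
                    gamma=np.zeros(12), phi=np.zeros(12))
        t4 = SimulationTruth(**base)
        rng = np.random.default_rng(0)
        var4, var5 = [], []
        for r in range(200):
            delta = rng.standard_normal((9, 12)) / np.sqrt(4.0)  # sd 0.5
            t5 = SimulationTruth(**base, delta=delta)
            y4 = simulate_panel(spec4, t4, grid33, None, pops, seed=1000 + r,
                                years=[2018])
            y5 = simulate_panel(spec5, t5, grid33, None, pops, seed=3000 + r,
                                years=[2018])
            var4.append(y4.Y.var())
            var5.append(y5.Y.var())
        assert np.mean(var5) > 1.5 * np.mean(var4)

    def test_negbin_large_dispersion_recovers_poisson_index(self, grid33):
        """Index of dispersion -> 1 as the NB dispersion -> infinity."""
        pops = np.full(9, 1000)
        base = dict(beta0=-3.0, s=np.zeros(9), v=np.zeros(9),
                    alpha_year=(0.0, 0.0, 0.0))
        spec_nb = ModelSpec.model(1, likelihood=Likelihood.NEGBIN)
        big = SimulationTruth(**base, nb_dispersion=1e8)
        small = SimulationTruth(**base, nb_dispersion=2.0)
        ys_big, ys_small = [], []
        for r in range(300):
            ys_big.append(simulate_panel(spec_nb, big, grid33, None, pops,
                                         seed=r).Y[0, 0])
            ys_small.append(simulate_panel(spec_nb, small, grid33, None, pops,
                                           seed=10_000 + r).Y[0, 0])
        iod_big = np.var(ys_big) / np.mean(ys_big)
        iod_small = np.var(ys_small) / np.mean(ys_small)
        assert iod_big == pytest.approx(1.0, abs=0.35)
        assert iod_small > 3.0

    def test_missing_truth_component_named(self, grid33):
        spec = ModelSpec.model(5)
        truth = SimulationTruth(beta0=-3.0, s=np.zeros(9), v=np.zeros(9),
                                gamma=np.zeros(12), phi=np.zeros(12))
        with pytest.raises(ValueError, match="delta"):
            simulate_panel(spec, truth, grid33, None, np.full(9, 100), seed=0,
                           years=[2018])

    def test_truth_json_round_trip(self, grid33, tmp_path):
        spec = ModelSpec.model(1, covariate_names=("median_age",))
        truth = make_truth(spec, grid33, 4, seed=5)
        p = tmp_path / "truth.json"
        truth.to_json(p)
        back = SimulationTruth.from_json(p)
        assert back.beta == truth.beta
        assert np.allclose(back.s, truth.s)
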