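"""VIF screening, quartiles, Q1->Q3 effects and the prior grid."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stcar import (ModelSpec, SamplerConfig, make_grid_lattice, make_truth,
                   prior_sensitivity, q1q3_effect, quartiles,
                   simulate_covariates, simulate_panel, simulate_populations,
                   vif)


def frame(**cols):
    return pd.DataFrame(cols)


class TestVIF:
    def test_independent_predictors_near_one(self):
        rng = np.random.default_rng(0)
        df = frame(a=rng.standard_normal(5000), b=rng.standard_normal(5000))
        out = vif(df, include_year=False).set_index("predictor")["vif"]
        assert out["a"] == pytest.approx(1.0, abs=0.02)
        assert out["b"] == pytest.approx(1.0, abs=0.02)

    def test_exact_correlation_09_closed_form(self):
        """Two predictors with sample correlation exactly 0.9:
        VIF = 1/(1-0.81) = 5.263..."""
        rng = np.random.default_rng(1)
        x = rng.standard_normal(400)
        z = rng.standard_normal(400)
        x = (x - x.mean()) / x.std()
        # orthogonalize z against x, then mix to hit r = 0.9 exactly
        z = z - (z @ x) / (x @ x) * x
        z = (z - z.mean()) / z.std()
        y = 0.9 * x + np.sqrt(1 - 0.81) * z
        out = vif(frame(x=x, y=y), include_year=False)
        assert out["vif"].to_numpy() == pytest.approx(
            [1 / (1 - 0.81)] * 2, rel=1e-6)

    def test_duplicated_predictor_infinite(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(100)
        out = vif(frame(a=x, b=x.copy(), c=rng.standard_normal(100)),
                  include_year=False).set_index("predictor")
        assert np.isinf(out.loc["a", "vif"])
        assert out.loc["a", "flag"] == "infinite"

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            vif(frame(a=np.ones(50), b=np.arange(50.0)), include_year=False)

    def test_year_included_from_covariate_table(self, grid33):
        tab = simulate_covariates(grid33, [2018, 2019, 2020, 2021], seed=3)
        out = vif(tab)
        assert "Year" in out["predictor"].tolist()
        assert len(out) == 6

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(0.01, 50), shift=st.floats(-100, 100))
    def test_affine_rescaling_invariance(self, scale, shift):
        rng = np.random.default_rng(4)
        a = rng.standard_normal(200)
        b = 0.5 * a + rng.standard_normal(200)
        base = vif(frame(a=a, b=b), include_year=False)["vif"].to_numpy()
        out = vif(frame(a=scale * a + shift, b=b),
                  include_year=False)["vif"].to_numpy()
        assert out == pytest.approx(base, rel=1e-6)

    def test_cross_check_against_statsmodels(self):
        """Independent oracle: R^2-based VIF from statsmodels OLS."""
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        X = rng.standard_normal((300, 3))
        X[:, 2] += 0.8 * X[:, 0]
        df = frame(a=X[:, 0], b=X[:, 1], c=X[:, 2])
        ours = vif(df, include_year=False).set_index("predictor")["vif"]
        for j, name in enumerate(["a", "b", "c"]):
            others = np.delete(X, j, axis=1)
            r2 = sm.OLS(X[:, j], sm.add_constant(others)).fit().rsquared
            assert ours[name] == pytest.approx(1 / (1 - r2), rel=1e-8)


class TestQuartiles:
    def test_one_to_eight_linear_interpolation(self):
        assert quartiles(range(1, 9)) == (2.75, 6.25)

    def test_constant_and_order_invariance(self):
        assert quartiles([4.0] * 6) == (4.0, 4.0)
        fwd = quartiles([3.0, 1.0, 7.0, 5.0, 9.0])
        rev = quartiles([9.0, 5.0, 7.0, 1.0, 3.0])
        assert fwd == rev

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            quartiles([1.0, 2.0, 3.0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=4, max_size=40))
    def test_brackets_median(self, values):
        q1, q3 = quartiles(values)
        med = float(np.median(values))
        assert q1 <= med <= q3


class TestQ1Q3Effect:
    def test_zero_slope_gives_unit_effect(self):
        assert q1q3_effect(0.0, 3.0, 99.0).effect == 1.0

    def test_known_exponential(self):
        assert q1q3_effect(0.1, 0.0, 10.0).effect == pytest.approx(np.e,
                                                                   rel=1e-12)

    def test_monotone_in_slope(self):
        effects = [q1q3_effect(b, 10.0, 20.0).effect
                   for b in (-0.1, 0.0, 0.1, 0.2)]
        assert effects == sorted(effects)
        assert effects[1] == 1.0

    def test_equal_quartiles_unit_effect(self):
        assert q1q3_effect(5.0, 2.0, 2.0).effect == 1.0

    def test_reversed_quartiles_rejected(self):
        with pytest.raises(ValueError):
            q1q3_effect(0.1, 5.0, 2.0)


class TestPriorSensitivity:
    def test_trivial_grid_gives_eight_identical_rows(self, grid33):
        """With alternatives equal to the defaults, all 8 combinations are
        the same model and the same seed gives identical rows."""
        spec = ModelSpec.model(2)
        pops = simulate_populations(grid33, seed=21)
        truth = make_truth(spec, grid33, 4, seed=22)
        panel = simulate_panel(spec, truth, grid33, None, pops, seed=23)
        default = spec.priors
        same = {
            "intercept": {"intercept_mean": default.intercept_mean,
                          "intercept_precision": default.intercept_precision},
            "slope": {"slope_precision": default.slope_precision},
            "precision": {"tau_shape": default.tau_shape,
                          "tau_rate": default.tau_rate},
        }
        out = prior_sensitivity(
            spec, panel, None, grid33,
            SamplerConfig(draws=100, warmup=100, chains=1, seed=31),
            alternatives=same)
        assert len(out) == 8
        est_cols = [c for c in out.columns if c.endswith("_mean")]
        assert (out[est_cols].nunique() == 1).all()
        assert (out["max_abs_dev"] == 0).all()

    def test_robustness_on_well_identified_data(self, grid33):
        """With large counts the default and alternative priors agree to
        well within one posterior sd."""
        spec = ModelSpec.model(2)
        pops = np.full(9, 20000)
        truth = make_truth(spec, grid33, 4, seed=41)
        panel = simulate_panel(spec, truth, grid33, None, pops, seed=42)
        out = prior_sensitivity(
            spec, panel, None, grid33,
            SamplerConfig(draws=300, warmup=300, chains=1, seed=43))
        assert len(out) == 8
        # compare the COVID-effect estimate across combinations to its sd
        dev = out["max_abs_dev"].max()
        assert dev < 0.1
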