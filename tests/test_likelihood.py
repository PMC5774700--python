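import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.special import expit
from scipy.stats import norm

import jointglmm as jg
from jointglmm.design import fixed_predictor
from jointglmm.estimation import (
    bernoulli_loglik,
    gauss_hermite_rule,
    marginal_loglik,
)

from oracles import trapezoid_triple_loglik


@pytest.fixture(scope="module")
def one_cluster_df():
    """Two women in a single cluster/division — the triple-integral toy."""
    return pd.DataFrame({
        "division_id": ["A", "A"], "cluster_id": ["A_c1", "A_c1"],
        "woman_id": [1, 2], "age": [25, 40], "tv": [1, 0],
        "y_cuc": [1, 0], "y_hiv": [0, 1],
    })


class TestConditionalLoglik:
    def _design(self, one_cluster_df):
        return jg.build_stacked_design(
            one_cluster_df, jg.ModelSpec.joint(("age", "tv")))

    def test_both_successes_at_even_odds(self, one_cluster_df):
        d = self._design(one_cluster_df)
        df = one_cluster_df.assign(y_cuc=1, y_hiv=1)
        d = jg.build_stacked_design(df, jg.ModelSpec.joint(("age", "tv")))
        params = jg.ModelParams(beta=np.zeros((2, 3)), sigma_u=1.0,
                                sigma_clu=1.0, sigma_div=1.0)
        val = jg.conditional_loglik_woman(d, 0, params, 0.0, 0.0, 0.0)
        assert np.isclose(val, 2 * np.log(0.5), atol=1e-12)

    def test_near_certain_events_contribute_nothing(self, one_cluster_df):
        # y=(1,0) with eta=(+20,-20): both observed outcomes are near-certain
        df = one_cluster_df.assign(y_cuc=1, y_hiv=0)
        d = jg.build_stacked_design(df, jg.ModelSpec.joint(()))
        params = jg.ModelParams(beta=np.array([[20.0], [-20.0]]), sigma_u=1.0,
                                sigma_clu=1.0, sigma_div=1.0)
        val = jg.conditional_loglik_woman(d, 0, params, 0.0, 0.0, 0.0)
        assert abs(val) < 1e-8

    def test_shared_effect_closed_form(self, one_cluster_df):
        df = one_cluster_df.assign(y_cuc=1, y_hiv=1)
        d = jg.build_stacked_design(df, jg.ModelSpec.joint(()))
        params = jg.ModelParams(beta=np.zeros((2, 1)), sigma_u=1.0,
                                sigma_clu=1.0, sigma_div=1.0)
        val = jg.conditional_loglik_woman(d, 0, params, 0.0, 0.0, 1.0)
        assert np.isclose(val, 2 * np.log(expit(1.0)), atol=1e-12)


class TestDegenerateAndContinuity:
    def test_no_random_effects_equals_closed_form(self, small_dataset):
        spec = jg.ModelSpec("joint", ("age", "tv"), (), quadrature_order=7)
        d = jg.build_stacked_design(small_dataset, spec)
        beta = np.array([[0.3, -0.01, 0.2], [-0.2, 0.005, 0.4]])
        params = jg.ModelParams(beta=beta)
        closed = float(bernoulli_loglik(d.y, fixed_predictor(d, params)).sum())
        assert abs(marginal_loglik(d, params) - closed) < 1e-10

    def test_sigma_to_zero_continuity(self, small_dataset):
        spec = jg.ModelSpec("joint", ("age", "tv"),
                            ("individual", "cluster", "division"),
                            quadrature_order=9)
        d = jg.build_stacked_design(small_dataset, spec)
        beta = np.array([[0.3, -0.01, 0.2], [-0.2, 0.005, 0.4]])
        tiny = jg.ModelParams(beta=beta, sigma_u=1e-8, sigma_clu=1e-8,
                              sigma_div=1e-8)
        closed = float(bernoulli_loglik(d.y, fixed_predictor(d, tiny)).sum())
        assert abs(marginal_loglik(d, tiny) - closed) < 1e-6


class TestOracleEquivalence:
    def test_triple_integral_matches_trapezoid_grid(self, one_cluster_df):
        spec = jg.ModelSpec("joint", ("age", "tv"),
                            ("individual", "cluster", "division"))
        d = jg.build_stacked_design(one_cluster_df, spec)
        params = jg.ModelParams(
            beta=np.array([[0.2, -0.02, 0.3], [-0.1, 0.01, 0.2]]),
            sigma_u=1.0, sigma_clu=0.5, sigma_div=0.3)
        oracle = trapezoid_triple_loglik(d, params, npts=401)
        ours = marginal_loglik(d, params)
        assert abs(ours - oracle) / abs(oracle) < 1e-6

    def test_single_woman_one_level_matches_adaptive_quad(self):
        """P(y=1) = Int phi(b) invlogit(b0 + b) db for one woman with only a
        cluster-level intercept, cross-checked against scipy.integrate.quad."""
        df = pd.DataFrame({"division_id": ["A"], "cluster_id": ["c"],
                           "woman_id": [1], "y_cuc": [1], "y_hiv": [0]})
        spec = jg.ModelSpec("cuc", (), ("cluster",), quadrature_order=11)
        d = jg.build_stacked_design(df, spec)
        b0 = 0.4
        params = jg.ModelParams(beta=np.array([[b0]]), sigma_clu=1.0)
        oracle, err = quad(lambda b: norm.pdf(b) * expit(b0 + b), -10, 10)
        assert err < 1e-8
        assert np.isclose(np.exp(marginal_loglik(d, params)), oracle,
                          rtol=1e-6)


class TestRandomSlopes:
    def test_zero_slope_variance_matches_intercept_model(self, small_dataset):
        beta = np.array([[0.2, 0.1, -0.1], [0.0, -0.05, 0.2]])
        with_slope = jg.ModelSpec("joint", ("age", "tv"),
                                  ("cluster", "division"), random_slope="tv",
                                  slope_levels=("cluster",), quadrature_order=7)
        no_slope = jg.ModelSpec("joint", ("age", "tv"),
                                ("cluster", "division"), quadrature_order=7)
        ds = jg.build_stacked_design(small_dataset, with_slope)
        dn = jg.build_stacked_design(small_dataset, no_slope)
        ps = jg.ModelParams(beta=beta, sigma_clu=0.4, sigma_div=0.3,
                            sigma_slope_clu=1e-12)
        pn = jg.ModelParams(beta=beta, sigma_clu=0.4, sigma_div=0.3)
        lls = marginal_loglik(ds, ps, adaptive=False)
        lln = marginal_loglik(dn, pn, adaptive=False)
        assert np.isclose(lls, lln, rtol=1e-9)

    def test_slope_generation_and_likelihood_run(self):
        params = jg.TrueParameters(
            covariates=("x1", "x2"), beta_cuc=np.array([0.2, 0.1, 0.3]),
            beta_hiv=np.array([0.0, 0.2, -0.1]), sigma_clu=0.3,
            slope_covariate="x1", sigma_slope_clu=0.5)
        from conftest import make_two_cov_data
        data = make_two_cov_data(2, 3, 10, params, seed=9)
        spec = jg.ModelSpec("joint", ("x1", "x2"), ("cluster",),
                            random_slope="x1", slope_levels=("cluster",),
                            quadrature_order=5)
        d = jg.build_stacked_design(data, spec)
        p = jg.ModelParams(beta=np.vstack([params.beta_cuc, params.beta_hiv]),
                           sigma_clu=0.3, sigma_slope_clu=0.5)
        assert np.isfinite(marginal_loglik(d, p))
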