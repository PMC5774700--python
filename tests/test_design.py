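import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import jointglmm as jg
from jointglmm.datasets import DatasetError
from jointglmm.design import Layout, fixed_predictor


class TestStacking:
    def test_joint_row_counts_and_indicators(self, small_dataset):
        spec = jg.ModelSpec.joint(("age", "tv"))
        d = jg.build_stacked_design(small_dataset, spec)
        n = len(small_dataset)
        assert d.n_rows == 2 * n
        assert d.indicators.sum(axis=0).tolist() == [n, n]
        # indicator exclusivity per row
        assert (d.indicators.prod(axis=1) == 0).all()
        assert (d.indicators.sum(axis=1) == 1).all()

    def test_single_outcome_rows(self, small_dataset):
        spec = jg.ModelSpec.separate("cuc", ("age",))
        d = jg.build_stacked_design(small_dataset, spec)
        assert d.n_rows == len(small_dataset)
        assert (d.outcome_idx == 0).all()

    def test_both_rows_of_a_woman_share_covariates(self, small_dataset):
        d = jg.build_stacked_design(small_dataset, jg.ModelSpec.joint(("age", "tv")))
        X = d.X.reshape(d.n_women, 2, -1)
        assert (X[:, 0, :] == X[:, 1, :]).all()

    def test_unknown_covariate_raises(self, small_dataset):
        with pytest.raises(DatasetError, match="height"):
            jg.build_stacked_design(small_dataset,
                                    jg.ModelSpec.joint(("age", "height")))

    def test_single_outcome_rejects_individual_level(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            jg.ModelSpec("cuc", ("age",), ("individual", "cluster"))


class TestInvLogit:
    def test_known_values(self):
        assert jg.inv_logit(0.0) == 0.5
        assert np.isclose(jg.inv_logit(np.log(3)), 0.75)

    def test_extreme_arguments_are_safe(self):
        assert jg.inv_logit(-745.0) >= 0.0
        assert jg.inv_logit(745.0) <= 1.0

    @given(st.floats(-30, 30))
    @settings(deadline=None, max_examples=50)
    def test_symmetry(self, eta):
        assert np.isclose(jg.inv_logit(-eta), 1.0 - jg.inv_logit(eta), atol=1e-12)


class TestLinearPredictor:
    def _design(self, toy_df):
        return jg.build_stacked_design(toy_df, jg.ModelSpec.joint(("age", "tv")))

    def test_all_zero(self, toy_df):
        d = self._design(toy_df)
        params = jg.ModelParams(beta=np.zeros((2, 3)))
        eff = {"division": np.zeros(2), "cluster": np.zeros(3),
               "woman": np.zeros(3)}
        assert (jg.linear_predictor(d, params, eff) == 0).all()

    def test_arithmetic(self, toy_df):
        # beta_1 = (1, 2) on one covariate, x = 3 -> eta = 7 for outcome 1
        df = toy_df.assign(age=3)
        d = jg.build_stacked_design(df, jg.ModelSpec.joint(("age",)))
        params = jg.ModelParams(beta=np.array([[1.0, 2.0], [0.0, 0.0]]))
        eff = {"division": np.zeros(2), "cluster": np.zeros(3),
               "woman": np.zeros(3)}
        eta = jg.linear_predictor(d, params, eff)
        assert np.allclose(eta[d.outcome_idx == 0], 7.0)
        assert np.allclose(eta[d.outcome_idx == 1], 0.0)

    def test_shared_woman_effect_enters_both_outcomes(self, toy_df):
        d = self._design(toy_df)
        params = jg.ModelParams(beta=np.zeros((2, 3)))
        eff = {"division": np.zeros(2), "cluster": np.zeros(3),
               "woman": np.array([1.5, 0.0, 0.0])}
        eta = jg.linear_predictor(d, params, eff)
        rows = d.woman_of_row == 0
        assert np.allclose(eta[rows], 1.5) and rows.sum() == 2

    def test_missing_effect_level_raises(self, toy_df):
        d = self._design(toy_df)
        params = jg.ModelParams(beta=np.zeros((2, 3)))
        with pytest.raises(KeyError, match="woman"):
            jg.linear_predictor(d, params, {"division": np.zeros(2),
                                            "cluster": np.zeros(3)})


class TestPacking:
    @given(
        beta=st.lists(st.floats(-20, 20), min_size=6, max_size=6),
        sigmas=st.lists(st.floats(1e-4, 50), min_size=3, max_size=3),
    )
    @settings(deadline=None, max_examples=50)
    def test_pack_unpack_roundtrip(self, beta, sigmas):
        spec = jg.ModelSpec("joint", ("x1", "x2"),
                            ("individual", "cluster", "division"))
        layout = Layout.from_spec(spec)
        params = jg.ModelParams(beta=np.array(beta).reshape(2, 3),
                                sigma_u=sigmas[0], sigma_clu=sigmas[1],
                                sigma_div=sigmas[2])
        back = layout.unpack(layout.pack(params))
        assert np.allclose(back.beta, params.beta, rtol=1e-12, atol=0)
        for name, val in zip(("sigma_u", "sigma_clu", "sigma_div"), sigmas):
            assert np.isclose(getattr(back, name), val, rtol=1e-12)

    def test_size_and_names(self):
        spec = jg.ModelSpec.separate("cuc", ("age", "tv"))
        layout = Layout.from_spec(spec)
        assert layout.size == 3 + 2
        names = layout.parameter_names()
        assert names[0] == "cuc:Intercept"
        assert names[-1] == "log_sigma_div"


class TestOrderInvariance:
    def test_row_permutation_and_relabeling_leave_loglik_unchanged(
            self, small_dataset, two_cov_params):
        spec = jg.ModelSpec("joint", ("age", "tv"),
                            ("individual", "cluster", "division"),
                            quadrature_order=5)
        params = jg.ModelParams(beta=np.array([[0.1, 0.01, -0.2],
                                               [-0.3, 0.0, 0.1]]),
                                sigma_u=0.8, sigma_clu=0.4, sigma_div=0.3)
        d0 = jg.build_stacked_design(small_dataset, spec)
        base = jg.marginal_loglik(d0, params)

        rng = np.random.default_rng(0)
        shuffled = small_dataset.sample(frac=1.0, random_state=1)
        d1 = jg.build_stacked_design(shuffled, spec)
        assert np.isclose(jg.marginal_loglik(d1, params), base, rtol=1e-12)

        relabeled = small_dataset.copy()
        relabeled["division_id"] = "zone_" + relabeled["division_id"].astype(str)
        relabeled["cluster_id"] = relabeled["cluster_id"] + "_x"
        relabeled["woman_id"] = rng.permutation(10_000 + np.arange(len(relabeled)))
        d2 = jg.build_stacked_design(relabeled, spec)
        assert np.isclose(jg.marginal_loglik(d2, params), base, rtol=1e-12)


def test_fixed_predictor_selects_outcome_block(toy_df, toy_beta):
    d = jg.build_stacked_design(toy_df, jg.ModelSpec.joint(("age", "tv")))
    eta = fixed_predictor(d, jg.ModelParams(beta=toy_beta))
    expected = np.where(d.outcome_idx == 0, d.X @ toy_beta[0], d.X @ toy_beta[1])
    assert np.allclose(eta, expected)
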