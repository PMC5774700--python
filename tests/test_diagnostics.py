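import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import expit
from scipy.stats import norm

import jointglmm as jg
from jointglmm.diagnostics import (
    LRTResult,
    hosmer_lemeshow,
    lrt_variance_component,
    mixture_pvalue,
    predict_random_effects,
)

from conftest import make_two_cov_data


class TestHosmerLemeshow:
    def test_perfect_calibration_gives_zero(self):
        y = np.tile([0, 1], 50)
        phat = np.full(100, 0.5)
        res = hosmer_lemeshow(y, phat, groups=10)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == 1.0

    def test_two_bin_hand_computation(self):
        """O=(3,7), n=(10,10), phat=0.4/0.6: each bin contributes
        (O-E)^2 / (E(1-E/n)) = 1/2.4, summing to 5/6."""
        y = np.concatenate([np.repeat([0, 1], [7, 3]), np.repeat([0, 1], [3, 7])])
        phat = np.repeat([0.4, 0.6], 10)
        res = hosmer_lemeshow(y, phat, groups=2)
        hand = (3 - 4) ** 2 / (4 * (1 - 0.4)) + (7 - 6) ** 2 / (6 * (1 - 0.6))
        assert res.statistic == pytest.approx(hand, rel=1e-12)
        assert res.groups == 2 and res.df == 0
        assert np.allclose(res.table["expected"], [4.0, 6.0])

    def test_joint_permutation_invariance(self):
        rng = np.random.default_rng(3)
        phat = rng.uniform(0.05, 0.95, 200)
        y = (rng.random(200) < phat).astype(int)
        base = hosmer_lemeshow(y, phat).statistic
        perm = rng.permutation(200)
        assert hosmer_lemeshow(y[perm], phat[perm]).statistic == pytest.approx(
            base, rel=1e-12)

    def test_degenerate_bin_suggests_fewer_groups(self):
        y = np.zeros(50, dtype=int)
        phat = np.full(50, 1e-9)
        phat = np.clip(phat, 1e-9, 1 - 1e-9)
        with pytest.raises(ValueError, match="fewer groups"):
            hosmer_lemeshow(y, phat, groups=5)

    def test_out_of_range_phat_rejected(self):
        with pytest.raises(ValueError, match="inside"):
            hosmer_lemeshow(np.array([0, 1]), np.array([0.0, 0.5]))


class TestBoundaryLRT:
    def test_point_mass_at_zero(self):
        assert mixture_pvalue(0.0) == 1.0
        assert mixture_pvalue(-1.0) == 1.0

    def test_known_critical_value(self):
        # 2.706 is the chi2_1 10% point, so the mixture tail is 5%
        assert mixture_pvalue(2.706) == pytest.approx(0.05, abs=5e-4)

    def test_monotone_decreasing(self):
        stats = np.linspace(0, 10, 50)
        ps = [mixture_pvalue(s) for s in stats]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_non_nested_specs_rejected(self, two_cov_params):
        data = make_two_cov_data(3, 4, 10, two_cov_params, seed=55)
        full = jg.fit(jg.build_stacked_design(
            data, jg.ModelSpec("cuc", ("x1",), ("cluster", "division"), quadrature_order=3)),
            compute_information=False)
        other_covs = jg.fit(jg.build_stacked_design(
            data, jg.ModelSpec("cuc", ("x2",), ("cluster",), quadrature_order=3)),
            compute_information=False)
        with pytest.raises(ValueError, match="not nested"):
            lrt_variance_component(full, other_covs)
        same = jg.fit(jg.build_stacked_design(
            data, jg.ModelSpec("cuc", ("x1",), ("cluster", "division"), quadrature_order=3)),
            compute_information=False)
        with pytest.raises(ValueError, match="exactly one"):
            lrt_variance_component(full, same)

    def test_identical_logliks_give_p_one(self, two_cov_params):
        data = make_two_cov_data(3, 4, 10, two_cov_params, seed=56)
        full = jg.fit(jg.build_stacked_design(
            data, jg.ModelSpec("cuc", ("x1",), ("cluster", "division"), quadrature_order=3)),
            compute_information=False)
        reduced = jg.fit(jg.build_stacked_design(
            data, jg.ModelSpec("cuc", ("x1",), ("cluster",), quadrature_order=3)),
            compute_information=False)
        res = lrt_variance_component(full, reduced)
        assert isinstance(res, LRTResult)
        assert res.statistic >= 0.0
        forced = LRTResult("division", 0.0, mixture_pvalue(0.0))
        assert forced.p == 1.0


class TestRandomEffectPrediction:
    def test_zero_variance_gives_zero_effects(self, toy_df):
        spec = jg.ModelSpec("joint", ("age", "tv"),
                            ("individual", "cluster", "division"),
                            quadrature_order=5)
        d = jg.build_stacked_design(toy_df, spec)
        params = jg.ModelParams(beta=np.zeros((2, 3)))
        pred = predict_random_effects(params, d)
        assert (pred.division == 0).all()
        assert (pred.cluster == 0).all()
        assert (pred.woman == 0).all()

    def test_overachieving_division_gets_positive_effect(self):
        df = pd.DataFrame({
            "division_id": np.repeat(["hi", "lo"], 20),
            "cluster_id": np.repeat(["hi_c", "lo_c"], 20),
            "woman_id": np.arange(40),
            "y_cuc": np.repeat([1, 0], 20),
            "y_hiv": np.repeat([1, 0], 20),
        })
        spec = jg.ModelSpec("joint", (), ("cluster", "division"),
                            quadrature_order=7)
        d = jg.build_stacked_design(df, spec)
        params = jg.ModelParams(beta=np.zeros((2, 1)), sigma_clu=0.3,
                                sigma_div=1.0)
        pred = predict_random_effects(params, d)
        assert pred.division["hi"] > 0 > pred.division["lo"]
        assert pred.ranked_divisions().index[0] == "hi"

    def test_single_woman_mode_matches_grid_search(self):
        """One woman, intercept-only, cluster level only: the predicted mode
        must agree with a brute-force maximization of the 1-D posterior."""
        df = pd.DataFrame({"division_id": ["A"], "cluster_id": ["c"],
                           "woman_id": [1], "y_cuc": [1], "y_hiv": [0]})
        spec = jg.ModelSpec("cuc", (), ("cluster",), quadrature_order=11)
        d = jg.build_stacked_design(df, spec)
        b0 = 0.3
        params = jg.ModelParams(beta=np.array([[b0]]), sigma_clu=1.0)
        pred = predict_random_effects(params, d)

        grid = np.linspace(-6, 6, 2_000_001)
        post = norm.logpdf(grid, 0, 1.0) + np.log(expit(b0 + grid))
        oracle = grid[np.argmax(post)]
        assert abs(pred.cluster.iloc[0] - oracle) < 1e-5

        refine = minimize_scalar(
            lambda b: -(norm.logpdf(b, 0, 1.0) + np.log(expit(b0 + b))),
            bounds=(-6, 6), method="bounded", options={"xatol": 1e-12})
        assert abs(pred.cluster.iloc[0] - refine.x) < 1e-6

    def test_balanced_effects_average_near_zero(self, two_cov_params):
        import dataclasses
        params = dataclasses.replace(two_cov_params, sigma_clu=0.5)
        data = make_two_cov_data(2, 10, 20, params, seed=66)
        spec = jg.ModelSpec("joint", ("x1", "x2"), ("cluster",),
                            quadrature_order=5)
        d = jg.build_stacked_design(data, spec)
        mp = jg.ModelParams(
            beta=np.vstack([params.beta_cuc, params.beta_hiv]), sigma_clu=0.5)
        pred = predict_random_effects(mp, d)
        # shrunken modes of a centred effect: mean within ~3 sd/sqrt(n)
        assert abs(pred.cluster.mean()) < 3 * 0.5 / np.sqrt(d.n_clusters)


@pytest.fixture(scope="module")
def all_fits(two_cov_params):
    data = make_two_cov_data(3, 5, 30, two_cov_params, seed=77)
    fits = {}
    for o in ("cuc", "hiv"):
        fits[f"standard_{o}"] = jg.fit(jg.build_stacked_design(
            data, jg.ModelSpec.standard(o, ("x1", "x2"))))
        fits[f"separate_{o}"] = jg.fit(jg.build_stacked_design(
            data, jg.ModelSpec.separate(o, ("x1", "x2"), order=3)))
    fits["joint"] = jg.fit(jg.build_stacked_design(
        data, jg.ModelSpec.joint(("x1", "x2"), order=3)))
    return fits


class TestCompareTable:
    def test_schema_mirrors_reported_layout(self, all_fits):
        table = jg.compare_joint_separate(all_fits)
        assert list(table.index) == ["Intercept", "x1", "x2"]
        for outcome in ("cuc", "hiv"):
            for model in ("standard", "three_level", "joint"):
                for metric in ("logodds", "OR", "p"):
                    assert (outcome, model, metric) in table.columns
            assert (outcome, "joint_minus_three_level", "logodds") in table.columns

    def test_difference_column_is_exact(self, all_fits):
        t = jg.compare_joint_separate(all_fits)
        for outcome in ("cuc", "hiv"):
            d = (t[(outcome, "joint", "logodds")]
                 - t[(outcome, "three_level", "logodds")])
            assert np.allclose(t[(outcome, "joint_minus_three_level", "logodds")], d)

    def test_missing_fit_rejected(self, all_fits):
        partial = {k: v for k, v in all_fits.items() if k != "joint"}
        with pytest.raises(ValueError, match="joint"):
            jg.compare_joint_separate(partial)

    def test_mismatched_covariates_rejected(self, all_fits, two_cov_params):
        data = make_two_cov_data(3, 5, 30, two_cov_params, seed=77)
        bad = dict(all_fits)
        bad["standard_cuc"] = jg.fit(jg.build_stacked_design(
            data, jg.ModelSpec.standard("cuc", ("x1",))))
        with pytest.raises(ValueError, match="covariate"):
            jg.compare_joint_separate(bad)
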