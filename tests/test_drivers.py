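"""Driver-screening statistics: correlation, OLS, ANOVA, Mantel, stepwise,
permutation importance."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eestoich.core import DistanceMatrix, DomainError
from eestoich.drivers import (
    anova_oneway,
    forward_stepwise,
    mantel,
    ols,
    pearson,
    permutation_importance,
)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson(x, 2 * x + 1)[0] == pytest.approx(1.0)
        assert pearson(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self):
        x = np.array([1, 2, 3, 4, 5.0])
        y = np.array([2, 1, 4, 3, 6.0])
        r, _ = pearson(x, y)
        oracle = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_named_in_error(self):
        with pytest.raises(DomainError, match="tds"):
            pearson([1, 1, 1], [1, 2, 3], x_name="tds")

    def test_pairwise_deletion_of_missing(self):
        x = np.array([1, 2, np.nan, 4, 5.0])
        y = np.array([1, 2, 3, 4, np.nan])
        r, _ = pearson(x, y)
        assert r == pytest.approx(1.0)


class TestOls:
    def test_exact_linear_fit(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.normal(size=30)})
        y = 2.0 * X["a"] + 3.0
        fit = ols(y, X)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.adj_r2 == pytest.approx(1.0)
        assert fit.coefficients["a"] == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(3.0)

    def test_noise_has_near_zero_adjusted_r2(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": rng.normal(size=10_000)})
        y = rng.normal(size=10_000)
        fit = ols(y, X)
        assert abs(fit.adj_r2) < 0.01

    def test_single_predictor_slope_identity(self):
        """slope = r · sd(y)/sd(x), and r itself on standardised data."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        y = 0.6 * x + rng.normal(size=200)
        r, _ = pearson(x, y)
        fit = ols(y, pd.DataFrame({"x": x}))
        assert fit.coefficients["x"] == pytest.approx(
            r * y.std(ddof=1) / x.std(ddof=1), abs=1e-10
        )
        zfit = ols(
            (y - y.mean()) / y.std(ddof=1),
            pd.DataFrame({"x": (x - x.mean()) / x.std(ddof=1)}),
        )
        assert zfit.coefficients["x"] == pytest.approx(r, abs=1e-10)

    def test_rank_deficient_design_names_columns(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [2.0, 4, 6, 8, 10]})
        with pytest.raises(DomainError, match=r"collinear columns: \['[ab]'\]"):
            ols(np.arange(5.0), X)

    def test_adjusted_r2_formula(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        y = X["a"].to_numpy() + rng.normal(size=50)
        fit = ols(y, X)
        n, p = fit.n, 3
        assert fit.adj_r2 == pytest.approx(
            1 - (1 - fit.r2) * (n - 1) / (n - p - 1), abs=1e-12
        )


class TestAnova:
    def test_identical_means_give_zero_f(self):
        res = anova_oneway([[1.0, 2, 3], [2.0, 1, 3]])
        assert res.f_stat == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_ssb_ssw_oracle(self):
        """Groups (1,2,3) and (4,5,6): SSB=13.5, SSW=4 ⇒ F = 13.5."""
        res = anova_oneway([[1, 2, 3], [4, 5, 6]])
        assert res.f_stat == pytest.approx(13.5, abs=1e-12)
        assert (res.df_between, res.df_within) == (1, 4)
        assert res.p_value == pytest.approx(float(stats.f.sf(13.5, 1, 4)), abs=1e-12)

    def test_two_group_f_equals_pooled_t_squared(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)
        res = anova_oneway([a, b])
        t, _ = stats.ttest_ind(a, b, equal_var=True)
        assert res.f_stat == pytest.approx(t**2, abs=1e-10)

    def test_zero_within_variance_rejected(self):
        with pytest.raises(DomainError):
            anova_oneway([[1.0, 1.0], [2.0, 2.0]])


def _random_dm(rng, n, ids=None):
    pts = rng.normal(size=(n, 3))
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    return DistanceMatrix(ids=ids or [f"s{i}" for i in range(n)], d=d)


class TestMantel:
    def test_self_comparison_minimum_p(self):
        rng = np.random.default_rng(0)
        dm = _random_dm(rng, 10)
        res = mantel(dm, dm, n_perm=999, seed=1)
        assert res.r_obs == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_matches_exhaustive_enumeration_on_4x4(self):
        """Random-permutation p agrees with the exact 24-permutation null."""
        rng = np.random.default_rng(5)
        d1, d2 = _random_dm(rng, 4), _random_dm(rng, 4)
        iu = np.triu_indices(4, k=1)
        v1 = d1.d[iu]
        r_obs = stats.pearsonr(v1, d2.d[iu])[0]
        rs = []
        for perm in itertools.permutations(range(4)):
            p = np.array(perm)
            rs.append(stats.pearsonr(v1, d2.d[p[:, None], p[None, :]][iu])[0])
        p_exact = np.mean(np.array(rs) >= r_obs - 1e-12)
        res = mantel(d1, d2, n_perm=4999, seed=2)
        se = math.sqrt(p_exact * (1 - p_exact) / 4999)
        assert abs(res.p_value - p_exact) < 4 * se + 1e-3

    def test_invariant_to_joint_relabelling(self):
        rng = np.random.default_rng(6)
        d1, d2 = _random_dm(rng, 8), _random_dm(rng, 8)
        perm = rng.permutation(8)
        ids = [d1.ids[i] for i in perm]
        d1p = DistanceMatrix(ids, d1.d[perm[:, None], perm[None, :]])
        d2p = DistanceMatrix(ids, d2.d[perm[:, None], perm[None, :]])
        a = mantel(d1, d2, n_perm=999, seed=3)
        b = mantel(d1p, d2p, n_perm=999, seed=3)
        assert a.r_obs == pytest.approx(b.r_obs, abs=1e-12)
        assert abs(a.p_value - b.p_value) < 0.05

    def test_agrees_with_skbio(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(7)
        d1, d2 = _random_dm(rng, 12), _random_dm(rng, 12)
        r_ref, p_ref, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(d1.d, d1.ids),
            skbio_distance.DistanceMatrix(d2.d, d2.ids),
            method="pearson", permutations=999, alternative="greater",
        )
        res = mantel(d1, d2, n_perm=999, seed=8)
        assert res.r_obs == pytest.approx(r_ref, abs=1e-10)
        assert abs(res.p_value - p_ref) < 0.06

    def test_id_mismatch_rejected(self):
        rng = np.random.default_rng(9)
        d1 = _random_dm(rng, 5)
        d2 = _random_dm(rng, 5, ids=[f"t{i}" for i in range(5)])
        with pytest.raises(DomainError):
            mantel(d1, d2)


class TestForwardStepwise:
    def test_single_perfect_predictor(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"a": rng.normal(size=50)})
        model = forward_stepwise(3 * X["a"] + 1, X)
        assert model.predictors == ["a"]
        assert model.adj_r2 == pytest.approx(1.0)

    def test_recovers_two_planted_predictors_of_eight(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(200, 8)), columns=[f"v{i}" for i in range(8)])
        y = 2.0 * X["v2"] - 1.5 * X["v5"] + rng.normal(size=200)
        model = forward_stepwise(y, X)
        assert {"v2", "v5"} <= set(model.predictors)

    def test_zero_candidates_returns_intercept_only(self):
        model = forward_stepwise(np.arange(10.0), pd.DataFrame(index=range(10)))
        assert model.predictors == []
        assert model.adj_r2 == 0.0

    def test_null_candidates_never_beat_intercept_aic_and_stay_weak(self):
        """With pure-noise candidates the returned model's AIC is never worse
        than the intercept-only model's, and any spuriously admitted
        predictors explain almost nothing."""
        weak = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(
                rng.normal(size=(100, 8)), columns=[f"v{i}" for i in range(8)]
            )
            y = rng.normal(size=100)
            model = forward_stepwise(y, X)
            intercept_only = ols(y, X[[]])
            assert model.aic <= intercept_only.aic + 1e-9
            if model.adj_r2 < 0.15:
                weak += 1
        assert weak >= 90


class TestPermutationImportance:
    def _fit(self, seed=0, n=300):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({
            "x1": rng.normal(size=n),
            "x2": rng.normal(size=n),
            "zero": rng.normal(size=n),
        })
        y = 3 * X["x1"] + X["x2"] + rng.normal(size=n)
        return y.to_numpy(), X, ols(y, X)

    def test_strong_predictor_dominates(self):
        wins = 0
        for seed in range(20):
            y, X, model = self._fit(seed)
            imp = permutation_importance(model, y, X, n_rep=30, seed=seed)
            tab = imp.set_index("predictor")["mse_increase"]
            wins += tab["x1"] > tab["x2"]
        assert wins >= 19

    def test_zero_coefficient_importance_near_zero(self):
        y, X, model = self._fit(3)
        imp = permutation_importance(model, y, X, n_rep=50, seed=0)
        tab = imp.set_index("predictor")["mse_increase"]
        assert abs(tab["zero"]) < 0.05 * tab["x1"]

    def test_contributions_sum_to_100(self):
        y, X, model = self._fit(4)
        imp = permutation_importance(model, y, X, n_rep=20, seed=1)
        assert imp["contribution_pct"].sum() == pytest.approx(100.0)

    def test_unknown_predictor_rejected(self):
        y, X, model = self._fit(5)
        with pytest.raises(DomainError, match="ghost"):
            permutation_importance(model, y, X, predictors=["ghost"])
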