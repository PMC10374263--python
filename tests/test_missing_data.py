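"""Little's MCAR test, chained imputation and Rubin pooling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats, optimize

import lcpain as lp
from lcpain.missing_data import LittleResult


def _ml_mean_cov_direct(x):
    """Independent oracle: maximize the observed-data normal likelihood
    directly with a generic optimizer (Cholesky-parameterized)."""
    p = x.shape[1]

    def unpack(theta):
        mu = theta[:p]
        l = np.zeros((p, p))
        idx = p
        for i in range(p):
            for j in range(i + 1):
                l[i, j] = theta[idx]
                idx += 1
        return mu, l @ l.T

    def nll(theta):
        mu, sigma = unpack(theta)
        total = 0.0
        for row in x:
            o = ~np.isnan(row)
            if not o.any():
                continue
            try:
                total -= stats.multivariate_normal.logpdf(
                    row[o], mu[o], sigma[np.ix_(o, o)], allow_singular=False)
            except (np.linalg.LinAlgError, ValueError):
                return 1e10
        return total

    mu0 = np.nanmean(x, axis=0)
    cov0 = np.cov(np.where(np.isnan(x), mu0, x), rowvar=False, bias=True)
    l0 = np.linalg.cholesky(cov0 + 1e-6 * np.eye(p))
    theta0 = np.concatenate([mu0, l0[np.tril_indices(p)]])
    res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                            options={"maxiter": 20000, "xatol": 1e-10,
                                     "fatol": 1e-12})
    return unpack(res.x)


def _little_d2_oracle(x, mu, sigma):
    obs = ~np.isnan(x)
    d2 = 0.0
    for mask in {tuple(r) for r in obs}:
        o = np.array(mask)
        rows = np.all(obs == o, axis=1)
        ybar = x[rows][:, o].mean(axis=0)
        diff = ybar - mu[o]
        d2 += rows.sum() * diff @ np.linalg.solve(sigma[np.ix_(o, o)], diff)
    return d2


class TestLittleMCAR:
    def test_complete_data_is_trivially_mcar(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(50, 3)))
        res = lp.little_mcar_test(df)
        assert res == LittleResult(d2=0.0, df=0, p=1.0, n_patterns=1)

    def test_centered_patterns_give_near_zero_statistic(self):
        # two patterns whose observed means equal the grand mean exactly
        a = np.array([-1.0, 1.0, -1.0, 1.0, -2.0, 2.0])
        b = np.array([2.0, -2.0, 1.0, -1.0, np.nan, np.nan])
        res = lp.little_mcar_test(pd.DataFrame({"a": a, "b": b}))
        assert res.d2 == pytest.approx(0.0, abs=1e-6)
        assert res.df == 1

    def test_statistic_matches_direct_ml_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, size=(40, 2))
        x[:, 1] = 0.7 * x[:, 0] + 0.5 * x[:, 1]
        x[rng.uniform(size=40) < 0.3, 1] = np.nan
        res = lp.little_mcar_test(pd.DataFrame(x, columns=["a", "b"]))
        mu, sigma = _ml_mean_cov_direct(x)
        d2_oracle = _little_d2_oracle(x, mu, sigma)
        assert res.d2 == pytest.approx(d2_oracle, rel=1e-3, abs=1e-3)
        assert res.df == 1

    def test_invariant_to_row_order_and_affine_rescaling(self):
        rng = np.random.default_rng(2)
        x = rng.normal(2.0, 1.5, size=(80, 3))
        for j in range(3):
            x[rng.uniform(size=80) < 0.15, j] = np.nan
        x = x[~np.all(np.isnan(x), axis=1)]
        df = pd.DataFrame(x, columns=list("abc"))
        base = lp.little_mcar_test(df)
        shuffled = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
        assert lp.little_mcar_test(shuffled).p == pytest.approx(base.p, abs=1e-6)
        rescaled = df * np.array([10.0, 0.2, 3.0]) + np.array([5.0, -1.0, 0.0])
        assert lp.little_mcar_test(rescaled).p == pytest.approx(base.p, abs=1e-5)

    def test_mar_missingness_is_detected(self):
        rng = np.random.default_rng(4)
        n = 400
        a = rng.normal(0, 1, n)
        b = 0.8 * a + rng.normal(0, 0.6, n)
        b[a > 0.3] = np.nan  # missingness depends on observed a
        res = lp.little_mcar_test(pd.DataFrame({"a": a, "b": b}))
        assert res.p < 0.01


class TestImputeChained:
    def test_complete_data_returned_unchanged(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0.0, 1.0, 0.0]})
        imp = lp.impute_chained(df, {"a": "continuous", "b": "binary"}, m=2, seed=0)
        for d in imp.datasets:
            pd.testing.assert_frame_equal(d, df)

    def test_observed_cells_identical_across_imputations(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"a": rng.normal(size=60), "b": rng.normal(size=60)})
        df.loc[rng.uniform(size=60) < 0.3, "b"] = np.nan
        obs = df["b"].notna()
        imp = lp.impute_chained(df, {"a": "continuous", "b": "continuous"},
                                m=3, seed=1, cycles=3)
        for d in imp.datasets:
            np.testing.assert_array_equal(d.loc[obs, "b"], df.loc[obs, "b"])
            assert d["b"].notna().all()

    def test_binary_imputations_respect_type(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({"a": rng.normal(size=100),
                           "b": (rng.uniform(size=100) < 0.4).astype(float)})
        df.loc[rng.uniform(size=100) < 0.25, "b"] = np.nan
        imp = lp.impute_chained(df, {"a": "continuous", "b": "binary"},
                                m=2, seed=2, cycles=3)
        for d in imp.datasets:
            assert set(d["b"].unique()) <= {0.0, 1.0}

    def test_count_imputations_are_nonnegative_integers(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"a": rng.normal(size=100),
                           "c": rng.poisson(3, size=100).astype(float)})
        df.loc[rng.uniform(size=100) < 0.25, "c"] = np.nan
        imp = lp.impute_chained(df, {"a": "continuous", "c": "count"},
                                m=2, seed=3, cycles=3)
        for d in imp.datasets:
            v = d["c"].to_numpy()
            assert np.all(v >= 0) and np.all(v == np.round(v))

    def test_mcar_imputation_nearly_unbiased_for_the_mean(self):
        # 20% MCAR on a variable correlated r=0.8 with a complete one
        truth_mean = 0.0
        biases = []
        for rep in range(50):
            rng = np.random.default_rng(100 + rep)
            n = 200
            a = rng.normal(0, 1, n)
            b = 0.8 * a + np.sqrt(1 - 0.64) * rng.normal(0, 1, n)
            df = pd.DataFrame({"a": a, "b": b})
            df.loc[rng.uniform(size=n) < 0.2, "b"] = np.nan
            imp = lp.impute_chained(df, {"a": "continuous", "b": "continuous"},
                                    m=3, seed=rep, cycles=4)
            pooled = np.mean([d["b"].mean() for d in imp.datasets])
            biases.append(pooled - truth_mean)
        assert abs(np.mean(biases)) < 0.05  # in SD units (b has unit variance)

    def test_all_missing_variable_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="all values missing"):
            lp.impute_chained(df, {"a": "continuous", "b": "continuous"}, m=2)

    def test_unknown_type_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(ValueError, match="unknown variable type"):
            lp.impute_chained(df, {"a": "ordinal"}, m=2)


class TestPoolRubin:
    def test_equal_estimates_have_no_between_variance(self):
        pe = lp.pool_rubin([1.0, 1.0], [0.5, 0.5])
        assert (pe.estimate, pe.between, pe.total) == (1.0, 0.0, 0.5)
        assert np.isinf(pe.df)

    def test_hand_arithmetic_case(self):
        pe = lp.pool_rubin([0.0, 2.0], [1.0, 1.0])
        assert pe.estimate == 1.0
        assert pe.within == 1.0
        assert pe.between == 2.0
        assert pe.total == pytest.approx(1.0 + 1.5 * 2.0)
        expected_df = (2 - 1) * (1 + 1.0 / (1.5 * 2.0)) ** 2
        assert pe.df == pytest.approx(expected_df)

    def test_identical_imputations_reduce_to_single_fit_wald_interval(self):
        est, var = 0.7, 0.04
        pe = lp.pool_rubin([est] * 20, [var] * 20)
        half = stats.norm.ppf(0.975) * np.sqrt(var)
        assert pe.ci_low == pytest.approx(est - half)
        assert pe.ci_high == pytest.approx(est + half)

    def test_total_variance_never_below_within(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            q = rng.normal(size=5)
            u = rng.uniform(0.1, 1.0, size=5)
            pe = lp.pool_rubin(q, u)
            assert pe.total >= pe.within
            assert pe.between >= 0

    def test_m_below_two_rejected(self):
        with pytest.raises(ValueError):
            lp.pool_rubin([1.0], [0.5])
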