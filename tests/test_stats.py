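"""Spearman matrix, standardization, OLS, VIF, permutation and grouped FDR
against closed forms and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dgmqsm.stats import (
    fdr_grouped,
    fit_ols,
    freedman_lane_pvalues,
    spearman_matrix,
    standardize,
    vif,
)


def _rank_then_pearson(x, y):
    """Oracle: average ranks then the Pearson formula."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


class TestSpearmanMatrix:
    def test_monotone_transform_gives_unity(self):
        df = pd.DataFrame({"x": np.linspace(0, 3, 20)})
        df["y"] = np.exp(df.x)
        cm = spearman_matrix(df, ["x", "y"])
        assert cm.r.loc["x", "y"] == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        df["y"] = -df.x
        cm = spearman_matrix(df, ["x", "y"])
        assert cm.r.loc["x", "y"] == pytest.approx(-1.0)

    def test_hand_computed_rank_correlation(self):
        """x = 1..5 vs y = (2,1,4,3,5): 1 - 6*4/(5*24) = 0.8."""
        df = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [2, 1, 4, 3, 5]})
        cm = spearman_matrix(df, ["x", "y"])
        d2 = sum((a - b) ** 2 for a, b in zip(df.x, df.y))
        oracle = 1 - 6 * d2 / (5 * (25 - 1))
        assert cm.r.loc["x", "y"] == pytest.approx(oracle)
        assert oracle == pytest.approx(0.8)

    def test_matches_brute_force_oracle_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            df = pd.DataFrame(rng.standard_normal((20, 6)), columns=list("abcdef"))
            cm = spearman_matrix(df, list("abcdef"))
            for i, a in enumerate("abcdef"):
                for b in "abcdef"[i + 1 :]:
                    assert cm.r.loc[a, b] == pytest.approx(
                        _rank_then_pearson(df[a], df[b]), abs=1e-12
                    )

    def test_constant_variable_reported_missing(self):
        df = pd.DataFrame({"x": np.arange(10.0), "c": np.ones(10)})
        cm = spearman_matrix(df, ["x", "c"])
        assert np.isnan(cm.r.loc["x", "c"])
        assert np.isnan(cm.p.loc["x", "c"])

    def test_pairwise_complete_counts(self):
        df = pd.DataFrame({"x": np.arange(10.0), "y": np.arange(10.0)})
        df.loc[:2, "y"] = np.nan
        cm = spearman_matrix(df, ["x", "y"])
        assert cm.n.loc["x", "y"] == 7

    def test_symmetry_and_diagonal(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((30, 4)), columns=list("abcd"))
        cm = spearman_matrix(df, list("abcd"))
        np.testing.assert_allclose(cm.r.to_numpy(), cm.r.to_numpy().T)
        np.testing.assert_allclose(np.diag(cm.r.to_numpy()), 1.0)


class TestStandardize:
    def test_zscore_moments(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.standard_normal(50) * 7 + 3})
        z = standardize(df, ["a"])
        assert z.a.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.a.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_already_standard_unchanged(self):
        x = np.array([-1.0, 0.0, 1.0])
        x = (x - x.mean()) / x.std(ddof=1)
        df = pd.DataFrame({"a": x})
        np.testing.assert_allclose(standardize(df, ["a"]).a, x, atol=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            standardize(pd.DataFrame({"a": np.ones(5)}), ["a"])


class TestFitOls:
    def test_intercept_only_is_mean(self):
        y = np.array([1.0, 2.0, 6.0, 3.0, 8.0])
        fit = fit_ols(pd.DataFrame(index=range(5)), y)
        assert fit.params[0] == pytest.approx(y.mean())

    def test_single_standardized_predictor_equals_pearson(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        y = 0.4 * x + rng.standard_normal(200)
        df = pd.DataFrame({"x": (x - x.mean()) / x.std(ddof=1)})
        yz = (y - y.mean()) / y.std(ddof=1)
        fit = fit_ols(df, yz)
        assert fit.params[1] == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_two_predictors_match_normal_equations(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((50, 2))
        y = x @ [0.5, -0.3] + rng.standard_normal(50)
        fit = fit_ols(pd.DataFrame(x, columns=["a", "b"]), y)
        xc = np.column_stack([np.ones(50), x])
        oracle = np.linalg.solve(xc.T @ xc, xc.T @ y)
        np.testing.assert_allclose(fit.params, oracle, atol=1e-10)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(30)
        df = pd.DataFrame({"a": a, "b": 2 * a})
        with pytest.raises(ValueError, match="rank deficient.*'a'.*'b'"):
            fit_ols(df, rng.standard_normal(30))


class TestVif:
    def test_orthogonal_predictors_unity(self):
        n = 400
        x = np.zeros((n, 2))
        x[: n // 2, 0] = 1
        x[::2, 1] = 1  # orthogonal binary contrasts
        x = (x - x.mean(0)) / x.std(0)
        v = vif(pd.DataFrame(x, columns=["a", "b"]))
        assert v["a"] == pytest.approx(1.0, abs=1e-10)

    def test_closed_form_at_known_correlation(self):
        """Two predictors with r = 0.6: VIF = 1/(1-0.36) = 1.5625."""
        rng = np.random.default_rng(0)
        n = 200000
        a = rng.standard_normal(n)
        b = 0.6 * a + np.sqrt(1 - 0.36) * rng.standard_normal(n)
        v = vif(pd.DataFrame({"a": a, "b": b}))
        assert v["a"] == pytest.approx(1.5625, rel=0.01)
        # exact closed-form on the empirical correlation
        r = np.corrcoef(a, b)[0, 1]
        assert v["a"] == pytest.approx(1 / (1 - r**2), rel=1e-10)

    def test_duplicated_column_flagged_infinite(self):
        a = np.arange(20.0)
        v = vif(pd.DataFrame({"a": a, "b": a}))
        assert np.isinf(v["a"]) and np.isinf(v["b"])


class TestFreedmanLane:
    def _toy(self, n=120, beta=0.0, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((n, 3))
        y = beta * x[:, 0] + 0.3 * x[:, 1] + rng.standard_normal(n)
        return pd.DataFrame(x, columns=["t", "n1", "n2"]), y

    def test_strong_effect_attains_minimum_p(self):
        design, y = self._toy(n=400, beta=0.5)
        p, _, _ = freedman_lane_pvalues(design, y, n_permutations=500, seed=0)
        assert p["t"] == pytest.approx(1 / 501)

    def test_seeded_reproducibility(self):
        design, y = self._toy(beta=0.1)
        a, _, _ = freedman_lane_pvalues(design, y, n_permutations=300, seed=5)
        b, _, _ = freedman_lane_pvalues(design, y, n_permutations=300, seed=5)
        pd.testing.assert_series_equal(a, b)

    def test_few_permutations_warn(self):
        design, y = self._toy()
        _, _, flags = freedman_lane_pvalues(design, y, n_permutations=50, seed=0)
        assert "warning" in flags

    def test_null_p_uniformity(self):
        """Under the null the permutation p is ~uniform on its grid."""
        pvals = []
        for s in range(200):
            design, y = self._toy(n=60, beta=0.0, seed=1000 + s)
            p, _, _ = freedman_lane_pvalues(
                design, y, n_permutations=99, seed=s, terms=["t"]
            )
            pvals.append(p["t"])
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_t_matches_ols(self):
        design, y = self._toy(beta=0.3)
        _, t_obs, _ = freedman_lane_pvalues(design, y, n_permutations=100, seed=0)
        fit = fit_ols(design, y)
        np.testing.assert_allclose(t_obs.to_numpy(), fit.tvalues[1:], atol=1e-10)


from oracles import bh_step_up as _bh_oracle  # noqa: E402


class TestFdrGrouped:
    def test_single_p_per_group_unchanged(self):
        q, sig = fdr_grouped(np.array([0.03, 0.2]), np.array(["a", "b"]))
        np.testing.assert_allclose(q, [0.03, 0.2])
        assert sig.tolist() == [True, False]

    def test_hand_computed_bh(self):
        """(0.01, 0.02, 0.03, 0.04) in one group -> all corrected to 0.04."""
        q, _ = fdr_grouped(np.array([0.01, 0.02, 0.03, 0.04]), np.repeat("g", 4))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_equal_ps_unchanged(self):
        q, _ = fdr_grouped(np.full(5, 0.02), np.repeat("g", 5))
        np.testing.assert_allclose(q, 0.02)

    def test_grouping_isolates_correction(self):
        p = np.array([0.01, 0.5, 0.01, 0.5])
        pooled, _ = fdr_grouped(p, np.repeat("g", 4))
        grouped, _ = fdr_grouped(p, np.array(["a", "a", "b", "b"]))
        np.testing.assert_allclose(grouped, [0.02, 0.5, 0.02, 0.5])
        assert pooled[0] == pytest.approx(0.02)

    def test_matches_oracle_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.random(17)
            groups = rng.integers(0, 3, 17)
            q, _ = fdr_grouped(p, groups)
            for g in np.unique(groups):
                m = groups == g
                np.testing.assert_allclose(q[m], _bh_oracle(p[m]), atol=1e-12)

    def test_corrected_never_below_raw(self):
        rng = np.random.default_rng(1)
        p = rng.random(40)
        q, _ = fdr_grouped(p, rng.integers(0, 4, 40))
        assert np.all(q >= p - 1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            fdr_grouped(np.array([0.5, 1.2]), np.array(["a", "a"]))
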