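import numpy as np
import pandas as pd
import pytest

from aerotox.response import (
    OPCSModel,
    SegmentedResponseModel,
    correlation_matrix,
    fold_change_ddct,
    normalize_op,
    ros_mass_norm,
)


class TestFoldChange:
    @pytest.mark.parametrize("ddct,expected", [(0.0, 1.0), (-1.0, 2.0), (1.0, 0.5)])
    def test_scalar_convention(self, ddct, expected):
        fc = fold_change_ddct(20.0 + ddct, 18.0, 20.0, 18.0)
        assert fc.value == pytest.approx(expected)
        assert fc.n == 1 and not fc.flagged

    def test_triplicates_geometric_mean_and_sd(self):
        te = np.array([19.0, 19.5, 18.5])
        fc = fold_change_ddct(te, 18.0, 20.0, 18.0)
        per_rep = 2.0 ** (-(te - 18.0 - 2.0))
        assert fc.value == pytest.approx(np.exp(np.mean(np.log(per_rep))))
        assert fc.sd == pytest.approx(np.std(per_rep, ddof=1))
        assert fc.n == 3

    def test_missing_replicate_flagged(self):
        fc = fold_change_ddct(np.array([19.0, np.nan, 18.5]), 18.0, 20.0, 18.0)
        assert fc.flagged and fc.n == 2

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            fold_change_ddct(np.array([np.nan]), 18.0, 20.0, 18.0)


class TestNormalisations:
    def test_ratio(self):
        assert normalize_op(1.0, 10.0) == pytest.approx(0.1)

    def test_scale_invariance(self):
        assert normalize_op(3.0, 30.0) == pytest.approx(normalize_op(0.3, 3.0))

    def test_round_trip(self):
        pm1, dtt_m = 12.5, 0.08
        assert normalize_op(dtt_m * pm1, pm1) == pytest.approx(dtt_m)

    def test_zero_pm_flagged_nan(self):
        assert np.isnan(normalize_op(1.0, 0.0))
        out = ros_mass_norm(np.array([1.0, 2.0]), np.array([0.0, 10.0]))
        assert np.isnan(out[0]) and out[1] == pytest.approx(0.2)


class TestCorrelationMatrix:
    def test_exact_linear_relation(self):
        x = np.arange(16.0)
        t = pd.DataFrame({"x": x, "y": 2 * x})
        m = correlation_matrix(t)
        assert m.r2.loc["x", "y"] == pytest.approx(1.0)
        assert m.rho2.loc["x", "y"] == pytest.approx(1.0)
        assert np.allclose(np.diag(m.r2), 1.0)

    def test_monotone_nonlinear_relation(self):
        x = np.linspace(-2, 2, 16)
        t = pd.DataFrame({"x": x, "y": x**3 + 5})
        m = correlation_matrix(t)
        assert m.rho2.loc["x", "y"] == pytest.approx(1.0)
        assert m.r2.loc["x", "y"] < 1.0

    def test_invariances(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame(rng.normal(size=(16, 3)), columns=list("abc"))
        m1 = correlation_matrix(t)
        shuffled = t.sample(frac=1, random_state=1)
        rescaled = shuffled * np.array([2.0, 0.1, 1000.0]) + np.array([5.0, -3.0, 0.0])
        m2 = correlation_matrix(rescaled)
        assert np.allclose(m1.r2.to_numpy(), m2.r2.to_numpy())
        assert np.allclose(m1.rho2.to_numpy(), m2.rho2.to_numpy())

    def test_pairwise_n_reported(self):
        t = pd.DataFrame({"x": np.arange(16.0), "y": np.arange(16.0)})
        t.loc[:7, "y"] = np.nan  # a DCFH-style half-coverage variable
        m = correlation_matrix(t)
        assert m.n.loc["x", "y"] == 8

    def test_zero_variance_flagged_nan(self):
        t = pd.DataFrame({"x": np.arange(16.0), "c": np.ones(16)})
        m = correlation_matrix(t)
        assert np.isnan(m.r2.loc["x", "c"])

    def test_bh_option_available_but_separate(self):
        rng = np.random.default_rng(2)
        t = pd.DataFrame(rng.normal(size=(16, 4)), columns=list("abcd"))
        m = correlation_matrix(t)
        adj = m.apply_bh()
        off = ~np.eye(4, dtype=bool)
        assert np.all(adj.to_numpy()[off] >= m.p_pearson.to_numpy()[off] - 1e-12)


class TestOPCSModel:
    @staticmethod
    def _z(x):
        return (x - x.mean()) / x.std(ddof=0)

    def test_exact_recovery(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"dtt_v": rng.uniform(0.1, 2, 16),
                          "cs_200_900": rng.uniform(1e-3, 1e-2, 16)})
        y = 2 * self._z(X["dtt_v"]) - 1 * self._z(X["cs_200_900"])
        res = OPCSModel(y, X).fit()
        assert res.params["dtt_v"] == pytest.approx(2.0, abs=1e-10)
        assert res.params["cs_200_900"] == pytest.approx(-1.0, abs=1e-10)
        assert res.rsquared == pytest.approx(1.0, abs=1e-12)
        assert res.coefficient_signs == {"dtt_v": 1, "cs_200_900": -1}

    def test_campaign_sign_recovery(self, winter_daily):
        from aerotox.synthesis import simulate_response

        tox, _ = simulate_response(winter_daily, seed=7)
        res = OPCSModel(tox["cxcl8_fc"], winter_daily[["dtt_v", "cs_8_20", "cs_200_900"]]).fit()
        assert res.params["dtt_v"] > 0
        assert res.params["cs_200_900"] < 0

    def test_permutation_null(self, winter_daily):
        from aerotox.synthesis import simulate_response

        tox, _ = simulate_response(winter_daily, seed=3)
        res = OPCSModel(tox["hmox1_fc"], winter_daily[["dtt_v", "cs_8_20", "cs_200_900"]]).fit()
        null = res.permutation_r2(n_permutations=500, seed=0)
        assert res.rsquared > np.quantile(null, 0.95)

    def test_too_few_rows_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 1, 4, 3]})
        with pytest.raises(ValueError):
            OPCSModel(np.arange(4.0), X)

    def test_collinearity_warning_with_vif(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 1, 20)
        X = pd.DataFrame({"a": a, "b": a + rng.normal(0, 1e-4, 20)})
        res = OPCSModel(rng.normal(size=20), X).fit()
        assert res.collinearity_warning
        assert all(v > 10 for v in res.vif.values())


class TestSegmented:
    def test_linear_data_prefers_linear(self):
        x = np.linspace(2, 40, 16)
        res = SegmentedResponseModel(x, 0.5 + 0.1 * x).fit()
        assert not res.prefers_segmented

    def test_negative_low_slope_sign_reported(self):
        rng = np.random.default_rng(0)
        x = np.linspace(2, 40, 20)
        y = 3 - 0.1 * np.minimum(x, 15) + rng.normal(0, 0.01, 20)
        res = SegmentedResponseModel(x, y).fit()
        assert res.slope1 < 0

    def test_breakpoint_recovery_monte_carlo(self):
        rng = np.random.default_rng(5)
        bps = []
        for _ in range(200):
            x = rng.uniform(2, 40, 16)
            y = 1 + 0.2 * np.minimum(x, 15) + rng.normal(0, 0.05, 16)
            bps.append(SegmentedResponseModel(x, y).fit().breakpoint)
        assert 10 <= np.median(bps) <= 20

    def test_fallback_when_grid_unusable(self):
        x = np.concatenate([np.full(8, 1.0), np.full(8, 60.0)])
        y = x * 0.1
        res = SegmentedResponseModel(x, y, breakpoint_grid=[30.0], min_side=9).fit()
        assert res.fallback_linear and np.isnan(res.breakpoint)

    def test_prediction_continuous_at_breakpoint(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(2, 40, 24)
        y = 1 + 0.2 * np.minimum(x, 12) + rng.normal(0, 0.03, 24)
        res = SegmentedResponseModel(x, y).fit()
        lo = res.predict(res.breakpoint - 1e-9)
        hi = res.predict(res.breakpoint + 1e-9)
        assert lo == pytest.approx(hi, abs=1e-6)
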