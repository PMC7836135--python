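"""Two-stage multilevel model machinery and Table-style inference.

Oracles: explicit normal-equation OLS, hand-computed SSE(full) vs
SSE(reduced) model comparisons, a brute-force Benjamini-Hochberg step-up,
and statsmodels OLS as an independent cross-check of the full level-2 fit.
"""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from ssvepmod.mlm import (
    TwoStageMLM,
    bootstrap_corr,
    center_brightness,
    ci_from_se,
    eta_p2,
    f_from_ss,
    fdr_adjust,
    fit_level1,
    fit_level2,
)

CODES = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])


class TestCenterBrightness:
    def test_one_to_five_maps_to_centered(self):
        assert np.array_equal(center_brightness([1, 2, 3, 4, 5]), CODES)

    def test_already_centered_unchanged(self):
        assert np.array_equal(center_brightness(CODES), CODES)

    def test_lux_levels_map_by_rank(self):
        assert np.array_equal(center_brightness([1, 30, 60, 90, 120]), CODES)

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError, match="5 distinct"):
            center_brightness([1, 2, 3, 4])

    @given(st.lists(st.floats(-1e3, 1e3), min_size=5, max_size=5, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_sum_zero_sumsq_ten(self, levels):
        out = center_brightness(levels)
        assert out.sum() == 0
        assert (out**2).sum() == 10


class TestLevel1:
    def test_exact_line(self):
        fit = fit_level1(3 + 2 * CODES, CODES)
        assert fit.b0 == pytest.approx(3.0)
        assert fit.b1 == pytest.approx(2.0)
        assert fit.residual_df == 3

    def test_constant_response(self):
        fit = fit_level1(np.full(5, 4.2), CODES, psd=np.array([1.0, 3, 2, 5, 4]))
        assert fit.b1 == pytest.approx(0.0, abs=1e-12)
        assert fit.b2 == pytest.approx(0.0, abs=1e-12)
        assert fit.residual_df == 2

    def test_matches_normal_equations_oracle(self, rng):
        y = rng.standard_normal(5)
        psd = rng.standard_normal(5)
        fit = fit_level1(y, CODES, psd)
        X = np.column_stack([np.ones(5), CODES, psd])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.b0 == pytest.approx(beta[0], abs=1e-10)
        assert fit.b1 == pytest.approx(beta[1], abs=1e-10)
        assert fit.b2 == pytest.approx(beta[2], abs=1e-10)

    def test_brightness_closed_form(self, rng):
        y = rng.standard_normal(5)
        fit = fit_level1(y, CODES)
        assert fit.b0 == pytest.approx(y.mean())
        assert fit.b1 == pytest.approx((CODES * y).sum() / 10)

    def test_collinear_psd_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            fit_level1(np.arange(5.0), CODES, psd=2 * CODES)


class TestTableStatistics:
    """Worked identities from the reported occipital-electrode results."""

    @pytest.mark.parametrize(
        "ss, df_den, mse, expected",
        [(617.64, 146, 1.22, 0.78), (134.33, 143, 14.92, 0.06), (0.0, 143, 14.92, 0.0)],
    )
    def test_eta_p2(self, ss, df_den, mse, expected):
        assert eta_p2(ss, df_den, mse) == pytest.approx(expected, abs=0.005)

    @pytest.mark.parametrize(
        "ss, mse, expected",
        [(134.33, 14.92, 9.00), (0.83, 0.17, 4.88), (0.0, 3.0, 0.0)],
    )
    def test_f_from_ss(self, ss, mse, expected):
        assert f_from_ss(ss, 1, mse) == pytest.approx(expected, abs=0.005)

    def test_ci_reported_brightness_slope(self):
        lo, hi = ci_from_se(2.05, 0.09, 146)
        assert lo == pytest.approx(1.87, abs=0.005)
        assert hi == pytest.approx(2.23, abs=0.005)

    def test_ci_zero_se_degenerate(self):
        assert ci_from_se(1.5, 0.0, 10) == (1.5, 1.5)

    def test_ci_matches_t_quantile_oracle(self, rng):
        b, se, df = 0.7, 0.21, 29
        lo, hi = ci_from_se(b, se, df)
        t = scipy.stats.t.ppf(0.975, df)
        assert (lo, hi) == pytest.approx((b - t * se, b + t * se))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            eta_p2(1.0, 10, 0.0)
        with pytest.raises(ValueError):
            f_from_ss(1.0, 1, -2.0)
        with pytest.raises(ValueError):
            ci_from_se(1.0, -0.1, 10)


class TestLevel2:
    def test_constant_coefficient(self, rng):
        mods = pd.DataFrame(rng.standard_normal((10, 3)), columns=list("abc"))
        res = fit_level2(np.full(10, 5.5), mods)
        mod_rows = res[res["term"] != "Intercept"]
        assert np.allclose(mod_rows["ss"], 0.0, atol=1e-18)
        assert res.loc[res["term"] == "Intercept", "b"].iloc[0] == pytest.approx(5.5)

    def test_eight_participant_model_comparison_oracle(self, rng):
        """SS/F/eta_p2 equal explicit SSE(full) - SSE(reduced) computations."""
        y = rng.standard_normal(8)
        mods = pd.DataFrame(rng.standard_normal((8, 2)), columns=["m1", "m2"])
        res = fit_level2(y, mods)
        Xc = np.column_stack([np.ones(8), mods - mods.mean(axis=0)])

        def sse(X):
            if X.shape[1] == 0:
                return float(y @ y)
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return float(r @ r)

        sse_full = sse(Xc)
        df_den = 8 - 3
        mse = sse_full / df_den
        for j, term in enumerate(["Intercept", "m1", "m2"]):
            row = res[res["term"] == term].iloc[0]
            ss = sse(np.delete(Xc, j, axis=1)) - sse_full
            assert row["ss"] == pytest.approx(ss, abs=1e-10)
            assert row["f"] == pytest.approx(ss / mse, abs=1e-8)
            assert row["eta_p2"] == pytest.approx(ss / (ss + df_den * mse), abs=1e-10)
            assert row["df_den"] == df_den

    def test_matches_statsmodels_ols(self, rng):
        y = rng.standard_normal(30)
        mods = pd.DataFrame(rng.standard_normal((30, 3)), columns=list("abc"))
        res = fit_level2(y, mods)
        X = sm.add_constant(np.asarray(mods - mods.mean(axis=0)))
        smres = sm.OLS(y, X).fit()
        assert np.allclose(res["b"], smres.params, atol=1e-10)
        assert np.allclose(res["se"], smres.bse, atol=1e-10)
        # single-df model comparison F equals the Wald t^2
        assert np.allclose(res["f"], smres.tvalues**2, rtol=1e-8)
        assert np.allclose(res["p"], smres.pvalues, atol=1e-12)

    def test_intercept_only_model(self, rng):
        y = rng.standard_normal(20) + 3
        res = fit_level2(y, None)
        assert len(res) == 1
        row = res.iloc[0]
        assert row["b"] == pytest.approx(y.mean())
        assert row["ss"] == pytest.approx(20 * y.mean() ** 2, rel=1e-10)
        assert row["df_den"] == 19

    def test_too_few_participants(self):
        with pytest.raises(ValueError, match="too few"):
            fit_level2(np.arange(5.0), None)


class TestFdr:
    @staticmethod
    def _brute_force_bh(p):
        """Textbook step-up: adj_i = min_{j>=i} ( n * p_(j) / j ), capped at 1."""
        p = np.asarray(p, dtype=float)
        n = len(p)
        order = np.argsort(p)
        adj = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            idx = order[rank - 1]
            running = min(running, n * p[idx] / rank)
            adj[idx] = running
        return adj

    def test_equal_p_fixed_point(self):
        p = pd.Series(0.01, index=[f"e{i}" for i in range(31)])
        out = fdr_adjust(p, a_priori=None)
        assert np.allclose(out, 0.01)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            raw = rng.uniform(0, 1, size=31)
            p = pd.Series(raw, index=[f"e{i}" for i in range(31)])
            out = fdr_adjust(p, a_priori=None)
            assert np.allclose(out, self._brute_force_bh(raw), atol=1e-12)

    def test_stepup_toy(self):
        p = pd.Series([0.01, 0.02, 0.03, 0.04], index=list("abcd"))
        out = fdr_adjust(p, a_priori=None)
        assert np.allclose(out, self._brute_force_bh(p.to_numpy()))

    def test_single_test_unchanged(self):
        out = fdr_adjust(pd.Series([0.3], index=["e1"]), a_priori=None)
        assert out.iloc[0] == pytest.approx(0.3)

    def test_a_priori_channel_reported_raw(self):
        idx = ["Oz"] + [f"e{i}" for i in range(31)]
        p = pd.Series([0.04] + [0.5] * 31, index=idx)
        out = fdr_adjust(p, a_priori="Oz")
        assert out["Oz"] == 0.04  # unadjusted
        assert np.allclose(out.drop("Oz"), 0.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            fdr_adjust(pd.Series([0.5, 1.5], index=["a", "b"]), a_priori=None)


class TestBootstrapCorr:
    def test_perfect_positive(self, rng):
        x = rng.standard_normal(20)
        out = bootstrap_corr(x, 2 * x + 1, seed=0)
        assert out.r == pytest.approx(1.0)
        assert out.ci_lo == pytest.approx(1.0)
        assert out.ci_hi == pytest.approx(1.0)
        assert out.p == 0.0

    def test_perfect_negative(self, rng):
        x = rng.standard_normal(20)
        assert bootstrap_corr(x, -x, seed=0).r == pytest.approx(-1.0)

    def test_ci_brackets_r_and_tightens(self, rng):
        x = rng.standard_normal(20)
        y = 0.6 * x + rng.standard_normal(20)
        out = bootstrap_corr(x, y, n_boot=4000, seed=7)
        assert out.ci_lo < out.r < out.ci_hi
        small = bootstrap_corr(x, y, n_boot=200, seed=7)
        # more resamples should not widen the percentile interval materially
        assert (out.ci_hi - out.ci_lo) < (small.ci_hi - small.ci_lo) * 1.25

    def test_p_matches_pearsonr(self, rng):
        x = rng.standard_normal(25)
        y = 0.4 * x + rng.standard_normal(25)
        out = bootstrap_corr(x, y, seed=1)
        r_sp, p_sp = scipy.stats.pearsonr(x, y)
        assert out.r == pytest.approx(r_sp)
        assert out.p == pytest.approx(p_sp, rel=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            bootstrap_corr(np.ones(10), np.arange(10.0))

    def test_seed_reproducibility(self, rng):
        x, y = rng.standard_normal((2, 15))
        a = bootstrap_corr(x, y, seed=5)
        b = bootstrap_corr(x, y, seed=5)
        assert (a.ci_lo, a.ci_hi) == (b.ci_lo, b.ci_hi)


def _noise_free_table(slope=2.05, base=-23.76, n=12):
    rows = []
    for pid in range(1, n + 1):
        for c in CODES:
            rows.append(
                {"participant": pid, "electrode": "Oz", "brightness": c,
                 "psd_db": base + slope * c}
            )
    return pd.DataFrame(rows)


class TestTwoStage:
    def test_noise_free_slope_recovered_exactly(self):
        """With a noise-free planted dB/step slope, the level-2 intercept of
        the slope model equals the planted slope exactly."""
        res = TwoStageMLM(_noise_free_table(), response="psd_db").fit()
        row = res.coef("Oz", "Brightness", "Intercept")
        assert row["b"] == pytest.approx(2.05, abs=1e-12)
        assert res.coef("Oz", "Intercept", "Intercept")["b"] == pytest.approx(-23.76)

    def test_emitted_rows_satisfy_table_identities(self, rng):
        data = _noise_free_table()
        data["psd_db"] += rng.standard_normal(len(data))
        res = TwoStageMLM(data, response="psd_db").fit()
        t2 = res.level2
        assert np.allclose(t2["f"], t2["ss"] / t2["mse"], rtol=1e-10)
        assert np.allclose(
            t2["eta_p2"], t2["ss"] / (t2["ss"] + t2["df_den"] * t2["mse"]), rtol=1e-10
        )
        tq = scipy.stats.t.ppf(0.975, t2["df_den"])
        assert np.allclose(t2["ci_lo"], t2["b"] - tq * t2["se"], rtol=1e-10)

    def test_df_den_conventions(self, rng):
        # stimulation-response analysis: df_den = N - 1
        res1 = TwoStageMLM(_noise_free_table(n=20), response="psd_db").fit()
        assert (res1.level2["df_den"] == 19).all()
        # moderation analysis with 3 moderators: df_den = N - 4
        from ssvepmod.synth import COVARIATES, simulate_ratings_study

        _, long = simulate_ratings_study(seed=3)
        res2 = TwoStageMLM(
            long, response="unpleasantness", include_psd="psd_db",
            moderators=COVARIATES,
        ).fit()
        assert (res2.level2["df_den"] == 147 - 4).all()

    def test_missing_block_participant_excluded_with_log(self):
        data = _noise_free_table(n=8)
        data = data.drop(data[(data.participant == 3)].index[:4])  # 1 usable block
        res = TwoStageMLM(data, response="psd_db").fit()
        assert any("3/Oz" in line for line in res.log)
        assert (res.level2["df_den"] == 6).all()  # N=7 included

    def test_summary_contains_key_fields(self):
        res = TwoStageMLM(_noise_free_table(), response="psd_db").fit()
        text = res.summary("Oz")
        assert "Brightness" in text and "eta_p2" in text and "Oz" in text
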