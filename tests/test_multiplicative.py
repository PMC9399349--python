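"""Multiplicative family: ratio factors, ratio regression, exponential model."""

import numpy as np
import pandas as pd
import pytest

from dmyest import (
    ModelSpec,
    build_mic_grid,
    fit_m5,
    fit_m6,
    fit_m7,
    fit_m8,
    mcf_from_ratio_fit,
    mcf_m8,
    predict_multiplicative,
)
from dmyest.data_model import EmptyDataError, to_session_long
from dmyest.multiplicative import _no_intercept_ols


def _records(t_am, t_pm, x_am, x_pm, dim):
    n = len(t_am)
    return pd.DataFrame(
        {
            "cow_id": [f"C{i}" for i in range(n)],
            "herd_id": "H",
            "breed": "Holstein",
            "parity": 1,
            "lactation_month": 5,
            "dim": dim,
            "am_interval_h": t_am,
            "pm_interval_h": t_pm,
            "am_yield_kg": x_am,
            "pm_yield_kg": x_pm,
            "measured_session": ["AM", "PM"] * (n // 2) + ["AM"] * (n % 2),
        }
    )


def _even_split_records(n=60, seed=0):
    """x_AM = x_PM = y/2 exactly: every proportion is 0.5."""
    rng = np.random.default_rng(seed)
    t_am = rng.uniform(9.2, 14.8, n)
    y = rng.uniform(20, 40, n)
    return _records(t_am, 24 - t_am, y / 2, y / 2, rng.integers(50, 280, n))


class TestM5:
    def test_even_split_gives_factor_two_everywhere(self):
        fit, tab = fit_m5(_even_split_records(), build_mic_grid(9, 15, 1))
        np.testing.assert_allclose(tab.table["F"], 2.0, rtol=1e-9)

    def test_quadratic_proportions_recovered_exactly(self):
        # proportions lying exactly on a quadratic in the bin midpoint
        rng = np.random.default_rng(1)
        rows = []
        for centre in (10.5, 11.5, 12.5, 13.5, 14.5):
            p = 0.9 - 0.05 * centre + 0.001 * centre**2
            for _ in range(4):
                y = rng.uniform(25, 35)
                rows.append((centre, 24 - centre, p * y, (1 - p) * y, 150))
        t_am, t_pm, x_am, x_pm, dim = map(np.array, zip(*rows))
        df = _records(t_am, t_pm, x_am, x_pm, dim)
        fit, tab = fit_m5(df, build_mic_grid(10, 15, 1))
        p = fit.params["AM"]
        assert p["alpha"] == pytest.approx(0.9, abs=1e-8)
        assert p["beta"] == pytest.approx(-0.05, abs=1e-8)
        assert p["beta2"] == pytest.approx(0.001, abs=1e-9)

    def test_factors_match_polyfit_oracle(self):
        rng = np.random.default_rng(2)
        rows = []
        props = {10.5: 0.54, 11.5: 0.52, 12.5: 0.50, 13.5: 0.48, 14.5: 0.46}
        for centre, p in props.items():
            for _ in range(5):
                y = rng.uniform(22, 38)
                jitter = rng.normal(0, 0.01)
                rows.append(
                    (centre + rng.uniform(-0.4, 0.4), 24 - centre,
                     (p + jitter) * y, (1 - p - jitter) * y, 150)
                )
        t_am, t_pm, x_am, x_pm, dim = map(np.array, zip(*rows))
        df = _records(t_am, t_pm, x_am, x_pm, dim)
        grid = build_mic_grid(10, 15, 1)
        fit, tab = fit_m5(df, grid)
        # independent oracle: bulk sums per bin + numpy quadratic fit
        long = to_session_long(df)
        am = long[long["session"] == "AM"]
        k = np.digitize(am["t"], grid.edges) - 1
        tbar, prop = [], []
        for kk in sorted(set(k)):
            m = k == kk
            tbar.append(grid.midpoints[kk])
            prop.append(am["x"][m].sum() / am["y"][m].sum())
        c = np.polyfit(tbar, prop, 2)
        expected = 1.0 / np.polyval(c, grid.midpoints)
        got = tab.table.query("session == 'AM'").sort_values("bin_lo")["F"]
        np.testing.assert_allclose(got, expected, rtol=1e-9)

    def test_too_few_bins_raises(self):
        df = _records([12.2, 12.4], [11.8, 11.6], [15.0, 16.0], [15.0, 14.0],
                      [100, 120])
        with pytest.raises(EmptyDataError):
            fit_m5(df, build_mic_grid(9, 15, 1))


class TestM6:
    def test_proportional_data_gives_factor_two(self):
        fit, tab = fit_m6(_even_split_records(), build_mic_grid(9, 15, 1))
        np.testing.assert_allclose(tab.table["F"], 2.0, rtol=1e-9)
        np.testing.assert_allclose(
            [fit.params[s]["beta"] for s in ("AM", "PM")], 0.0, atol=1e-10
        )

    def test_no_intercept_slope_closed_form(self):
        # single bin, gamma suppressed: b = (10*21 + 12*25) / (10² + 12²)
        b, g = _no_intercept_ols(
            np.array([10.0, 12.0]), np.array([21.0, 25.0]),
            np.array([0.0, 0.0]), with_dim=True,
        )
        assert b == pytest.approx(510.0 / 244.0)
        assert g == 0.0

    def test_per_bin_slopes_match_oracle(self, holstein_small, grid):
        fit, _ = fit_m6(holstein_small, grid)
        long = to_session_long(holstein_small)
        am = long[long["session"] == "AM"]
        k = np.digitize(am["t"], grid.edges) - 1
        for _, row in fit.per_bin.query("session == 'AM'").iterrows():
            m = k == row["mic"]
            X = np.column_stack([am["x"][m], am["dim"][m] - 158.0])
            coef = np.linalg.lstsq(X, am["y"][m], rcond=None)[0]
            assert row["b"] == pytest.approx(coef[0], rel=1e-8)

    def test_gamma_applied_in_prediction(self):
        df = _even_split_records()
        grid = build_mic_grid(9, 15, 1)
        fit, tab = fit_m6(df, grid)
        tab.table["gamma"] = 0.1
        rec = df.head(1).copy()
        rec["measured_session"] = "AM"
        rec["dim"] = 258  # d - d0 = 100
        base = rec["am_yield_kg"].iloc[0]
        pred = predict_multiplicative(rec, fit, mcf_table=tab, grid=grid)
        assert pred.estimate[0] == pytest.approx(2.0 * base + 0.1 * 100, rel=1e-6)


class TestM7:
    def test_constant_ratio_recovered(self):
        df = _even_split_records()
        fit = fit_m7(df)
        for s in ("AM", "PM"):
            assert fit.params[s]["alpha"] == pytest.approx(0.5, abs=1e-10)
            assert fit.params[s]["beta"] == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_ratio_recovered(self):
        rng = np.random.default_rng(3)
        n = 40
        t_am = rng.uniform(10, 14, n)
        dim = rng.integers(50, 280, n)
        ratio = 0.068 + 0.037 * t_am / 12.0 + 1e-4 * (dim - 158)
        y = rng.uniform(25, 35, n)
        df = _records(t_am, 24 - t_am, ratio * y, (1 - ratio) * y, dim)
        fit = fit_m7(df, ModelSpec("M7", "direct", session_scope="separate"))
        p = fit.params["AM"]
        assert p["alpha"] == pytest.approx(0.068, abs=1e-9)
        assert p["beta"] == pytest.approx(0.037 / 12.0, abs=1e-10)
        assert p["gamma"] == pytest.approx(1e-4, abs=1e-12)

    def test_coefficients_match_normal_equations_oracle(self):
        df = _records(
            [12.1, 11.4, 13.2, 12.8, 10.9], [11.9, 12.6, 10.8, 11.2, 13.1],
            [16.0, 14.5, 17.1, 15.2, 13.9], [15.1, 14.9, 13.8, 14.6, 15.5],
            [100, 150, 200, 250, 120],
        )
        fit = fit_m7(df, ModelSpec("M7", "direct", session_scope="separate"))
        long = to_session_long(df)
        am = long[long["session"] == "AM"]
        X = np.column_stack([np.ones(5), am["t"], am["dim"] - 158.0])
        beta_hat = np.linalg.solve(
            X.T @ X, X.T @ (am["x"] / am["y"]).to_numpy()
        )
        p = fit.params["AM"]
        np.testing.assert_allclose(
            [p["alpha"], p["beta"], p["gamma"]], beta_hat, atol=1e-9
        )

    def test_zero_daily_yield_excluded_and_counted(self):
        df = _even_split_records(10)
        df.loc[0, ["am_yield_kg", "pm_yield_kg"]] = 0.0
        fit = fit_m7(df)
        assert fit.n_excluded == 2  # both session rows of the record

    def test_mcf_reciprocal_of_line(self):
        df = _even_split_records()
        grid = build_mic_grid(9, 15, 1)
        fit = fit_m7(df)
        fit.params["AM"].update(alpha=0.05, beta=0.0375)
        fit.params["PM"].update(alpha=0.05, beta=0.0375)
        tab = mcf_from_ratio_fit(fit, grid)
        am = tab.table.query("session == 'AM'").set_index("midpoint")
        assert am.loc[12.5, "F"] == pytest.approx(1.0 / (0.05 + 0.0375 * 12.5))
        expected = 1.0 / (0.05 + 0.0375 * grid.midpoints)
        np.testing.assert_allclose(am["F"].to_numpy(), expected)

    def test_nonpositive_denominator_names_bin(self):
        df = _even_split_records()
        fit = fit_m7(df)
        fit.params["AM"].update(alpha=0.5, beta=-0.05)  # line crosses zero at 10 h
        with pytest.raises(ValueError, match="midpoint"):
            mcf_from_ratio_fit(fit, build_mic_grid(9, 15, 1))


class TestM8:
    def _exponential_records(self, n=50, alpha=1.86, beta=-0.065, gamma=-2e-4,
                             b=0.86, seed=4):
        rng = np.random.default_rng(seed)
        t_am = rng.uniform(10, 14, n)
        x_am = rng.uniform(12, 20, n)
        dim = rng.integers(50, 280, n)
        y = x_am**b * np.exp(alpha + beta * t_am + gamma * (dim - 158))
        x_pm = np.maximum(y - x_am, 0.1)
        return _records(t_am, 24 - t_am, x_am, x_pm, dim), (alpha, beta, gamma, b)

    def test_noise_free_exact_recovery(self):
        df, (alpha, beta, gamma, b) = self._exponential_records()
        fit = fit_m8(df, ModelSpec("M8", "direct", session_scope="separate"))
        p = fit.params["AM"]
        assert p["alpha"] == pytest.approx(alpha, abs=1e-8)
        assert p["beta"] == pytest.approx(beta, abs=1e-9)
        assert p["gamma"] == pytest.approx(gamma, abs=1e-10)
        assert p["b"] == pytest.approx(b, abs=1e-9)

    def test_doubling_special_case(self):
        # b=1, alpha=log 2, beta=gamma=0 reduces to y = 2x
        df, _ = self._exponential_records(alpha=np.log(2.0), beta=0.0,
                                          gamma=0.0, b=1.0)
        fit = fit_m8(df, ModelSpec("M8", "direct", session_scope="separate"))
        p = fit.params["AM"]
        assert p["alpha"] == pytest.approx(np.log(2.0), abs=1e-8)
        assert p["b"] == pytest.approx(1.0, abs=1e-8)

    def test_coefficients_match_log_scale_oracle(self):
        df = _records(
            [12.1, 11.4, 13.2, 12.8, 10.9, 11.7],
            [11.9, 12.6, 10.8, 11.2, 13.1, 12.3],
            [16.0, 14.5, 17.1, 15.2, 13.9, 15.8],
            [15.1, 14.9, 13.8, 14.6, 15.5, 14.2],
            [100, 150, 200, 250, 120, 180],
        )
        fit = fit_m8(df, ModelSpec("M8", "direct", session_scope="separate"))
        long = to_session_long(df)
        am = long[long["session"] == "AM"]
        X = np.column_stack(
            [np.ones(6), am["t"], am["dim"] - 158.0, np.log(am["x"])]
        )
        beta_hat = np.linalg.solve(X.T @ X, X.T @ np.log(am["y"].to_numpy()))
        p = fit.params["AM"]
        np.testing.assert_allclose(
            [p["alpha"], p["beta"], p["gamma"], p["b"]], beta_hat, atol=1e-9
        )

    def test_direct_prediction_reproduces_noise_free_yield(self):
        df, _ = self._exponential_records()
        df["measured_session"] = "AM"
        fit = fit_m8(df, ModelSpec("M8", "direct", session_scope="separate"))
        pred = predict_multiplicative(df, fit)
        y = (df["am_yield_kg"] + df["pm_yield_kg"]).to_numpy()
        np.testing.assert_allclose(pred.estimate, y, rtol=1e-8)


class TestMCFm8:
    def test_rho_one_when_variances_zero(self, holstein_small, grid):
        fit = fit_m8(holstein_small)
        df = _records([12.3] * 4, [11.7] * 4, [16.0] * 4, [15.0] * 4, [150] * 4)
        tab = mcf_m8(fit, build_mic_grid(11, 13, 1), df)
        np.testing.assert_allclose(tab.table["rho"], 1.0, atol=1e-12)

    def test_factor_formula_single_expression_oracle(self, holstein_small):
        fit = fit_m8(holstein_small)
        b_hat, a_hat, beta_hat = 0.9, 1.8, -0.06
        for s in ("AM", "PM"):
            fit.params[s].update(alpha=a_hat, beta=beta_hat, b=b_hat, gamma=0.0)
        # toy bin moments: Ex=16, Vx=4, Ey=32, Vy=16 at midpoint 12
        rng = np.random.default_rng(5)
        x = np.array([14.0, 18.0, 16.0, 16.0])
        x = 16.0 + (x - x.mean()) * np.sqrt(4.0 / x.var(ddof=1))
        y = np.array([28.0, 36.0, 32.0, 32.0])
        y = 32.0 + (y - y.mean()) * np.sqrt(16.0 / y.var(ddof=1))
        df = _records([12.0] * 4, [12.0] * 4, x, y - x, [158] * 4)
        tab = mcf_m8(fit, build_mic_grid(11.5, 12.5, 1), df)
        rho = np.exp(0.5 * (16.0 / 32.0**2 - b_hat * 4.0 / 16.0**2))
        expected = 16.0 ** (b_hat - 1.0) * rho * np.exp(a_hat + beta_hat * 12.0)
        am = tab.table.query("session == 'AM'")
        assert am["rho"].iloc[0] == pytest.approx(rho, rel=1e-9)
        assert am["F"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_doubling_parameters_give_factor_two(self, holstein_small):
        fit = fit_m8(holstein_small)
        for s in ("AM", "PM"):
            fit.params[s].update(alpha=np.log(2.0), beta=0.0, b=1.0, gamma=0.0)
        df = _records([12.3] * 4, [11.7] * 4, [16.0] * 4, [15.0] * 4, [150] * 4)
        tab = mcf_m8(fit, build_mic_grid(11, 13, 1), df)
        np.testing.assert_allclose(tab.table["F"], 2.0, rtol=1e-12)

    def test_single_record_bins_borrow_moments_flagged(self, holstein_small, grid):
        fit = fit_m8(holstein_small)
        tab = mcf_m8(fit, build_mic_grid(0.5, 23.5, 1), holstein_small)
        assert tab.table["imputed_flag"].any()
        assert (tab.table["F"] > 0).all()

    def test_m8b_matches_m8a_at_bin_mean_conditions(self, holstein_small):
        """Factor and direct estimates coincide at x=E(x), t=t̄, d=d0, ρ=1."""
        fit = fit_m8(holstein_small)
        grid = build_mic_grid(11.5, 12.5, 1)
        # degenerate moments: identical records in the only bin
        df = _records([12.0] * 3, [12.0] * 3, [16.0] * 3, [15.5] * 3, [158] * 3)
        tab = mcf_m8(fit, grid, df)
        rec = df.head(1).copy()
        rec["measured_session"] = "AM"
        direct = predict_multiplicative(rec, fit)
        spec_b = ModelSpec("M8", "factor")
        fit_b = fit_m8(holstein_small, spec_b)
        for s in ("AM", "PM"):
            fit_b.params[s] = dict(fit.params[s])
        factor = predict_multiplicative(rec, fit_b, mcf_table=tab, grid=grid)
        assert factor.estimate[0] == pytest.approx(direct.estimate[0], rel=1e-9)


class TestFactorStructure:
    def test_symmetric_data_factors_near_two_at_12h(self, symmetric_large, grid):
        k12 = grid.containing(12.0)
        _, m5 = fit_m5(symmetric_large, grid)
        _, m6 = fit_m6(symmetric_large, grid)
        m7 = mcf_from_ratio_fit(fit_m7(symmetric_large), grid, symmetric_large)
        m8 = mcf_m8(fit_m8(symmetric_large), grid, symmetric_large)
        for tab in (m5, m6, m7, m8):
            for s in ("AM", "PM"):
                assert tab.factor(s, k12) == pytest.approx(2.0, abs=0.05)

    def test_am_factor_decreases_with_interval(self, holstein_mid, grid):
        tab = mcf_from_ratio_fit(fit_m7(holstein_mid), grid, holstein_mid)
        am = tab.table.query("session == 'AM'").sort_values("midpoint")
        mid = am[(am["midpoint"] >= 10) & (am["midpoint"] <= 14)]
        assert mid["F"].is_monotonic_decreasing
        k12 = grid.containing(12.0)
        k10 = grid.containing(10.0)
        assert tab.factor("AM", k10) > tab.factor("AM", k12)

    def test_all_factors_positive_and_predictions_finite(self, holstein_mid, grid):
        for fit_fn in (fit_m5, fit_m6):
            _, tab = fit_fn(holstein_mid, grid)
            assert (tab.table["F"] > 0).all()
        fit = fit_m8(holstein_mid)
        tab = mcf_m8(fit, grid, holstein_mid)
        pred = predict_multiplicative(
            holstein_mid, fit_m8(holstein_mid, ModelSpec("M8", "factor")),
            mcf_table=tab, grid=grid,
        )
        assert np.isfinite(pred.estimate).all()
        assert (pred.estimate >= 0).all()

    def test_m8_parameter_recovery_within_three_ses(self):
        """Bias of (β, γ, b) within 3 empirical SEs over 20 replicates."""
        from dmyest import generate_exponential_model_data

        truth = {"beta": -0.065, "gamma": -2e-4, "b": 0.86}
        rng = np.random.default_rng(99)
        draws = {k: [] for k in truth}
        for _ in range(20):
            df = generate_exponential_model_data(10_000, rng)
            fit = fit_m8(df, ModelSpec("M8", "direct", session_scope="separate"))
            for k in truth:
                draws[k].append(fit.params["AM"][k])
        for k, tv in truth.items():
            est = np.asarray(draws[k])
            se = est.std(ddof=1) / np.sqrt(len(est))
            assert abs(est.mean() - tv) <= 3 * se
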