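"""Windowed mixing-model inversion: windows, identifiability, bootstrap."""

import warnings

import numpy as np
import pandas as pd
import pytest

from paddyiso.partition import (
    DEFAULT_BOUNDS,
    bootstrap_uncertainty,
    combine_heights_and_models,
    invert_window,
    make_windows,
    partition_season,
    weighted_source,
)


def _window(kp, deltaP, deltaNP, eps, noise=0.0, seed=0, se=None):
    kp = np.asarray(kp, dtype=float)
    rng = np.random.default_rng(seed)
    mix = deltaP * kp + deltaNP * (1 - kp) + eps + noise * rng.standard_normal(kp.size)
    df = pd.DataFrame({"kp": kp, "delta13c_mix_permil": mix})
    if se is not None:
        df["intercept_se_permil"] = se
    return df


class TestWindows:
    def test_first_window_starts_three_days_after_transplant(self):
        dates = pd.date_range("2018-06-24", periods=108)  # DOY 175 transplant
        win = make_windows(dates, pd.Timestamp("2018-06-24"))
        assert win[0][0].dayofyear == 178
        assert (win[0][1] - win[0][0]).days == 14

    def test_thirty_days_gives_two_windows(self):
        dates = pd.date_range("2018-07-01", periods=30)
        win = make_windows(dates, dates[0], start_offset_d=0)
        assert len(win) == 2

    def test_trailing_partial_window_rule(self):
        dates = pd.date_range("2018-07-01", periods=20)
        win = make_windows(dates, dates[0], start_offset_d=0)
        assert len(win) == 2 and (win[1][1] - win[1][0]).days + 1 == 5
        short = make_windows(pd.date_range("2018-07-01", periods=18), dates[0], start_offset_d=0)
        assert len(short) == 1


class TestInversion:
    def test_identifiable_combinations_recovered_exactly(self):
        """With >= 3 distinct kp the data pin the end-member separation and
        the mixture level; the joint (deltaP, deltaNP, eps) retain the
        structural flat direction and are reported at the feasible
        segment's center."""
        r = invert_window(_window([0.3, 0.5, 0.7, 0.4, 0.6], -70.0, -50.0, 1.0))
        assert r["status"] == "ok" and not r["identifiability_flag"]
        assert r["deltaP_permil"] - r["deltaNP_permil"] == pytest.approx(-20.0, abs=1e-6)
        assert r["deltaNP_permil"] + r["epsilon_permil"] == pytest.approx(-49.0, abs=1e-6)
        assert r["rmse_permil"] < 1e-9

    def test_gauge_shifted_truths_give_identical_estimates(self):
        # truths differing only along (+c, +c, -c) produce the same data,
        # hence identical reported estimates
        kp = [0.2, 0.35, 0.5, 0.65, 0.8]
        a = invert_window(_window(kp, -70.0, -50.0, 1.5))
        b = invert_window(_window(kp, -69.0, -49.0, 0.5))
        assert a["deltaP_permil"] == pytest.approx(b["deltaP_permil"], abs=1e-9)
        assert a["epsilon_permil"] == pytest.approx(b["epsilon_permil"], abs=1e-9)

    def test_constant_kp_raises_identifiability_flag(self):
        r = invert_window(_window(np.full(8, 0.6), -70.0, -50.0, 1.0))
        assert r["identifiability_flag"]
        # midpoint-of-feasible estimates still reproduce the mixture level
        level = 0.6 * r["deltaP_permil"] + 0.4 * r["deltaNP_permil"] + r["epsilon_permil"]
        assert level == pytest.approx(0.6 * -70 + 0.4 * -50 + 1.0, abs=1e-6)

    def test_too_few_days_skipped_with_reason(self):
        r = invert_window(_window([0.3, 0.7], -70.0, -50.0, 1.0))
        assert r["status"] == "too_few_days"

    def test_estimates_respect_bounds_under_noise(self):
        rng = np.random.default_rng(3)
        (lo, hi) = DEFAULT_BOUNDS
        for _ in range(50):
            kp = rng.uniform(0, 1, 10)
            r = invert_window(_window(kp, -72.0, -60.0, 0.5, noise=2.0, seed=rng.integers(1e6)))
            x = (r["deltaP_permil"], r["deltaNP_permil"], r["epsilon_permil"])
            assert all(l - 1e-9 <= v <= h + 1e-9 for v, l, h in zip(x, lo, hi))

    def test_matches_multistart_objective_oracle(self):
        """Exact convex solve agrees with an independent multi-start
        bounded local optimizer on the weighted objective."""
        from scipy.optimize import minimize

        rng = np.random.default_rng(4)
        for _ in range(10):
            kp = rng.uniform(0.1, 0.9, 12)
            df = _window(kp, -68.0, -58.0, 1.0, noise=1.0, seed=rng.integers(1e6))
            y = df.delta13c_mix_permil.to_numpy()

            def obj(x):
                pred = x[0] * kp + x[1] * (1 - kp) + x[2]
                return float(((y - pred) ** 2).sum())

            lo, hi = DEFAULT_BOUNDS
            best = np.inf
            for p in np.linspace(lo[0], hi[0], 3):
                for q in np.linspace(lo[1], hi[1], 3):
                    for e in np.linspace(lo[2], hi[2], 3):
                        res = minimize(
                            obj, [p, q, e], method="L-BFGS-B", bounds=list(zip(lo, hi))
                        )
                        best = min(best, res.fun)
            r = invert_window(df)
            assert len(df) * r["rmse_permil"] ** 2 == pytest.approx(best, rel=1e-6, abs=1e-9)


class TestSourceAndBootstrap:
    def test_weighted_source_limits(self):
        assert weighted_source(-70.0, -50.0, [1.0, 1.0]) == -70.0
        assert weighted_source(-70.0, -50.0, [0.5] * 4) == -60.0
        kp = np.linspace(0.4, 0.8, 15)
        direct = np.mean(-70.0 * kp + -50.0 * (1 - kp))
        assert weighted_source(-70.0, -50.0, kp) == pytest.approx(direct, rel=1e-14)

    def test_source_between_end_members(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            kp = rng.uniform(0, 1, 15)
            r = invert_window(_window(kp, -70.0, -55.0, 1.0, noise=1.0, seed=rng.integers(1e6)))
            s = weighted_source(r["deltaP_permil"], r["deltaNP_permil"], kp)
            assert (
                min(r["deltaP_permil"], r["deltaNP_permil"]) - 1e-9
                <= s
                <= max(r["deltaP_permil"], r["deltaNP_permil"]) + 1e-9
            )

    def test_bootstrap_deterministic_and_shrinks_with_noise(self):
        df_noisy = _window(np.linspace(0.2, 0.8, 15), -70.0, -55.0, 1.0, noise=0.5, seed=6)
        a = bootstrap_uncertainty(df_noisy, B=200, seed=9)
        b = bootstrap_uncertainty(df_noisy, B=200, seed=9)
        assert a == b
        df_clean = _window(np.linspace(0.2, 0.8, 15), -70.0, -55.0, 1.0)
        c = bootstrap_uncertainty(df_clean, B=200, seed=9)
        assert c["sd_source"] < 1e-9 < a["sd_source"]

    def test_bootstrap_sd_within_factor_two_of_analytic(self):
        """Day-resampling sd of the window source agrees with the
        closed-form weighted-regression noise propagation to a factor 2."""
        kp = np.linspace(0.2, 0.8, 15)
        noise = 0.5
        reps = [
            weighted_source(
                r["deltaP_permil"], r["deltaNP_permil"], kp
            )
            for r in (
                invert_window(_window(kp, -70.0, -55.0, 1.0, noise=noise, seed=s))
                for s in range(150)
            )
        ]
        mc_sd = float(np.std(reps, ddof=1))
        # analytic: the source is the mean fitted mixture (gauge shift is
        # deterministic), so var = noise^2 * 1'H1 / n^2 with H the hat
        # matrix of the regression span
        X = np.column_stack([kp, 1 - kp])
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        n = len(kp)
        analytic = noise * np.sqrt(float(np.ones(n) @ H @ np.ones(n))) / n
        assert 0.5 < mc_sd / analytic < 2.0

    def test_small_bootstrap_warns(self):
        with pytest.warns(UserWarning, match="B=10"):
            bootstrap_uncertainty(
                _window(np.linspace(0.2, 0.8, 8), -70.0, -55.0, 1.0), B=10, seed=0
            )


class TestSeasonAssembly:
    def test_combine_heights_simple_means(self):
        base = {
            "window_index": 0,
            "window_start": pd.Timestamp("2018-06-28"),
            "window_end": pd.Timestamp("2018-07-12"),
            "model_label": "IBIS",
            "status": "ok",
            "deltaNP_permil": -60.0,
            "epsilon_permil": 1.0,
            "delta_source_permil": -65.0,
            "mix_mean_permil": -64.0,
            "identifiability_flag": False,
            "sd_deltaP": 0.5,
            "sd_deltaNP": 0.5,
            "sd_source": 0.5,
        }
        rows = [
            {**base, "height_m": h, "deltaP_permil": d}
            for h, d in zip((0.5, 1.5, 3.0), (-66.0, -67.0, -68.0))
        ]
        out = combine_heights_and_models(pd.DataFrame(rows))
        assert len(out) == 1
        assert out.deltaP_permil.iloc[0] == pytest.approx(-67.0)
        assert out.n_heights.iloc[0] == 3

    def test_partition_season_consistency_with_truth(self, scenario_small, campaign_small):
        """Truth-level daily mix (+ noise-free) inverted per window
        reproduces the window source up to the epsilon gauge."""
        truth = campaign_small["truth"]
        daily = pd.DataFrame(
            {
                "date": truth.date,
                "height_m": 0.5,
                "delta13c_mix_permil": truth.true_delta_source_permil
                + scenario_small.epsilon_truth_permil,
            }
        )
        kp = pd.DataFrame(
            {"date": truth.date, "model_label": "IBIS", "kp": truth.true_kp}
        )
        w = partition_season(daily, kp, truth.date.iloc[0], bootstrap_B=0)
        ok = w[w.status == "ok"]
        assert len(ok) >= 2
        truth_idx = truth.set_index(pd.to_datetime(truth.date))
        for _, row in ok.iterrows():
            sub = truth_idx.loc[row.window_start : row.window_end]
            gauge = scenario_small.epsilon_truth_permil - row.epsilon_permil
            assert row.delta_source_permil == pytest.approx(
                sub.true_delta_source_permil.mean() + gauge, abs=0.35
            )
            # source minus window-mean mix equals minus the estimated eps
            assert row.delta_source_permil - row.mix_mean_permil == pytest.approx(
                -row.epsilon_permil, abs=0.35
            )
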