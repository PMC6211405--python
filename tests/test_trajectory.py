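import numpy as np
import pytest

import denphen
from denphen.io import LagWindowSet
from denphen.trajectory import (
    TemperatureTrajectoryModel,
    snow_trajectory_summary,
)


def make_windows(values, park_ids, years=None, lags=None, variable="temperature_c",
                 kind="first_exit"):
    values = np.asarray(values, float)
    lags = np.asarray(lags if lags is not None else
                      np.arange(-(values.shape[1] // 2), values.shape[1] // 2 + 1))
    years = np.asarray(years if years is not None else np.arange(values.shape[0]))
    return LagWindowSet(event_kind=kind, variable=variable, lags=lags,
                        park_ids=np.asarray(park_ids), years=years,
                        values=values, mask=~np.isnan(values))


def dense_oracle_w_mean(windows, h, grid):
    """Independent dense joint-Gaussian conditioning for E[w | data].

    Builds the full covariance over every observed (park, window, lag)
    value directly from the model equations and solves once.
    """
    rows, cols = np.where(windows.mask)
    t = grid[cols]
    y = windows.values[rows, cols]
    parks = sorted(set(windows.park_ids))
    pidx = np.array([parks.index(windows.park_ids[r]) for r in rows])
    d = t[:, None] - t[None, :]
    k1 = h["sd1"] ** 2 * np.exp(-0.5 * (d / h["ls1"]) ** 2)
    k2 = h["sd2"] ** 2 * np.exp(-0.5 * (d / h["ls2"]) ** 2)
    same_park = pidx[:, None] == pidx[None, :]
    same_win = rows[:, None] == rows[None, :]
    sd3 = np.array([h["sd3"][parks.index(windows.park_ids[r])] for r in rows])
    cov = (k1 + (k2 + h["tau"] ** 2) * same_park
           + same_win * np.outer(sd3, sd3) * np.exp(-np.abs(d) / h["range3"]))
    dg = grid[:, None] - t[None, :]
    cross = h["sd1"] ** 2 * np.exp(-0.5 * (dg / h["ls1"]) ** 2)
    return h["mu"] + cross @ np.linalg.solve(cov, y - h["mu"])


FIXED = dict(sd1=2.0, ls1=8.0, sd2=1.0, ls2=6.0, tau=0.5, range3=3.0, mu=-1.0)


class TestOracleEquivalence:
    def build(self, n_parks, n_years, n_lags, seed=0):
        rng = np.random.default_rng(seed)
        vals = rng.normal(-1.0, 2.0, (n_parks * n_years, n_lags))
        parks = np.repeat([f"pk{i}" for i in range(n_parks)], n_years)
        lags = np.arange(n_lags) - n_lags // 2
        return make_windows(vals, parks, years=np.tile(np.arange(n_years), n_parks),
                            lags=lags)

    def test_structured_path_matches_dense_conditioning(self):
        w = self.build(2, 3, 11)
        model = TemperatureTrajectoryModel(w)
        hp = dict(FIXED, sd3=np.array([1.5, 2.5]))
        fit = model.fit(fixed_hyperparameters=hp, n_func_draws_per_hyper=0)
        h = model._unpack(model.pack(**hp))
        expected = dense_oracle_w_mean(w, h, model.grid)
        assert np.max(np.abs(fit.w_mean - expected)) < 1e-6

    def test_masked_dense_path_matches_oracle(self):
        w = self.build(3, 2, 9, seed=1)
        w.values[0, 2] = np.nan
        w.values[4, 7] = np.nan
        w.mask = ~np.isnan(w.values)
        model = TemperatureTrajectoryModel(w)
        assert not model._complete
        hp = dict(FIXED, sd3=np.array([1.0, 2.0, 1.2]))
        fit = model.fit(fixed_hyperparameters=hp, n_func_draws_per_hyper=0)
        h = model._unpack(model.pack(**hp))
        expected = dense_oracle_w_mean(w, h, model.grid)
        assert np.max(np.abs(fit.w_mean - expected)) < 1e-6

    def test_structured_and_dense_loglik_agree(self):
        w = self.build(2, 4, 7, seed=2)
        model_s = TemperatureTrajectoryModel(w)
        # force the dense path on identical data
        w2 = self.build(2, 4, 7, seed=2)
        model_d = TemperatureTrajectoryModel(w2)
        model_d.__init__(w2)  # rebuild
        model_d._complete = False
        rows, cols = np.where(w2.mask)
        model_d._obs_y = w2.values[rows, cols]
        model_d._obs_t = model_d.grid[cols]
        model_d._obs_window = rows
        model_d._obs_park = np.array(
            [model_d.parks.index(w2.park_ids[r]) for r in rows])
        theta = model_s.pack(**dict(FIXED, sd3=np.array([1.5, 2.5])))
        assert model_s.loglike(theta) == pytest.approx(model_d.loglike(theta), abs=1e-7)


class TestDegenerateAndPartition:
    def test_identical_parks_recover_common_trajectory(self):
        lags = np.arange(-5, 6)
        traj = -1.0 + 0.3 * lags
        vals = np.tile(traj, (6, 1))
        w = make_windows(vals, np.repeat(["a", "b"], 3), lags=lags)
        model = TemperatureTrajectoryModel(w)
        fit = model.fit(fixed_hyperparameters=dict(
            sd1=2.0, ls1=5.0, sd2=1e-3, ls2=5.0, tau=1e-3, range3=3.0,
            sd3=np.array([0.05, 0.05]), mu=0.0))
        post_sd = np.sqrt(np.mean(fit.w_cov_diag_per_hyper, axis=0))
        for i in range(2):
            assert np.all(np.abs(fit.u_mean[i] - traj) <= 2 * post_sd + 1e-3)

    def test_partition_identical_noiseless_trajectories(self):
        lags = np.arange(-10, 11)
        traj = 3.0 * np.sin(lags / 4.0)
        w = make_windows(np.tile(traj, (8, 1)), np.repeat(["a", "b"], 4), lags=lags)
        fit = TemperatureTrajectoryModel(w).fit(fixed_hyperparameters=dict(
            sd1=3.0, ls1=4.0, sd2=0.01, ls2=4.0, tau=0.01, range3=3.0,
            sd3=np.array([0.05, 0.05]), mu=0.0))
        part = fit.variance_partition()
        assert part["shared_pct"] == pytest.approx(100.0, abs=2.0)
        assert part["park_additional_pct"] == pytest.approx(0.0, abs=1.0)

    def test_partition_pure_white_noise(self):
        rng = np.random.default_rng(5)
        lags = np.arange(-10, 11)
        w = make_windows(rng.normal(0, 2, (20, 21)),
                         np.repeat(["a", "b"], 10), lags=lags)
        fit = TemperatureTrajectoryModel(w).fit(fixed_hyperparameters=dict(
            sd1=0.3, ls1=8.0, sd2=0.2, ls2=8.0, tau=0.1, range3=1.0,
            sd3=np.array([2.0, 2.0]), mu=0.0))
        part = fit.variance_partition()
        assert part["shared_pct"] < 10.0
        assert part["idiosyncratic_pct"] > 80.0

    def test_partition_components_sum_to_100(self):
        rng = np.random.default_rng(6)
        lags = np.arange(-10, 11)
        w = make_windows(rng.normal(0, 2, (12, 21)),
                         np.repeat(["a", "b", "c"], 4), lags=lags)
        fit = TemperatureTrajectoryModel(w).fit(fixed_hyperparameters=dict(
            sd1=1.0, ls1=8.0, sd2=0.5, ls2=8.0, tau=0.3, range3=2.0,
            sd3=np.array([1.0, 1.5, 2.0]), mu=0.0))
        for per_draw in (False, True):
            part = fit.variance_partition(per_draw=per_draw)
            total = (part["shared_pct"] + part["park_additional_pct"]
                     + part["idiosyncratic_pct"])
            assert total == pytest.approx(100.0, abs=0.1)

    def test_zero_variance_partition_errors(self):
        lags = np.arange(-3, 4)
        w = make_windows(np.full((4, 7), 2.0), np.repeat(["a", "b"], 2), lags=lags)
        fit = TemperatureTrajectoryModel(w).fit(fixed_hyperparameters=dict(
            sd1=1.0, ls1=5.0, sd2=0.5, ls2=5.0, tau=0.1, range3=2.0,
            sd3=np.array([1.0, 1.0]), mu=2.0))
        with pytest.raises(ValueError, match="zero total variance"):
            fit.variance_partition()


class TestPosteriorContraction:
    def test_doubling_years_roughly_halves_posterior_variance(self):
        # with the smooth-level variances small, w's posterior variance is
        # noise-dominated and should scale ~ 1/n_years
        rng = np.random.default_rng(9)
        lags = np.arange(-8, 9)
        hp = dict(sd1=2.0, ls1=6.0, sd2=0.05, ls2=6.0, tau=0.02, range3=3.0, mu=0.0)

        def post_var(n_years):
            vals = rng.normal(0, 2, (2 * n_years, lags.size))
            w = make_windows(vals, np.repeat(["a", "b"], n_years), lags=lags)
            fit = TemperatureTrajectoryModel(w).fit(
                fixed_hyperparameters=dict(hp, sd3=np.array([2.0, 2.0])),
                n_func_draws_per_hyper=0)
            return np.mean(fit.w_cov_diag_per_hyper)

        ratio = post_var(16) / post_var(8)
        assert 0.4 <= ratio <= 0.65


class TestEventDaySummary:
    def fit_constant(self, c):
        lags = np.arange(-5, 6)
        w = make_windows(np.full((4, 11), c) + 1e-6 * np.arange(11),
                         np.repeat(["a", "b"], 2), lags=lags)
        return TemperatureTrajectoryModel(w).fit(fixed_hyperparameters=dict(
            sd1=5.0, ls1=10.0, sd2=0.01, ls2=5.0, tau=0.01, range3=2.0,
            sd3=np.array([0.05, 0.05]), mu=c))

    def test_constant_trajectory_value_and_zero_slope(self):
        fit = self.fit_constant(-1.8)
        s = fit.event_day_summary()
        assert s["value_at_event_day"] == pytest.approx(-1.8, abs=0.05)
        assert s["slope_per_day"] == pytest.approx(0.0, abs=0.01)
        assert s["predictive_sd"] >= s["posterior_sd"]

    def test_ramp_slope_recovered(self):
        lags = np.arange(-10, 11)
        traj = 0.27 * lags
        w = make_windows(np.tile(traj, (6, 1)), np.repeat(["a", "b"], 3), lags=lags)
        fit = TemperatureTrajectoryModel(w).fit(fixed_hyperparameters=dict(
            sd1=4.0, ls1=8.0, sd2=0.01, ls2=5.0, tau=0.01, range3=2.0,
            sd3=np.array([0.05, 0.05]), mu=0.0))
        assert fit.event_day_summary()["slope_per_day"] == pytest.approx(0.27, abs=0.02)


class TestValidation:
    def test_single_park_refused(self):
        w = make_windows(np.zeros((3, 5)), ["a", "a", "a"], lags=np.arange(-2, 3))
        with pytest.raises(ValueError, match="two parks"):
            TemperatureTrajectoryModel(w)

    def test_single_window_refused(self):
        w = make_windows(np.zeros((1, 5)), ["a"], lags=np.arange(-2, 3))
        with pytest.raises(ValueError, match="two park-year windows"):
            TemperatureTrajectoryModel(w)

    def test_quantiles_monotone(self):
        rng = np.random.default_rng(3)
        lags = np.arange(-5, 6)
        w = make_windows(rng.normal(0, 1, (6, 11)),
                         np.repeat(["a", "b"], 3), lags=lags)
        fit = TemperatureTrajectoryModel(w).fit(fixed_hyperparameters=dict(
            sd1=1.0, ls1=5.0, sd2=0.5, ls2=5.0, tau=0.2, range3=2.0,
            sd3=np.array([1.0, 1.0]), mu=0.0))
        q = fit.w_quantiles()
        assert (q["q5"] <= q["q50"]).all() and (q["q50"] <= q["q95"]).all()


class TestSnowSummary:
    def test_single_park_year_raw_equals_window_and_loess_linear_exact(self):
        lags = np.arange(-30, 31)
        line = 10.0 + 0.25 * lags  # positive everywhere: clipping inert
        w = make_windows(line[None, :], ["a"], lags=lags, variable="snow_cm")
        s = snow_trajectory_summary(w, loess_span=0.3)
        assert np.array_equal(s.raw_mean[0], line)
        assert np.max(np.abs(s.smoothed[0] - line)) < 1e-6
        assert s.low_support_parks == ["a"]
        assert s.event_day_summary()["slope_per_day"] == pytest.approx(0.25, abs=1e-6)

    def test_global_mean_is_park_average(self):
        lags = np.arange(-5, 6)
        vals = np.vstack([np.full((3, 11), 10.0), np.full((3, 11), 20.0)])
        w = make_windows(vals, np.repeat(["a", "b"], 3), lags=lags,
                         variable="snow_cm")
        s = snow_trajectory_summary(w)
        assert np.allclose(s.global_mean, 15.0)
        assert s.low_support_parks == []

    def test_noisy_triangle_mean_recovered_within_mc_bound(self):
        rng = np.random.default_rng(11)
        lags = np.arange(-30, 31)
        truth = 20.0 - 0.3 * np.abs(lags)
        noise_sd, n_years = 2.0, 30
        vals = truth[None, :] + rng.normal(0, noise_sd, (n_years, 61))
        w = make_windows(vals, ["a"] * n_years, lags=lags, variable="snow_cm")
        s = snow_trajectory_summary(w, loess_span=0.3)
        rmse = np.sqrt(np.mean((s.global_mean - truth) ** 2))
        assert rmse < 2 * noise_sd / np.sqrt(n_years)

    def test_missing_lags_excluded_from_mean(self):
        lags = np.arange(-3, 4)
        vals = np.full((3, 7), 8.0)
        vals[0, 2] = np.nan
        w = make_windows(vals, ["a"] * 3, lags=lags, variable="snow_cm")
        s = snow_trajectory_summary(w)
        assert np.allclose(s.raw_mean[0], 8.0)
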