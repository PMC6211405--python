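import numpy as np
import pandas as pd
import pytest

import denphen
from denphen.events import CredibilitySurface, EventDateModel, EventModelResults
from denphen.simulate import CoefParams, EventParams, center_climate


def build_dataset(n_parks=3, n_years=8, t0=90, T=109, seed=4, sigma=3.0):
    grid_len = T - t0 + 1
    sc = denphen.SyntheticScenario(
        n_parks=n_parks, first_year=2000, last_year=2000 + n_years - 1, seed=seed,
        event_params=EventParams(mu=99.0, park_intercept_sd=6.0,
                                 residual_sd_mean=sigma, residual_sd_spread=0.0,
                                 t0=t0, T=T),
        coef_params=CoefParams(alpha=np.full(grid_len, -0.02),
                               beta=np.zeros(grid_len)),
    )
    climate = denphen.simulate_climate(sc)
    coefs = denphen.simulate_coefficient_functions(sc)
    events, truth = denphen.simulate_event_dates(climate, coefs, sc)
    return sc, climate, events, truth


FIXED = dict(sd_alpha=0.05, sd_beta=0.02, ls_global=5.0, sd_a=0.02, sd_b=0.01,
             ls_park=4.0, sd_r=6.0)


def conjugate_oracle(model, h):
    """Closed-form Gaussian posterior of the equivalent Bayesian linear model.

    Weight space: theta = (mu, r_1..p, alpha, beta, a-dev per park,
    b-dev per park); z = A theta + eps.  Entirely independent of the
    function-space conditioning inside the model.
    """
    n, L, p = model.n, model.L, model.p
    g = model.grid
    d = g[:, None] - g[None, :]

    def se(sd, ls):
        return sd**2 * np.exp(-0.5 * (d / ls) ** 2)

    blocks = [np.array([[model.priors.mu_sd**2]]),
              h["sd_r"] ** 2 * np.eye(p),
              se(h["sd_alpha"], h["ls_global"]), se(h["sd_beta"], h["ls_global"])]
    blocks += [se(h["sd_a"], h["ls_park"]) for _ in range(p)]
    blocks += [se(h["sd_b"], h["ls_park"]) for _ in range(p)]
    dim = 1 + p + 2 * L + 2 * p * L
    V = np.zeros((dim, dim))
    off = 0
    for b in blocks:
        k = b.shape[0]
        V[off:off + k, off:off + k] = b
        off += k
    A = np.zeros((n, dim))
    A[:, 0] = 1.0
    for j in range(n):
        i = model.park_index[j]
        A[j, 1 + i] = 1.0
        A[j, 1 + p:1 + p + L] = model.U[j]
        A[j, 1 + p + L:1 + p + 2 * L] = model.S[j]
        a_off = 1 + p + 2 * L + i * L
        A[j, a_off:a_off + L] = model.U[j]
        b_off = 1 + p + 2 * L + p * L + i * L
        A[j, b_off:b_off + L] = model.S[j]
    prior_mean = np.zeros(dim)
    prior_mean[0] = model.priors.mu_mean
    noise = np.diag(h["sigma"][model.park_index] ** 2)
    S = A @ V @ A.T + noise
    gain = V @ A.T @ np.linalg.solve(S, model.z - A @ prior_mean)
    post = prior_mean + gain
    return {"mu": post[0], "r": post[1:1 + p],
            "alpha": post[1 + p:1 + p + L] + post[1 + p + 2 * L:1 + p + 3 * L] * 0,
            "alpha_global": post[1 + p:1 + p + L],
            "beta_global": post[1 + p + L:1 + p + 2 * L],
            "a_dev": post[1 + p + 2 * L:1 + p + (2 + p) * L].reshape(p, L)}


class TestConjugateOracle:
    def test_posterior_means_match_closed_form(self):
        sc, climate, events, truth = build_dataset()
        model = EventDateModel(events, climate, "first_exit", t0=90, T=109)
        sigma = np.full(model.p, 3.0)
        theta = model.pack(**FIXED, sigma=sigma)
        fit = model.fit(fixed_hyperparameters=theta, n_func_draws_per_hyper=500)
        h = model._unpack(theta)
        oracle = conjugate_oracle(model, h)
        assert abs(fit.mu_mean - oracle["mu"]) < 1e-6
        assert np.max(np.abs(fit.alpha_mean - oracle["alpha_global"])) < 1e-6
        assert np.max(np.abs(fit.beta_mean - oracle["beta_global"])) < 1e-6
        assert np.max(np.abs(fit.r_mean - oracle["r"])) < 1e-6
        assert np.max(np.abs(fit.a_mean - (oracle["alpha_global"] + oracle["a_dev"]))) < 1e-6

    def test_low_rank_basis_approximates_exact_posterior(self):
        sc, climate, events, truth = build_dataset(n_years=10)
        exact = EventDateModel(events, climate, "first_exit", t0=90, T=109,
                               low_rank=None)
        approx = EventDateModel(events, climate, "first_exit", t0=90, T=109,
                                low_rank=48)
        sigma = np.full(exact.p, 3.0)
        theta = exact.pack(**FIXED, sigma=sigma)
        fe = exact.fit(fixed_hyperparameters=theta, n_func_draws_per_hyper=0)
        fa = approx.fit(fixed_hyperparameters=theta, n_func_draws_per_hyper=0)
        assert np.max(np.abs(fe.alpha_mean - fa.alpha_mean)) < 5e-3
        assert abs(fe.mu_mean - fa.mu_mean) < 1e-2


def fake_results(draws_alpha, grid=None, model=None):
    draws_alpha = np.asarray(draws_alpha, float)
    L = draws_alpha.shape[1]
    grid = np.asarray(grid if grid is not None else np.arange(1, L + 1), float)
    res = EventModelResults(
        model=model, grid=grid, park_ids=["a"],
        hyper_draws=pd.DataFrame(), mu_mean=0.0, r_mean=np.zeros(1),
        alpha_mean=draws_alpha.mean(axis=0), beta_mean=np.zeros(L),
        a_mean=np.zeros((1, L)), b_mean=np.zeros((1, L)),
        fitted_mean=np.zeros(1), climate_pred_mean=np.zeros(1),
        alpha_draws=draws_alpha, beta_draws=np.zeros_like(draws_alpha),
        sigma_draws=np.ones((1, 1)),
    )
    res.MIN_DRAWS = 1
    return res


class TestWindowSumCredibility:
    def test_eight_handwritten_draws_match_exhaustive_count(self):
        draws = np.array([
            [1, -2, 0.5, 0.5, -1],
            [-1, -1, -1, -1, -1],
            [2, 2, 2, 2, 2],
            [0.5, -0.5, 0.5, -0.5, 0.5],
            [-3, 1, 1, 1, -1],
            [0, 0, 0, 0, 0],
            [1, 1, -5, 1, 1],
            [-0.25, 0.5, -0.25, 0.5, -0.25],
        ])
        res = fake_results(draws)
        surf = res.window_sum_credibility("alpha")
        for i in range(5):
            for j in range(i, 5):
                expected = np.mean(draws[:, i:j + 1].sum(axis=1) >= 0)
                # exhaustive hand count over the 8 draws
                count = sum(1 for d in draws if d[i:j + 1].sum() >= 0) / 8
                assert expected == count
                assert surf.matrix[i, j] == pytest.approx(count)
        assert np.isnan(surf.matrix[3, 1])

    def test_all_positive_draws_give_surface_of_ones(self):
        res = fake_results(np.abs(np.random.default_rng(0).normal(1, 0.1, (50, 4))))
        surf = res.window_sum_credibility("alpha")
        tri = surf.matrix[np.triu_indices(4)]
        assert np.allclose(tri, 1.0)

    def test_symmetric_draws_give_half(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0, 1, (4000, 3))
        res = fake_results(np.vstack([d, -d]))  # exactly symmetric
        surf = res.window_sum_credibility("alpha")
        tri = surf.matrix[np.triu_indices(3)]
        assert np.allclose(tri, 0.5, atol=0.01)

    def test_surface_bounds_and_at_accessor(self):
        res = fake_results(np.random.default_rng(2).normal(0, 1, (100, 6)))
        surf = res.window_sum_credibility("alpha")
        tri = surf.matrix[np.triu_indices(6)]
        assert np.all((tri >= 0) & (tri <= 1))
        with pytest.raises(IndexError):
            surf.at(4, 2)

    def test_diagonal_consistent_with_pointwise_sign(self):
        draws = np.random.default_rng(3).normal(0.2, 1.0, (500, 5))
        res = fake_results(draws)
        surf = res.window_sum_credibility("alpha")
        p_neg = np.mean(draws < 0, axis=0)
        assert np.allclose(np.diag(surf.matrix), 1.0 - p_neg)


class TestPointwiseSignCredibility:
    def test_all_zero_draws_give_empty_set(self):
        res = fake_results(np.zeros((100, 5)))
        assert res.pointwise_sign_credibility("alpha") == []

    def test_negative_block_returns_exact_run(self):
        rng = np.random.default_rng(4)
        L = 30
        draws = rng.normal(0, 1, (400, L))
        draws[:, 9:20] = -1.0  # grid days 10..20
        res = fake_results(draws)
        runs = res.pointwise_sign_credibility("alpha", threshold=0.95)
        assert runs == [(10, 20)]

    def test_min_draw_threshold_enforced(self):
        res = fake_results(np.zeros((8, 5)))
        res.MIN_DRAWS = 500
        with pytest.raises(ValueError, match="500"):
            res.pointwise_sign_credibility("alpha")


class TestPredictEventShift:
    def test_zero_draws_zero_shift(self):
        res = fake_results(np.zeros((100, 40)))
        out = res.predict_event_shift((5, 25))
        assert out["mean_days"] == 0.0 and out["sd_days"] == 0.0

    def test_constant_coefficient_window_sum_exact(self):
        res = fake_results(np.full((100, 40), -0.01))
        out = res.predict_event_shift((10, 30), delta=1.0)
        assert out["mean_days"] == pytest.approx(-0.21, abs=1e-12)
        assert out["sd_days"] == 0.0

    def test_window_outside_grid_raises(self):
        res = fake_results(np.zeros((100, 10)))
        with pytest.raises(IndexError):
            res.predict_event_shift((5, 30))


class TestModelValidation:
    def test_too_few_observations_refused(self):
        sc, climate, events, _ = build_dataset(n_parks=2, n_years=2)
        with pytest.raises(ValueError, match="at least 10"):
            EventDateModel(events, climate, "first_exit", t0=90, T=109)

    def test_nonfinite_climate_rejected(self):
        sc, climate, events, _ = build_dataset()
        climate.loc[climate.index[5], "temperature_c"] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            EventDateModel(events, climate, "first_exit", t0=90, T=109)

    def test_park_year_with_missing_climate_excluded_and_reported(self):
        sc, climate, events, _ = build_dataset(n_years=10)
        cut = climate[~((climate["park_id"] == "park01") & (climate["year"] == 2003)
                        & (climate["doy"] == 95))]
        model = EventDateModel(events, cut, "first_exit", t0=90, T=109)
        assert ("park01", 2003) in model.excluded
        assert model.n == len(events) - 1

    def test_unknown_kind_without_grid_rejected(self):
        sc, climate, events, _ = build_dataset()
        ev = events.assign(event_kind="hibernation")
        with pytest.raises(ValueError, match="hibernation"):
            EventDateModel(ev, climate, "hibernation")


class TestCenteringInvariance:
    def test_constant_park_shift_leaves_covariates_and_likelihood_unchanged(self):
        sc, climate, events, _ = build_dataset()
        shifted = climate.copy()
        mask = shifted["park_id"] == "park02"
        shifted.loc[mask, "temperature_c"] += 3.0
        c1 = center_climate(climate)
        c2 = center_climate(shifted)
        assert np.allclose(c1["temperature_c"], c2["temperature_c"])
        m1 = EventDateModel(events, climate, "first_exit", t0=90, T=109)
        m2 = EventDateModel(events, shifted, "first_exit", t0=90, T=109)
        assert np.allclose(m1.U, m2.U)
        theta = m1.pack(**FIXED, sigma=np.full(m1.p, 3.0))
        assert m1.loglike(theta) == pytest.approx(m2.loglike(theta), abs=1e-8)


class TestVarianceExplained:
    def test_noise_free_simulation_total_near_100(self):
        sc, climate, events, truth = build_dataset(n_years=8, sigma=0.05)
        model = EventDateModel(events, climate, "first_exit", t0=90, T=109)
        theta = model.pack(**FIXED, sigma=np.full(model.p, 0.1))
        fit = model.fit(fixed_hyperparameters=theta, n_func_draws_per_hyper=0)
        ve = fit.variance_explained()
        assert ve["total_pct"] > 97.0

    def test_zero_variance_response_errors(self):
        sc, climate, events, _ = build_dataset()
        events = events.assign(day_of_year=99)
        model = EventDateModel(events, climate, "first_exit", t0=90, T=109)
        fit = model.fit(fixed_hyperparameters=model.pack(
            **FIXED, sigma=np.full(model.p, 3.0)), n_func_draws_per_hyper=0)
        with pytest.raises(ValueError, match="zero response variance"):
            fit.variance_explained()
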