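"""Hierarchical Gaussian-process model of event-aligned climate.

The response is the daily mean temperature observed in park ``i`` and
year ``y`` at lag ``t`` days from the recorded denning event
(``t = 0`` is the event day)::

    v_iy(t) ~ GP(u_i(t),        k3_i)     park-year trajectories
    u_i(t)  ~ GP(w(t) + h_i,    k2)       park mean trajectories
    w(t)    ~ GP(mu,            k1)       population mean trajectory

``k1`` and ``k2`` are squared-exponential kernels (smooth averages);
``k3_i`` are exponential (Ornstein--Uhlenbeck) kernels with a common
range and park-specific variances (rough daily residuals, park
heteroscedasticity).  ``h_i`` is a constant park offset with a
Normal(0, tau^2) prior.

Inference: the model is linear-Gaussian given the kernel
hyperparameters, so ``w`` and all ``u_i`` are integrated out
analytically and only the hyperparameters are sampled by MCMC on the
marginal posterior.  Function draws are then recovered by exact
conditional-Gaussian sampling (jointly: first ``w | data``, then each
``u_i | w, data``, which factorizes over parks).  With hyperparameters
held fixed the conditional moments are exact, which is how the
dense-conditioning equivalence tests gate this implementation.

Snow depth is deliberately not modelled this way: daily snow dynamics
(spiky accumulation, compaction, melt) break the GP assumptions, so the
package instead provides the loess-based exploratory trajectory summary
:func:`snow_trajectory_summary`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._mcmc import (
    EnsembleResult,
    SamplerConfig,
    half_normal_logpdf,
    normal_logpdf,
    run_ensemble,
)
from .gaussian import CholFactor, chol_with_jitter, mvn_logpdf
from .io import LagWindowSet
from .kernels import exponential_kernel, se_kernel

log = logging.getLogger(__name__)

__all__ = [
    "TrajectoryPriors",
    "TemperatureTrajectoryModel",
    "TrajectoryResults",
    "SnowTrajectorySummary",
    "snow_trajectory_summary",
]

_DENSE_LIMIT = 6000  # max observed values for the dense (masked-data) path


@dataclass(frozen=True)
class TrajectoryPriors:
    """Weakly-informative defaults scaled to the data.

    Kernel SDs get half-Normal priors with scale equal to the empirical
    SD of the observed windows; length-scales and the OU range get a
    log-Normal(log 10 d, 0.75) prior; the top-level constant gets a
    Normal(empirical grand mean, 10^2).  All are artifact choices and
    configurable.
    """

    sd_scale: float
    mu_mean: float
    mu_sd: float = 10.0
    ls_log_mean: float = float(np.log(10.0))
    ls_log_sd: float = 0.75

    @staticmethod
    def from_windows(windows: LagWindowSet) -> "TrajectoryPriors":
        vals = windows.values[windows.mask]
        return TrajectoryPriors(
            sd_scale=float(np.std(vals)) or 1.0,
            mu_mean=float(np.mean(vals)),
        )


def _log_halfnormal_on_log(log_sd: float, scale: float) -> float:
    # half-Normal prior on sd, sampled as log sd (Jacobian included)
    return half_normal_logpdf(np.exp(log_sd), scale) + log_sd


class TemperatureTrajectoryModel:
    """Three-level GP regression of a :class:`~denphen.io.LagWindowSet`.

    Parameters
    ----------
    windows : LagWindowSet
        Event-aligned climate windows (typically temperature).
    priors : TrajectoryPriors, optional
        Defaults are scaled to the data.
    """

    def __init__(self, windows: LagWindowSet, priors: TrajectoryPriors | None = None):
        if windows.values.shape[0] < 2:
            raise ValueError("need at least two park-year windows; hierarchy unidentifiable")
        self.windows = windows
        self.parks = windows.parks
        if len(self.parks) < 2:
            raise ValueError("need at least two parks; hierarchy unidentifiable")
        self.priors = priors or TrajectoryPriors.from_windows(windows)
        self.grid = windows.lags.astype(float)
        self.L = self.grid.size
        self.p = len(self.parks)
        self.param_names = (
            ["log_sd1", "log_ls1", "log_sd2", "log_ls2", "log_tau", "log_range3"]
            + [f"log_sd3_{pk}" for pk in self.parks]
            + ["mu"]
        )
        self.dim = len(self.param_names)

        self._complete = windows.complete()
        park_rows = {pk: np.where(windows.park_ids == pk)[0] for pk in self.parks}
        self._n_years = np.array([len(park_rows[pk]) for pk in self.parks])
        if self._complete:
            # per-park year means and within-park residual stacks
            self._ybar = np.stack(
                [windows.values[park_rows[pk]].mean(axis=0) for pk in self.parks]
            )  # (p, L)
            resid = []
            self._resid_slices = []
            start = 0
            for ci, pk in enumerate(self.parks):
                v = windows.values[park_rows[pk]]
                r = (v - self._ybar[ci]).T  # (L, n_i)
                resid.append(r)
                self._resid_slices.append(slice(start, start + r.shape[1]))
                start += r.shape[1]
            self._resid = np.concatenate(resid, axis=1)  # (L, total years)
        else:
            n_obs = int(windows.mask.sum())
            if n_obs > _DENSE_LIMIT:
                raise ValueError(
                    f"{n_obs} observed values with masked lags exceeds the dense-path "
                    f"limit ({_DENSE_LIMIT}); drop incomplete windows first"
                )
            rows, cols = np.where(windows.mask)
            self._obs_y = windows.values[rows, cols]
            self._obs_t = self.grid[cols]
            self._obs_window = rows
            self._obs_park = np.array(
                [self.parks.index(windows.park_ids[r]) for r in rows]
            )

    # -- hyperparameter handling -------------------------------------------------

    def _unpack(self, theta: np.ndarray) -> dict:
        t = np.asarray(theta, float)
        p = self.p
        return {
            "sd1": np.exp(t[0]), "ls1": np.exp(t[1]),
            "sd2": np.exp(t[2]), "ls2": np.exp(t[3]),
            "tau": np.exp(t[4]), "range3": np.exp(t[5]),
            "sd3": np.exp(t[6:6 + p]),
            "mu": t[6 + p],
        }

    def pack(self, sd1, ls1, sd2, ls2, tau, range3, sd3, mu) -> np.ndarray:
        """Hyperparameters (natural scale) -> sampler vector."""
        return np.concatenate([
            np.log([sd1, ls1, sd2, ls2, max(tau, 1e-8), range3]),
            np.log(np.asarray(sd3, float)),
            [mu],
        ])

    def _start(self) -> np.ndarray:
        s = self.priors.sd_scale
        return self.pack(
            sd1=0.8 * s, ls1=10.0, sd2=0.4 * s, ls2=10.0, tau=0.3 * s,
            range3=5.0, sd3=np.full(self.p, 0.7 * s), mu=self.priors.mu_mean,
        )

    def log_prior(self, theta: np.ndarray) -> float:
        t = np.asarray(theta, float)
        pr = self.priors
        lp = 0.0
        for i in (0, 2, 4):
            lp += _log_halfnormal_on_log(t[i], pr.sd_scale)
        for i in (1, 3, 5):
            lp += normal_logpdf(t[i], pr.ls_log_mean, pr.ls_log_sd)
        for i in range(6, 6 + self.p):
            lp += _log_halfnormal_on_log(t[i], pr.sd_scale)
        lp += normal_logpdf(t[6 + self.p], pr.mu_mean, pr.mu_sd)
        return lp

    # -- marginal likelihood -----------------------------------------------------

    def _kernels(self, h: dict):
        k1 = se_kernel(h["sd1"] ** 2, h["ls1"])(self.grid)
        k2 = se_kernel(h["sd2"] ** 2, h["ls2"])(self.grid)
        c3 = exponential_kernel(1.0, h["range3"])(self.grid)
        return k1, k2, c3

    def loglike(self, theta: np.ndarray) -> float:
        h = self._unpack(theta)
        try:
            if self._complete:
                return self._loglike_structured(h)
            return self._loglike_dense(h)
        except np.linalg.LinAlgError:
            return -np.inf

    def _ybar_cov(self, h: dict) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Covariance of stacked per-park year-mean trajectories."""
        k1, k2, c3 = self._kernels(h)
        L, p = self.L, self.p
        tau2 = h["tau"] ** 2
        cov = np.tile(k1, (p, p))
        for ci in range(p):
            sl = slice(ci * L, (ci + 1) * L)
            cov[sl, sl] += k2 + tau2 + (h["sd3"][ci] ** 2 / self._n_years[ci]) * c3
        return cov, k1, k2

    def _loglike_structured(self, h: dict) -> float:
        _, _, c3 = self._kernels(h)
        c3_chol = chol_with_jitter(c3, scale=1.0)
        half = c3_chol.half_solve(self._resid)
        rss_by_col = np.sum(half**2, axis=0)
        ll = 0.0
        for ci in range(self.p):
            n_i = self._n_years[ci]
            if n_i < 2:
                continue
            sd3 = h["sd3"][ci]
            rss = float(np.sum(rss_by_col[self._resid_slices[ci]])) / sd3**2
            logdet_k3 = self.L * 2.0 * np.log(sd3) + c3_chol.logdet
            ll += (
                -0.5 * rss
                - 0.5 * (n_i - 1) * (self.L * np.log(2 * np.pi) + logdet_k3)
                - 0.5 * self.L * np.log(n_i)
            )
        cov, _, _ = self._ybar_cov(h)
        chol = chol_with_jitter(cov)
        ybar = self._ybar.ravel()
        ll += mvn_logpdf(ybar, np.full(ybar.size, h["mu"]), chol)
        return ll

    def _dense_cov(self, h: dict) -> np.ndarray:
        k1s = se_kernel(h["sd1"] ** 2, h["ls1"])
        k2s = se_kernel(h["sd2"] ** 2, h["ls2"])
        t = self._obs_t
        cov = k1s(t)
        same_park = self._obs_park[:, None] == self._obs_park[None, :]
        cov += (k2s(t) + h["tau"] ** 2) * same_park
        same_window = self._obs_window[:, None] == self._obs_window[None, :]
        d = np.abs(t[:, None] - t[None, :])
        sd3 = h["sd3"][self._obs_park]
        cov += same_window * (sd3[:, None] * sd3[None, :]) * np.exp(-d / h["range3"])
        return cov

    def _loglike_dense(self, h: dict) -> float:
        cov = self._dense_cov(h)
        chol = chol_with_jitter(cov)
        return mvn_logpdf(self._obs_y, np.full(self._obs_y.size, h["mu"]), chol)

    def log_posterior(self, theta: np.ndarray) -> float:
        lp = self.log_prior(theta)
        if not np.isfinite(lp):
            return -np.inf
        ll = self.loglike(theta)
        return lp + ll if np.isfinite(ll) else -np.inf

    # -- conditional layer -------------------------------------------------------

    def _conditional(self, theta: np.ndarray, rng: np.random.Generator | None,
                     n_func_draws: int = 4) -> dict:
        """Exact conditional moments and (optionally) joint function draws."""
        h = self._unpack(theta)
        if self._complete:
            return self._conditional_structured(h, rng, n_func_draws)
        return self._conditional_dense(h, rng, n_func_draws)

    def _conditional_structured(self, h, rng, n_func_draws) -> dict:
        L, p = self.L, self.p
        cov, k1, k2 = self._ybar_cov(h)
        _, _, c3 = self._kernels(h)
        tau2 = h["tau"] ** 2
        chol = chol_with_jitter(cov)
        resid = self._ybar.ravel() - h["mu"]

        cross_w = np.tile(k1, (1, p))                   # Cov(w, ybar)
        alpha = chol.solve(resid)
        w_mean = h["mu"] + cross_w @ alpha
        v = chol.half_solve(cross_w.T)
        w_cov = k1 - v.T @ v

        # per-park factors for u_i | w, data  (parks decouple given w)
        kp = k2 + tau2                                   # prior cov of u_i - w
        u_mean = np.empty((p, L))
        S = []
        u_cond_cov = []
        for ci in range(p):
            a_i = kp + (h["sd3"][ci] ** 2 / self._n_years[ci]) * c3
            ai_chol = chol_with_jitter(a_i)
            s_i = ai_chol.solve(kp).T                    # kp @ a_i^{-1}
            S.append(s_i)
            hv = ai_chol.half_solve(kp)
            u_cond_cov.append(kp - hv.T @ hv)
            u_mean[ci] = w_mean + s_i @ (self._ybar[ci] - w_mean)

        out = {"w_mean": w_mean, "w_cov": w_cov, "u_mean": u_mean, "h": h}
        if rng is not None and n_func_draws > 0:
            w_chol = chol_with_jitter(w_cov, scale=max(h["sd1"] ** 2, 1e-10))
            u_chols = [chol_with_jitter(c, scale=max(h["sd2"] ** 2 + tau2, 1e-10))
                       for c in u_cond_cov]
            wd = np.empty((n_func_draws, L))
            ud = np.empty((n_func_draws, p, L))
            for d in range(n_func_draws):
                w = w_mean + w_chol.lower @ rng.standard_normal(L)
                wd[d] = w
                for ci in range(p):
                    m = w + S[ci] @ (self._ybar[ci] - w)
                    ud[d, ci] = m + u_chols[ci].lower @ rng.standard_normal(L)
            out["w_draws"], out["u_draws"] = wd, ud
        return out

    def _conditional_dense(self, h, rng, n_func_draws) -> dict:
        L, p = self.L, self.p
        k1s = se_kernel(h["sd1"] ** 2, h["ls1"])
        k2s = se_kernel(h["sd2"] ** 2, h["ls2"])
        tau2 = h["tau"] ** 2
        cov = self._dense_cov(h)
        chol = chol_with_jitter(cov)
        resid = self._obs_y - h["mu"]
        alpha = chol.solve(resid)

        cross_w = k1s(self.grid, self._obs_t)            # (L, N)
        w_mean = h["mu"] + cross_w @ alpha
        v = chol.half_solve(cross_w.T)
        w_cov = k1s(self.grid) - v.T @ v

        kp_grid = k2s(self.grid) + tau2
        u_mean = np.empty((p, L))
        park_factors = []
        for ci in range(p):
            idx = np.where(self._obs_park == ci)[0]
            t_o = self._obs_t[idx]
            win = self._obs_window[idx]
            a_i = k2s(t_o) + tau2
            d = np.abs(t_o[:, None] - t_o[None, :])
            a_i += (win[:, None] == win[None, :]) * h["sd3"][ci] ** 2 * np.exp(-d / h["range3"])
            ai_chol = chol_with_jitter(a_i)
            cross_u = k2s(self.grid, t_o) + tau2         # Cov(u_i - w, v_obs - w)
            park_factors.append((idx, ai_chol, cross_u))
            # plug-in mean: E[u_i|data] = E[w|..] + cross a^{-1} (y_o - E[w](t_o))
            w_mean_at_obs = h["mu"] + (k1s(t_o, self._obs_t) @ alpha)
            u_mean[ci] = w_mean + cross_u @ ai_chol.solve(self._obs_y[idx] - w_mean_at_obs)

        out = {"w_mean": w_mean, "w_cov": w_cov, "u_mean": u_mean, "h": h}
        if rng is not None and n_func_draws > 0:
            w_chol = chol_with_jitter(w_cov, scale=max(h["sd1"] ** 2, 1e-10))
            wd = np.empty((n_func_draws, L))
            ud = np.empty((n_func_draws, p, L))
            grid_pos = {float(t): j for j, t in enumerate(self.grid)}
            for d in range(n_func_draws):
                w = w_mean + w_chol.lower @ rng.standard_normal(L)
                wd[d] = w
                for ci, (idx, ai_chol, cross_u) in enumerate(park_factors):
                    t_o = self._obs_t[idx]
                    w_at_obs = np.array([w[grid_pos[float(t)]] for t in t_o])
                    m = w + cross_u @ ai_chol.solve(self._obs_y[idx] - w_at_obs)
                    hv = ai_chol.half_solve(cross_u.T)
                    c = kp_grid - hv.T @ hv
                    cchol = chol_with_jitter(c, scale=max(h["sd2"] ** 2 + tau2, 1e-10))
                    ud[d, ci] = m + cchol.lower @ rng.standard_normal(L)
            out["w_draws"], out["u_draws"] = wd, ud
        return out

    # -- fitting -------------------------------------------------------------

    def fit(
        self,
        sampler_config: SamplerConfig | None = None,
        fixed_hyperparameters: np.ndarray | dict | None = None,
        n_func_draws_per_hyper: int = 4,
    ) -> "TrajectoryResults":
        """Sample the marginal posterior and recover function draws.

        With ``fixed_hyperparameters`` (a packed vector or keyword dict
        for :meth:`pack`) no MCMC is run and the conditional layer is
        evaluated exactly at the given values.
        """
        config = sampler_config or SamplerConfig()
        if fixed_hyperparameters is not None:
            if isinstance(fixed_hyperparameters, dict):
                theta = self.pack(**fixed_hyperparameters)
            else:
                theta = np.asarray(fixed_hyperparameters, float)
            hyper_draws = theta[None, :]
            diagnostics = {"fixed_hyperparameters": True}
        else:
            res: EnsembleResult = run_ensemble(self.log_posterior, self._start(), config)
            hyper_draws = res.draws
            diagnostics = res.diagnostics

        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x7261)))
        n_hyper = hyper_draws.shape[0]
        w_means = np.empty((n_hyper, self.L))
        u_means = np.empty((n_hyper, self.p, self.L))
        w_draws, u_draws = [], []
        w_cov_diag = np.empty((n_hyper, self.L))
        for d in range(n_hyper):
            cond = self._conditional(hyper_draws[d], rng, n_func_draws_per_hyper)
            w_means[d] = cond["w_mean"]
            u_means[d] = cond["u_mean"]
            w_cov_diag[d] = np.diag(cond["w_cov"])
            if "w_draws" in cond:
                w_draws.append(cond["w_draws"])
                u_draws.append(cond["u_draws"])

        observed = self.windows.values[self.windows.mask]
        return TrajectoryResults(
            model=self,
            lags=self.grid.copy(),
            park_ids=list(self.parks),
            hyper_draws=pd.DataFrame(hyper_draws, columns=self.param_names),
            w_mean=w_means.mean(axis=0),
            u_mean=u_means.mean(axis=0),
            w_mean_per_hyper=w_means,
            w_cov_diag_per_hyper=w_cov_diag,
            w_draws=np.concatenate(w_draws) if w_draws else np.empty((0, self.L)),
            u_draws=np.concatenate(u_draws) if u_draws else np.empty((0, self.p, self.L)),
            total_observed_variance=float(np.var(observed)),
            diagnostics=diagnostics,
        )


@dataclass
class TrajectoryResults:
    """Posterior summary of a fitted :class:`TemperatureTrajectoryModel`."""

    model: TemperatureTrajectoryModel
    lags: np.ndarray
    park_ids: list
    hyper_draws: pd.DataFrame
    w_mean: np.ndarray                 # (L,) posterior mean of w(t)
    u_mean: np.ndarray                 # (p, L) posterior means of u_i(t)
    w_mean_per_hyper: np.ndarray
    w_cov_diag_per_hyper: np.ndarray
    w_draws: np.ndarray                # pooled joint function draws
    u_draws: np.ndarray
    total_observed_variance: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.w_draws.shape[0]

    def w_quantiles(self, probs=(0.05, 0.5, 0.95)) -> pd.DataFrame:
        q = np.quantile(self.w_draws, probs, axis=0)
        return pd.DataFrame({"lag": self.lags, **{f"q{int(100*p)}": q[i]
                                                  for i, p in enumerate(probs)}})

    # -- headline summaries ----------------------------------------------------

    def variance_partition(self, per_draw: bool = False) -> dict:
        """Split observed variance into shared / park-additional / idiosyncratic %.

        shared: variance over the lag grid of the posterior-mean ``w``;
        park-additional: mean over parks of the lag-grid variance of
        ``u_i - w``; idiosyncratic: remainder.  All relative to the
        pooled empirical variance of the observed window values.
        With ``per_draw=True`` the first two components use joint
        function draws instead of posterior means (sensitivity variant).
        """
        total = self.total_observed_variance
        if total <= 0:
            raise ValueError("zero total variance; partition undefined")
        if per_draw:
            if self.n_draws == 0:
                raise ValueError("no function draws available for per_draw partition")
            shared = float(np.mean(np.var(self.w_draws, axis=1))) / total * 100
            dev = self.u_draws - self.w_draws[:, None, :]
            park = float(np.mean(np.var(dev, axis=2))) / total * 100
        else:
            shared = float(np.var(self.w_mean)) / total * 100
            park = float(np.mean(np.var(self.u_mean - self.w_mean, axis=1))) / total * 100
        return {
            "shared_pct": shared,
            "park_additional_pct": park,
            "idiosyncratic_pct": 100.0 - shared - park,
        }

    def event_day_summary(self) -> dict:
        """Expected climate at lag 0 and the local slope per day.

        Reports both the posterior SD of the mean trajectory ``w(0)``
        and the predictive SD for a new daily value (adds the mean
        posterior short-range OU variance).
        """
        i0 = int(np.where(self.lags == 0)[0][0])
        w0 = float(self.w_mean[i0])
        if self.n_draws:
            post_sd = float(np.std(self.w_draws[:, i0]))
        else:
            post_sd = float(np.sqrt(np.mean(self.w_cov_diag_per_hyper[:, i0])))
        sd3_cols = [c for c in self.hyper_draws.columns if c.startswith("log_sd3_")]
        mean_k3_var = float(np.mean(np.exp(2 * self.hyper_draws[sd3_cols].to_numpy())))
        slope = float((self.w_mean[i0 + 1] - self.w_mean[i0 - 1]) / 2.0) \
            if 0 < i0 < len(self.lags) - 1 else np.nan
        return {
            "value_at_event_day": w0,
            "posterior_sd": post_sd,
            "predictive_sd": float(np.sqrt(post_sd**2 + mean_k3_var)),
            "slope_per_day": slope,
        }

    def summary(self) -> str:
        ed = self.event_day_summary()
        vp = self.variance_partition()
        hyper = self.hyper_draws.copy()
        for c in hyper.columns:
            if c.startswith("log_"):
                hyper[c[4:]] = np.exp(hyper[c])
                del hyper[c]
        desc = hyper.describe(percentiles=[0.05, 0.5, 0.95]).T[["mean", "5%", "50%", "95%"]]
        lines = [
            "Hierarchical GP trajectory model",
            "=" * 48,
            f"parks: {len(self.park_ids)}   windows: {self.model.windows.values.shape[0]}"
            f"   lags: {self.lags.min():.0f}..{self.lags.max():.0f}",
            f"w(0) = {ed['value_at_event_day']:.2f} (+/- {ed['posterior_sd']:.3f} posterior SD)",
            f"slope of w at lag 0: {ed['slope_per_day']:+.3f} per day",
            "variance partition (% of observed): "
            f"shared {vp['shared_pct']:.1f} / park +{vp['park_additional_pct']:.1f} / "
            f"idiosyncratic {vp['idiosyncratic_pct']:.1f}",
            "",
            desc.to_string(float_format=lambda x: f"{x:.3f}"),
        ]
        if "max_rhat" in self.diagnostics:
            lines.append(
                f"\nmax split-R-hat {self.diagnostics['max_rhat']:.3f}, "
                f"min bulk ESS {self.diagnostics['min_ess']:.0f}"
            )
        return "\n".join(lines)

    def curves_to_csv(self, path) -> None:
        """Per-lag posterior mean and 5/95% quantiles for w and each u_i."""
        out = {"lag": self.lags, "w_mean": self.w_mean}
        if self.n_draws:
            out["w_q5"] = np.quantile(self.w_draws, 0.05, axis=0)
            out["w_q95"] = np.quantile(self.w_draws, 0.95, axis=0)
        for ci, pk in enumerate(self.park_ids):
            out[f"u_{pk}_mean"] = self.u_mean[ci]
            if self.n_draws:
                out[f"u_{pk}_q5"] = np.quantile(self.u_draws[:, ci], 0.05, axis=0)
                out[f"u_{pk}_q95"] = np.quantile(self.u_draws[:, ci], 0.95, axis=0)
        pd.DataFrame(out).to_csv(path, index=False)


# -- snow: exploratory loess trajectory summary ---------------------------------


@dataclass
class SnowTrajectorySummary:
    """Loess-smoothed average snow trajectories around the event day."""

    lags: np.ndarray
    park_ids: list
    raw_mean: np.ndarray       # (p, L) per-park mean over years, NaN-aware
    smoothed: np.ndarray       # (p, L) loess of raw_mean, clipped at 0
    global_mean: np.ndarray    # (L,) park average of smoothed
    loess_span: float
    low_support_parks: list

    @property
    def n_parks(self) -> int:
        return len(self.park_ids)

    def event_day_summary(self) -> dict:
        i0 = int(np.where(self.lags == 0)[0][0])
        slope = float((self.global_mean[i0 + 1] - self.global_mean[i0 - 1]) / 2.0) \
            if 0 < i0 < len(self.lags) - 1 else np.nan
        return {"value_at_event_day": float(self.global_mean[i0]), "slope_per_day": slope}

    def variance_partition(self, windows: LagWindowSet) -> dict:
        """Analogue of the GP partition using the loess curves as u_i and w."""
        observed = windows.values[windows.mask]
        total = float(np.var(observed))
        if total <= 0:
            raise ValueError("zero total variance; partition undefined")
        shared = float(np.var(self.global_mean)) / total * 100
        park = float(np.mean(np.var(self.smoothed - self.global_mean, axis=1))) / total * 100
        return {"shared_pct": shared, "park_additional_pct": park,
                "idiosyncratic_pct": 100.0 - shared - park}


def snow_trajectory_summary(
    windows: LagWindowSet, loess_span: float = 0.3
) -> SnowTrajectorySummary:
    """Average snow windows per park, loess-smooth, then average over parks.

    Missing lags are excluded from the per-park means; parks with fewer
    than 3 years are computed but flagged low-support.  Smoothed values
    are clipped at zero (snow depth cannot be negative) before the park
    average is taken.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    parks = windows.parks
    if not parks:
        raise ValueError("no snow windows provided")
    lags = windows.lags.astype(float)
    raw = np.empty((len(parks), lags.size))
    smooth = np.empty_like(raw)
    low_support = []
    for ci, pk in enumerate(parks):
        rows = windows.values[windows.park_ids == pk]
        if rows.shape[0] < 3:
            low_support.append(pk)
        with np.errstate(invalid="ignore"):
            raw[ci] = np.nanmean(rows, axis=0)
        ok = ~np.isnan(raw[ci])
        sm = lowess(raw[ci, ok], lags[ok], frac=loess_span, return_sorted=False)
        smooth[ci] = np.interp(lags, lags[ok], sm)
        smooth[ci] = np.clip(smooth[ci], 0.0, None)
    return SnowTrajectorySummary(
        lags=windows.lags.copy(),
        park_ids=parks,
        raw_mean=raw,
        smoothed=smooth,
        global_mean=smooth.mean(axis=0),
        loess_span=loess_span,
        low_support_parks=low_support,
    )
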