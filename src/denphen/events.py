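"""Time-varying-coefficient model of denning dates on daily climate.

An extension of a linear mixed model: the observed event day ``z_iy``
(park ``i``, year ``y``) responds to every single day's centered
temperature ``u_iy(t)`` and snow depth ``v_iy(t)`` over the season grid
``[t0, T]`` through coefficient *functions* with GP priors::

    z_iy   = mu + r_i + sum_t a_i(t) u_iy(t) + sum_t b_i(t) v_iy(t) + eps_iy
    a_i(t) ~ GP(alpha(t), k_a),   b_i(t) ~ GP(beta(t), k_b)
    alpha  ~ GP(0, k_alpha),      beta   ~ GP(0, k_beta)
    r_i    ~ N(0, sigma_r^2),     eps_iy ~ N(0, sigma_i^2)

``k_alpha``/``k_beta`` share one squared-exponential length-scale with
separate variances, and likewise ``k_a``/``k_b`` (the park-deviation
kernels).  The park residual SDs are hierarchical: ``log sigma_i ~
N(m_sigma, rho^2)`` (the log scale keeps every draw positive while
preserving the intent of a Normal hierarchy on the SDs).

Climate covariates are centered per park x day-of-year before entering
the sums — the same convention the synthetic generator uses — which
decouples the climate terms from the intercepts ``mu + r_i``.

Inference mirrors the trajectory model: all Gaussian parameters
(including ``mu``, which carries a Normal prior) are integrated out, the
kernel/variance hyperparameters are sampled by ensemble MCMC on the
marginal posterior (warm-started at the marginal MAP), and coefficient
curves are recovered by exact conditional-Gaussian draws.  A reduced-
rank sine-basis representation of the SE kernels is available for long
season grids; the exact dense representation is the default and is the
one the closed-form-posterior equivalence tests gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._mcmc import (
    SamplerConfig,
    half_normal_logpdf,
    normal_logpdf,
    run_ensemble,
)
from .gaussian import chol_with_jitter, loo_gaussian_moments, mvn_logpdf
from .simulate import center_climate

log = logging.getLogger(__name__)

__all__ = [
    "EventModelPriors",
    "EventDateModel",
    "EventModelResults",
    "CredibilitySurface",
    "SEASON_GRIDS",
]

SEASON_GRIDS = {"last_entry": (211, 365), "first_exit": (1, 150)}


def _log_halfnormal_on_log(log_sd: float, scale: float) -> float:
    return half_normal_logpdf(np.exp(log_sd), scale) + log_sd


@dataclass(frozen=True)
class EventModelPriors:
    """Data-scaled weakly-informative defaults (documented artifact choices).

    Coefficient-SD scales are ``sd(z) / (sd(covariate) * sqrt(L))`` — the
    size a single coefficient would need if the whole seasonal effect
    were spread evenly over the grid.  Park-deviation kernels share the
    same scale; length-scales get log-Normal(log 10 d, 0.75); ``mu``
    gets Normal(mean(z), 20^2); ``log sigma_i`` is hierarchical with a
    Normal(log sd(z), 1) prior on its mean and half-Normal(0.5) on its
    spread.
    """

    coef_sd_scale_temp: float
    coef_sd_scale_snow: float
    sigma_r_scale: float
    mu_mean: float
    mu_sd: float = 20.0
    ls_log_mean: float = float(np.log(10.0))
    ls_log_sd: float = 0.75
    logsig_mean_loc: float = 0.0
    logsig_mean_sd: float = 1.0
    logsig_spread_scale: float = 0.5

    @staticmethod
    def from_data(z: np.ndarray, U: np.ndarray, S: np.ndarray) -> "EventModelPriors":
        sd_z = float(np.std(z)) or 1.0
        L = U.shape[1]
        sd_u = float(np.std(U)) or 1.0
        sd_s = float(np.std(S)) or 1.0
        return EventModelPriors(
            coef_sd_scale_temp=sd_z / (sd_u * np.sqrt(L)),
            coef_sd_scale_snow=sd_z / (sd_s * np.sqrt(L)),
            sigma_r_scale=sd_z,
            mu_mean=float(np.mean(z)),
            logsig_mean_loc=float(np.log(sd_z)),
        )


def _hsgp_basis(grid: np.ndarray, m: int, boundary: float = 1.5):
    """Sine basis and frequency roots for the reduced-rank SE kernel."""
    c = 0.5 * (grid[0] + grid[-1])
    half = 0.5 * (grid[-1] - grid[0])
    Lb = boundary * half
    j = np.arange(1, m + 1)
    sqrt_lam = j * np.pi / (2.0 * Lb)
    phi = np.sqrt(1.0 / Lb) * np.sin(sqrt_lam[None, :] * (grid[:, None] - c + Lb))
    return phi, sqrt_lam


def _se_spectral(sd: float, ls: float, sqrt_lam: np.ndarray) -> np.ndarray:
    return sd**2 * np.sqrt(2.0 * np.pi) * ls * np.exp(-0.5 * (ls * sqrt_lam) ** 2)


class EventDateModel:
    """Scalar-on-function regression of event dates on daily climate.

    Parameters
    ----------
    events : DataFrame
        Columns ``park_id, year, event_kind, day_of_year`` (one kind).
    climate : DataFrame
        Park-daily frame ``park_id, year, doy, temperature_c, snow_cm``
        covering ``[t0, T]`` for every park-year with an event.
    t0, T : int, optional
        Season grid; defaults per event kind (211..365 for last den
        entry, 1..150 for first den exit).
    low_rank : int or None or "auto"
        Rank of the reduced SE-kernel basis; ``None`` = exact dense
        kernels (default for grids up to 100 days under "auto").
    """

    def __init__(
        self,
        events: pd.DataFrame,
        climate: pd.DataFrame,
        event_kind: str | None = None,
        t0: int | None = None,
        T: int | None = None,
        priors: EventModelPriors | None = None,
        low_rank: int | None | str = "auto",
    ):
        kinds = events["event_kind"].unique()
        if event_kind is None:
            if len(kinds) != 1:
                raise ValueError(f"events contain multiple kinds {kinds}; pass event_kind")
            event_kind = str(kinds[0])
        events = events[events["event_kind"] == event_kind]
        if event_kind not in SEASON_GRIDS and (t0 is None or T is None):
            raise ValueError(f"unknown event kind {event_kind!r} and no t0/T given")
        d0, dT = SEASON_GRIDS.get(event_kind, (None, None))
        self.t0 = int(t0 if t0 is not None else d0)
        self.T = int(T if T is not None else dT)
        if not self.t0 < self.T:
            raise ValueError(f"need t0 < T, got {self.t0} >= {self.T}")
        self.event_kind = event_kind
        self.grid = np.arange(self.t0, self.T + 1, dtype=float)
        self.L = self.grid.size

        for col in ("temperature_c", "snow_cm"):
            vals = climate[col].to_numpy(float)
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"non-finite values in climate column {col}")

        centered = center_climate(climate)
        sub = centered[centered["doy"].between(self.t0, self.T)]
        piv_t = sub.pivot_table(index=["park_id", "year"], columns="doy",
                                values="temperature_c", sort=True)
        piv_s = sub.pivot_table(index=["park_id", "year"], columns="doy",
                                values="snow_cm", sort=True)

        self.excluded = []
        rows_u, rows_s, keep = [], [], []
        for _, ev in events.iterrows():
            key = (ev["park_id"], int(ev["year"]))
            if key not in piv_t.index:
                self.excluded.append(key)
                continue
            u = piv_t.loc[key].to_numpy(float)
            s = piv_s.loc[key].to_numpy(float)
            if u.size != self.L or np.isnan(u).any() or np.isnan(s).any():
                self.excluded.append(key)
                continue
            rows_u.append(u)
            rows_s.append(s)
            keep.append(ev)
        if self.excluded:
            log.warning("excluded %d park-years with incomplete climate: %s",
                        len(self.excluded), self.excluded[:5])
        if len(keep) < 10:
            raise ValueError(f"only {len(keep)} usable observations; need at least 10")

        kept = pd.DataFrame(keep).reset_index(drop=True)
        self.obs = kept
        self.z = kept["day_of_year"].to_numpy(float)
        self.U = np.array(rows_u)
        self.S = np.array(rows_s)
        self.parks = sorted(kept["park_id"].unique().tolist())
        self.p = len(self.parks)
        self.park_index = kept["park_id"].map({pk: i for i, pk in enumerate(self.parks)}).to_numpy()
        self.n = self.z.size
        self.priors = priors or EventModelPriors.from_data(self.z, self.U, self.S)

        if low_rank == "auto":
            low_rank = None if self.L <= 100 else max(64, int(0.5 * self.L))
        self.low_rank = low_rank
        if low_rank is None:
            self._phi = np.eye(self.L)
            self._sqrt_lam = None
            self._gu, self._gs = self.U, self.S
        else:
            self._phi, self._sqrt_lam = _hsgp_basis(self.grid, int(low_rank))
            self._gu = self.U @ self._phi
            self._gs = self.S @ self._phi
        self.m = self._phi.shape[1]
        self._park_rows = [np.where(self.park_index == i)[0] for i in range(self.p)]
        self._same_park = self.park_index[:, None] == self.park_index[None, :]

        self.param_names = (
            ["log_sd_alpha", "log_sd_beta", "log_ls_global",
             "log_sd_a", "log_sd_b", "log_ls_park", "log_sd_r"]
            + [f"log_sigma_{pk}" for pk in self.parks]
            + ["logsig_mean", "log_logsig_spread"]
        )
        self.dim = len(self.param_names)

    # -- hyperparameters ---------------------------------------------------------

    def _unpack(self, theta: np.ndarray) -> dict:
        t = np.asarray(theta, float)
        p = self.p
        return {
            "sd_alpha": np.exp(t[0]), "sd_beta": np.exp(t[1]), "ls_global": np.exp(t[2]),
            "sd_a": np.exp(t[3]), "sd_b": np.exp(t[4]), "ls_park": np.exp(t[5]),
            "sd_r": np.exp(t[6]),
            "sigma": np.exp(t[7:7 + p]),
            "logsig_mean": t[7 + p],
            "logsig_spread": np.exp(t[8 + p]),
        }

    def pack(self, sd_alpha, sd_beta, ls_global, sd_a, sd_b, ls_park, sd_r,
             sigma, logsig_mean=None, logsig_spread=0.3) -> np.ndarray:
        sigma = np.asarray(sigma, float)
        if logsig_mean is None:
            logsig_mean = float(np.mean(np.log(sigma)))
        return np.concatenate([
            np.log([sd_alpha, sd_beta, ls_global, max(sd_a, 1e-10), max(sd_b, 1e-10),
                    ls_park, max(sd_r, 1e-10)]),
            np.log(sigma),
            [logsig_mean, np.log(logsig_spread)],
        ])

    def _start(self) -> np.ndarray:
        pr = self.priors
        sd_z = float(np.std(self.z)) or 1.0
        return self.pack(
            sd_alpha=0.5 * pr.coef_sd_scale_temp, sd_beta=0.5 * pr.coef_sd_scale_snow,
            ls_global=10.0,
            sd_a=0.2 * pr.coef_sd_scale_temp, sd_b=0.2 * pr.coef_sd_scale_snow,
            ls_park=10.0, sd_r=0.6 * sd_z,
            sigma=np.full(self.p, 0.6 * sd_z),
        )

    def log_prior(self, theta: np.ndarray) -> float:
        t = np.asarray(theta, float)
        pr = self.priors
        h = self._unpack(t)
        lp = _log_halfnormal_on_log(t[0], pr.coef_sd_scale_temp)
        lp += _log_halfnormal_on_log(t[1], pr.coef_sd_scale_snow)
        lp += normal_logpdf(t[2], pr.ls_log_mean, pr.ls_log_sd)
        lp += _log_halfnormal_on_log(t[3], pr.coef_sd_scale_temp)
        lp += _log_halfnormal_on_log(t[4], pr.coef_sd_scale_snow)
        lp += normal_logpdf(t[5], pr.ls_log_mean, pr.ls_log_sd)
        lp += _log_halfnormal_on_log(t[6], pr.sigma_r_scale)
        # hierarchical log-sigmas
        lp += normal_logpdf(t[7:7 + self.p], h["logsig_mean"], h["logsig_spread"])
        lp += normal_logpdf(h["logsig_mean"], pr.logsig_mean_loc, pr.logsig_mean_sd)
        lp += _log_halfnormal_on_log(t[8 + self.p], pr.logsig_spread_scale)
        return lp

    # -- marginal likelihood -----------------------------------------------------

    def _weight_cov(self, sd: float, ls: float) -> np.ndarray:
        """Prior covariance of basis weights: dense kernel or spectral diag."""
        if self.low_rank is None:
            d = self.grid[:, None] - self.grid[None, :]
            return sd**2 * np.exp(-0.5 * (d / ls) ** 2)
        return np.diag(_se_spectral(sd, ls, self._sqrt_lam))

    def _marginal_cov(self, h: dict) -> np.ndarray:
        pr = self.priors
        cov = np.full((self.n, self.n), pr.mu_sd**2)
        cov += h["sd_r"] ** 2 * self._same_park
        d_alpha = self._weight_cov(h["sd_alpha"], h["ls_global"])
        d_beta = self._weight_cov(h["sd_beta"], h["ls_global"])
        cov += self._gu @ d_alpha @ self._gu.T
        cov += self._gs @ d_beta @ self._gs.T
        if h["sd_a"] > 0 or h["sd_b"] > 0:
            d_a = self._weight_cov(h["sd_a"], h["ls_park"])
            d_b = self._weight_cov(h["sd_b"], h["ls_park"])
            for rows in self._park_rows:
                gu, gs = self._gu[rows], self._gs[rows]
                blk = gu @ d_a @ gu.T + gs @ d_b @ gs.T
                cov[np.ix_(rows, rows)] += blk
        cov[np.diag_indices(self.n)] += h["sigma"][self.park_index] ** 2
        return cov

    def loglike(self, theta: np.ndarray) -> float:
        h = self._unpack(theta)
        try:
            cov = self._marginal_cov(h)
            chol = chol_with_jitter(cov)
        except np.linalg.LinAlgError:
            return -np.inf
        return mvn_logpdf(self.z, np.full(self.n, self.priors.mu_mean), chol)

    def log_posterior(self, theta: np.ndarray) -> float:
        lp = self.log_prior(theta)
        if not np.isfinite(lp):
            return -np.inf
        ll = self.loglike(theta)
        return lp + ll if np.isfinite(ll) else -np.inf

    # -- conditional Gaussian layer ----------------------------------------------

    def _conditional(self, theta: np.ndarray, rng: np.random.Generator | None,
                     n_func_draws: int = 5) -> dict:
        """Exact posterior of (mu, r, alpha, beta, park curves) given theta."""
        pr = self.priors
        h = self._unpack(theta)
        cov = self._marginal_cov(h)
        chol = chol_with_jitter(cov)
        resid = self.z - pr.mu_mean
        kinv_r = chol.solve(resid)

        mu_mean = pr.mu_mean + pr.mu_sd**2 * float(np.sum(kinv_r))
        r_mean = np.array([h["sd_r"] ** 2 * float(np.sum(kinv_r[rows]))
                           for rows in self._park_rows])

        d_alpha = self._weight_cov(h["sd_alpha"], h["ls_global"])
        d_beta = self._weight_cov(h["sd_beta"], h["ls_global"])
        ca_mean = d_alpha @ (self._gu.T @ kinv_r)
        cb_mean = d_beta @ (self._gs.T @ kinv_r)
        alpha_mean = self._phi @ ca_mean
        beta_mean = self._phi @ cb_mean

        d_a = self._weight_cov(h["sd_a"], h["ls_park"])
        d_b = self._weight_cov(h["sd_b"], h["ls_park"])
        a_dev_mean = np.empty((self.p, self.L))
        b_dev_mean = np.empty((self.p, self.L))
        for i, rows in enumerate(self._park_rows):
            a_dev_mean[i] = self._phi @ (d_a @ (self._gu[rows].T @ kinv_r[rows]))
            b_dev_mean[i] = self._phi @ (d_b @ (self._gs[rows].T @ kinv_r[rows]))

        out = {
            "h": h, "mu_mean": mu_mean, "r_mean": r_mean,
            "alpha_mean": alpha_mean, "beta_mean": beta_mean,
            "a_mean": alpha_mean[None, :] + a_dev_mean,
            "b_mean": beta_mean[None, :] + b_dev_mean,
            "fitted_mean": self.z - h["sigma"][self.park_index] ** 2 * kinv_r,
            "climate_pred_mean": (
                np.einsum("nl,nl->n", self.U, (alpha_mean[None, :] + a_dev_mean)[self.park_index])
                + np.einsum("nl,nl->n", self.S, (beta_mean[None, :] + b_dev_mean)[self.park_index])
            ),
        }
        if rng is not None and n_func_draws > 0:
            va = chol.half_solve(self._gu @ d_alpha)
            cov_ca = d_alpha - va.T @ va
            vb = chol.half_solve(self._gs @ d_beta)
            cov_cb = d_beta - vb.T @ vb
            scale_a = max(float(np.max(np.abs(np.diag(d_alpha)))), 1e-14)
            scale_b = max(float(np.max(np.abs(np.diag(d_beta)))), 1e-14)
            la = chol_with_jitter(cov_ca, scale=scale_a)
            lb = chol_with_jitter(cov_cb, scale=scale_b)
            za = rng.standard_normal((self.m, n_func_draws))
            zb = rng.standard_normal((self.m, n_func_draws))
            out["alpha_draws"] = (alpha_mean[:, None] + self._phi @ (la.lower @ za)).T
            out["beta_draws"] = (beta_mean[:, None] + self._phi @ (lb.lower @ zb)).T
        return out

    # -- fitting -------------------------------------------------------------

    def fit(
        self,
        sampler_config: SamplerConfig | None = None,
        fixed_hyperparameters: np.ndarray | dict | None = None,
        n_func_draws_per_hyper: int = 5,
    ) -> "EventModelResults":
        config = sampler_config or SamplerConfig(n_steps=120, n_warmup=70, n_keep=110)
        if fixed_hyperparameters is not None:
            if isinstance(fixed_hyperparameters, dict):
                theta = self.pack(**fixed_hyperparameters)
            else:
                theta = np.asarray(fixed_hyperparameters, float)
            hyper_draws = theta[None, :]
            diagnostics = {"fixed_hyperparameters": True}
            n_func = max(n_func_draws_per_hyper, 500)
        else:
            # the hierarchical-spread coordinate has a degenerate MAP
            # (funnel); keep it fixed during the warm-start optimization
            res = run_ensemble(self.log_posterior, self._start(), config,
                               optimize_frozen=(self.dim - 1,))
            hyper_draws = res.draws
            diagnostics = res.diagnostics
            n_func = n_func_draws_per_hyper

        rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0xE7E)))
        n_hyper = hyper_draws.shape[0]
        acc = {k: [] for k in ("mu", "r", "alpha", "beta", "a", "b",
                               "fitted", "climate_pred", "alpha_draws", "beta_draws",
                               "sigma")}
        for d in range(n_hyper):
            c = self._conditional(hyper_draws[d], rng, n_func)
            acc["mu"].append(c["mu_mean"])
            acc["r"].append(c["r_mean"])
            acc["alpha"].append(c["alpha_mean"])
            acc["beta"].append(c["beta_mean"])
            acc["a"].append(c["a_mean"])
            acc["b"].append(c["b_mean"])
            acc["fitted"].append(c["fitted_mean"])
            acc["climate_pred"].append(c["climate_pred_mean"])
            acc["alpha_draws"].append(c["alpha_draws"])
            acc["beta_draws"].append(c["beta_draws"])
            acc["sigma"].append(c["h"]["sigma"])

        return EventModelResults(
            model=self,
            grid=self.grid.copy(),
            park_ids=list(self.parks),
            hyper_draws=pd.DataFrame(hyper_draws, columns=self.param_names),
            mu_mean=float(np.mean(acc["mu"])),
            r_mean=np.mean(acc["r"], axis=0),
            alpha_mean=np.mean(acc["alpha"], axis=0),
            beta_mean=np.mean(acc["beta"], axis=0),
            a_mean=np.mean(acc["a"], axis=0),
            b_mean=np.mean(acc["b"], axis=0),
            fitted_mean=np.mean(acc["fitted"], axis=0),
            climate_pred_mean=np.mean(acc["climate_pred"], axis=0),
            alpha_draws=np.concatenate(acc["alpha_draws"]),
            beta_draws=np.concatenate(acc["beta_draws"]),
            sigma_draws=np.array(acc["sigma"]),
            diagnostics=diagnostics,
        )


@dataclass
class CredibilitySurface:
    """P_post(sum of a coefficient over [t1, t2] >= 0) on the upper triangle."""

    coefficient: str
    grid: np.ndarray
    matrix: np.ndarray  # (L, L), NaN below the diagonal; rows t1, cols t2

    def at(self, t1: int, t2: int) -> float:
        if t1 > t2:
            raise IndexError(f"need t1 <= t2, got ({t1}, {t2})")
        i = int(np.where(self.grid == t1)[0][0])
        j = int(np.where(self.grid == t2)[0][0])
        return float(self.matrix[i, j])

    def to_csv(self, path) -> None:
        pd.DataFrame(self.matrix, index=self.grid.astype(int),
                     columns=self.grid.astype(int)).to_csv(path)


@dataclass
class EventModelResults:
    """Posterior summaries of a fitted :class:`EventDateModel`."""

    model: EventDateModel
    grid: np.ndarray
    park_ids: list
    hyper_draws: pd.DataFrame
    mu_mean: float
    r_mean: np.ndarray
    alpha_mean: np.ndarray          # (L,) days per °C
    beta_mean: np.ndarray           # (L,) days per cm
    a_mean: np.ndarray              # (p, L)
    b_mean: np.ndarray              # (p, L)
    fitted_mean: np.ndarray         # (n,) posterior-mean full linear predictor
    climate_pred_mean: np.ndarray   # (n,) posterior-mean climate sums only
    alpha_draws: np.ndarray         # (D, L) pooled coefficient draws
    beta_draws: np.ndarray
    sigma_draws: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    MIN_DRAWS = 500

    @property
    def n_draws(self) -> int:
        return self.alpha_draws.shape[0]

    def _draws(self, coefficient: str) -> np.ndarray:
        if coefficient not in ("alpha", "beta"):
            raise ValueError(f"coefficient must be 'alpha' or 'beta', got {coefficient!r}")
        draws = self.alpha_draws if coefficient == "alpha" else self.beta_draws
        if draws.shape[0] < self.MIN_DRAWS:
            raise ValueError(
                f"{draws.shape[0]} coefficient draws < required {self.MIN_DRAWS}; "
                "increase n_keep or n_func_draws_per_hyper"
            )
        return draws

    # -- posterior summaries ---------------------------------------------------

    def window_sum_credibility(self, coefficient: str = "alpha") -> CredibilitySurface:
        """P(sum over [t1, t2] of the coefficient >= 0) for every window."""
        draws = self._draws(coefficient)
        csum = np.concatenate(
            [np.zeros((draws.shape[0], 1)), np.cumsum(draws, axis=1)], axis=1
        )
        L = self.grid.size
        mat = np.full((L, L), np.nan)
        for i in range(L):
            sums = csum[:, i + 1:] - csum[:, i:i + 1]     # windows starting at i
            mat[i, i:] = np.mean(sums >= 0, axis=0)
        return CredibilitySurface(coefficient=coefficient, grid=self.grid.copy(), matrix=mat)

    def pointwise_sign_credibility(
        self, coefficient: str = "alpha", threshold: float = 0.95
    ) -> list[tuple[int, int]]:
        """Maximal runs of days with P(coef(t) < 0) above the threshold."""
        draws = self._draws(coefficient)
        p_neg = np.mean(draws < 0, axis=0)
        days = self.grid[p_neg > threshold].astype(int)
        runs = []
        for d in days:
            if runs and d == runs[-1][1] + 1:
                runs[-1] = (runs[-1][0], d)
            else:
                runs.append((d, d))
        return runs

    def variance_explained(self) -> dict:
        """Total R^2 and the climate-component share after removing park means, %.

        ``total_pct`` is 1 - Var(z - posterior-mean linear predictor)/Var(z).
        ``climate_pct`` is the variance share of the posterior-mean climate
        sums in the park-mean-centered response, Var(pred_c)/Var(z_c) —
        the same component/total form the trajectory-model partition
        uses.  The residual-subtraction variant
        1 - Var(z_c - pred_c)/Var(z_c) is also reported
        (``climate_subtraction_pct``); being an in-sample fit statistic
        it absorbs roughly 2*dof/n of pure noise-fitting for a flexible
        posterior-mean smoother and therefore does not vanish under a
        climate-free null, which is why the share is the headline number.
        """
        z = self.model.z
        var_z = float(np.var(z))
        if var_z <= 0:
            raise ValueError("zero response variance; R^2 undefined")
        total = 1.0 - float(np.var(z - self.fitted_mean)) / var_z

        park_mean = np.zeros_like(z)
        for rows in self.model._park_rows:
            park_mean[rows] = z[rows].mean()
        zc = z - park_mean
        cp = self.climate_pred_mean
        cpc = cp.copy()
        for rows in self.model._park_rows:
            cpc[rows] -= cp[rows].mean()
        var_zc = float(np.var(zc))
        return {
            "total_pct": 100.0 * total,
            "climate_pct": 100.0 * float(np.var(cpc)) / var_zc,
            "climate_subtraction_pct": 100.0 * (1.0 - float(np.var(zc - cpc)) / var_zc),
        }

    def predict_event_shift(
        self, window: tuple[int, int], delta: float = 1.0, variable: str = "temperature"
    ) -> dict:
        """Expected shift (days) for a per-day ``delta`` change over ``window``.

        Negative means the event happens earlier.  Summarized over
        posterior coefficient draws; Monte-Carlo error reported.
        """
        t1, t2 = window
        if t1 > t2 or t1 < self.grid[0] or t2 > self.grid[-1]:
            raise IndexError(f"window {window} outside season grid "
                             f"[{self.grid[0]:.0f}, {self.grid[-1]:.0f}]")
        coefficient = "alpha" if variable.startswith("temp") else "beta"
        draws = self._draws(coefficient)
        i = int(np.where(self.grid == t1)[0][0])
        j = int(np.where(self.grid == t2)[0][0])
        shifts = delta * draws[:, i:j + 1].sum(axis=1)
        return {
            "mean_days": float(np.mean(shifts)),
            "sd_days": float(np.std(shifts)),
            "mc_error": float(np.std(shifts) / np.sqrt(len(shifts))),
        }

    def loo_lpd(self) -> dict:
        """Exact-refit leave-one-out log predictive density, summed over events.

        For each hyperparameter draw the Gaussian layer is re-solved
        without each observation in closed form (equivalent to an exact
        refit of all Gaussian parameters); the predictive density is the
        average over hyperparameter draws.  Hyperparameters themselves
        come from the full-data posterior.
        """
        model = self.model
        thetas = self.hyper_draws.to_numpy()
        resid = model.z - model.priors.mu_mean
        dens = np.zeros((thetas.shape[0], model.n))
        for d, theta in enumerate(thetas):
            h = model._unpack(theta)
            chol = chol_with_jitter(model._marginal_cov(h))
            mean_r, var = loo_gaussian_moments(chol, resid)
            dens[d] = np.exp(-0.5 * np.log(2 * np.pi * var)
                             - 0.5 * (resid - mean_r) ** 2 / var)
        per_obs = np.log(np.mean(dens, axis=0))
        return {
            "total_lpd": float(np.sum(per_obs)),
            "per_obs_lpd": per_obs,
            "n": int(model.n),
        }

    # -- output --------------------------------------------------------------

    def coefficient_table(self) -> pd.DataFrame:
        qa = np.quantile(self.alpha_draws, [0.05, 0.95], axis=0)
        qb = np.quantile(self.beta_draws, [0.05, 0.95], axis=0)
        out = pd.DataFrame({
            "day": self.grid.astype(int),
            "alpha_mean": self.alpha_mean, "alpha_q5": qa[0], "alpha_q95": qa[1],
            "beta_mean": self.beta_mean, "beta_q5": qb[0], "beta_q95": qb[1],
        })
        for i, pk in enumerate(self.park_ids):
            out[f"a_{pk}_mean"] = self.a_mean[i]
            out[f"b_{pk}_mean"] = self.b_mean[i]
        return out

    def summary(self) -> str:
        ve = self.variance_explained()
        runs = self.pointwise_sign_credibility("alpha")
        lines = [
            "Time-varying-coefficient event-date model",
            "=" * 48,
            f"event kind: {self.model.event_kind}   observations: {self.model.n}"
            f"   parks: {len(self.park_ids)}   season grid: "
            f"{self.grid[0]:.0f}..{self.grid[-1]:.0f}",
            f"overall mean day mu: {self.mu_mean:.1f}",
            f"variance explained: total {ve['total_pct']:.1f}%, "
            f"climate after park-centering {ve['climate_pct']:.1f}%",
            f"days with P(alpha<0)>0.95: {runs if runs else 'none'}",
            f"coefficient draws: {self.n_draws}",
        ]
        if "max_rhat" in self.diagnostics:
            lines.append(
                f"max split-R-hat {self.diagnostics['max_rhat']:.3f}, "
                f"min bulk ESS {self.diagnostics['min_ess']:.0f}"
            )
        return "\n".join(lines)
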