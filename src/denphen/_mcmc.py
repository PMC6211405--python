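"""Hyperparameter MCMC shared by both hierarchical models.

Both fits integrate the linear-Gaussian layer out analytically and
sample only the kernel/variance hyperparameters (on log scale) from the
marginal posterior.  The ensemble sampler from :mod:`emcee` does the
sampling; a short derivative-free optimization first moves the walkers
into the high-posterior region so that modest chain lengths suffice.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import emcee

log = logging.getLogger(__name__)

__all__ = ["SamplerConfig", "run_ensemble", "EnsembleResult"]


@dataclass(frozen=True)
class SamplerConfig:
    """Budget and seeding for the hyperparameter ensemble sampler.

    ``n_keep`` hyperparameter draws are thinned from the post-warmup
    chain for downstream conditional-Gaussian summaries.
    """

    n_walkers: int | None = None   # default: 2*dim + 6, even
    n_steps: int = 220
    n_warmup: int = 150
    n_keep: int = 120
    seed: int = 0
    optimize_first: bool = True
    optimize_budget: int = 1200


@dataclass
class EnsembleResult:
    draws: np.ndarray              # (n_keep, dim), thinned post-warmup
    chain: np.ndarray              # (n_steps, n_walkers, dim)
    log_prob: np.ndarray           # (n_steps, n_walkers)
    diagnostics: dict


def _optimize_start(log_post, x0: np.ndarray, budget: int,
                    frozen: tuple[int, ...] = ()) -> np.ndarray:
    """Powell warm start; ``frozen`` coordinates stay at their x0 values.

    Freezing is used for hierarchical-spread parameters whose profile
    density is unbounded at zero spread (the usual funnel): the MAP over
    those coordinates is degenerate, while the posterior itself is
    proper and left to the sampler.
    """
    from scipy.optimize import minimize

    free = np.array([i for i in range(x0.size) if i not in frozen])

    def neg(xf):
        x = x0.copy()
        x[free] = xf
        return -log_post(x)

    res = minimize(neg, x0[free], method="Powell",
                   options={"maxfev": budget, "xtol": 1e-3, "ftol": 1e-4})
    if not np.isfinite(res.fun) or res.fun > -log_post(x0):
        return x0
    out = x0.copy()
    out[free] = res.x
    return out


def run_ensemble(
    log_post,
    x0: np.ndarray,
    config: SamplerConfig,
    init_scale: float | np.ndarray = 0.1,
    optimize_frozen: tuple[int, ...] = (),
) -> EnsembleResult:
    """Sample ``log_post`` starting near ``x0``; fully deterministic per seed."""
    x0 = np.asarray(x0, dtype=float)
    dim = x0.size
    nw = config.n_walkers or max(2 * dim + 6, 16)
    if nw % 2:
        nw += 1
    if nw < 2 * dim:
        raise ValueError(f"need at least {2 * dim} walkers for dim={dim}, got {nw}")

    if config.optimize_first:
        x0 = _optimize_start(log_post, x0, config.optimize_budget,
                             frozen=optimize_frozen)

    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 0x5A17)))
    p0 = x0[None, :] + init_scale * rng.standard_normal((nw, dim))
    # make sure every walker starts at finite posterior
    lp0 = np.array([log_post(p) for p in p0])
    bad = ~np.isfinite(lp0)
    for j in np.where(bad)[0]:
        for _ in range(50):
            cand = x0 + 0.02 * rng.standard_normal(dim)
            if np.isfinite(log_post(cand)):
                p0[j] = cand
                break
        else:
            p0[j] = x0

    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(nw, dim, log_post, moves=moves)
    state = emcee.State(p0, random_state=np.random.RandomState(config.seed % (2**31)).get_state())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sampler.run_mcmc(state, config.n_steps, progress=False, skip_initial_state_check=True)

    chain = sampler.get_chain()                      # (steps, walkers, dim)
    lp = sampler.get_log_prob()
    post = chain[config.n_warmup:].reshape(-1, dim)  # walkers flattened
    idx = np.linspace(0, post.shape[0] - 1, min(config.n_keep, post.shape[0])).astype(int)
    draws = post[idx]

    diagnostics = _diagnostics(chain[config.n_warmup:], lp[config.n_warmup:])
    return EnsembleResult(draws=draws, chain=chain, log_prob=lp, diagnostics=diagnostics)


def _diagnostics(chain: np.ndarray, log_prob: np.ndarray) -> dict:
    """Split-R-hat and bulk ESS per parameter via arviz, walkers as chains."""
    import arviz as az

    # arviz expects (chain, draw, ...); cap chains to keep this cheap
    sub = chain[:, : min(chain.shape[1], 16), :]
    data = np.moveaxis(sub, 0, 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(az.convert_to_dataset(data))["x"].values
        ess = az.ess(az.convert_to_dataset(data))["x"].values
    max_rhat = float(np.nanmax(rhat))
    if max_rhat > 1.05:
        log.warning("max split-R-hat %.3f > 1.05: chains may be too short", max_rhat)
    return {
        "rhat": np.asarray(rhat),
        "ess_bulk": np.asarray(ess),
        "max_rhat": max_rhat,
        "min_ess": float(np.nanmin(ess)),
        "mean_log_prob": float(np.mean(log_prob)),
    }


def half_normal_logpdf(x: np.ndarray | float, scale: float) -> float:
    """log density of |N(0, scale^2)| evaluated at x >= 0."""
    x = np.asarray(x, float)
    return float(np.sum(
        0.5 * np.log(2.0 / np.pi) - np.log(scale) - 0.5 * (x / scale) ** 2
    ))


def lognormal_logpdf(x: np.ndarray | float, mu: float, sigma: float) -> float:
    """log density of LogNormal(mu, sigma^2) at x > 0."""
    x = np.asarray(x, float)
    return float(np.sum(
        -np.log(x) - np.log(sigma) - 0.5 * np.log(2 * np.pi)
        - 0.5 * ((np.log(x) - mu) / sigma) ** 2
    ))


def normal_logpdf(x: np.ndarray | float, mu: float, sigma: float) -> float:
    x = np.asarray(x, float)
    return float(np.sum(
        -np.log(sigma) - 0.5 * np.log(2 * np.pi) - 0.5 * ((x - mu) / sigma) ** 2
    ))
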