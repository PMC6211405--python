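"""Dense linear-Gaussian primitives shared by both model fits.

Everything here is exact: Cholesky-based multivariate-normal log
densities, conditional distributions, and closed-form per-observation
leave-one-out predictive moments.  Jitter is added to a covariance
diagonal only when plain factorization fails, and the amount used is
recorded on the returned object.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

log = logging.getLogger(__name__)

__all__ = ["CholFactor", "chol_with_jitter", "mvn_logpdf", "conditional_gaussian"]

_JITTERS = (0.0, 1e-10, 1e-8, 1e-6, 1e-4)


@dataclass
class CholFactor:
    """Lower Cholesky factor of a covariance matrix, plus the jitter used."""

    lower: np.ndarray
    jitter: float

    def solve(self, b: np.ndarray) -> np.ndarray:
        return cho_solve((self.lower, True), b)

    def half_solve(self, b: np.ndarray) -> np.ndarray:
        """L^{-1} b, so that ||half_solve(x)||^2 = x' K^{-1} x."""
        return solve_triangular(self.lower, b, lower=True)

    @property
    def logdet(self) -> float:
        return 2.0 * float(np.sum(np.log(np.diag(self.lower))))


def chol_with_jitter(cov: np.ndarray, scale: float | None = None) -> CholFactor:
    """Cholesky-factor ``cov``, escalating diagonal jitter on failure.

    Jitter is relative to ``scale`` (default: mean diagonal entry), tried
    in increasing steps; the amount finally used is logged and stored.
    """
    cov = np.asarray(cov, dtype=float)
    if not np.all(np.isfinite(cov)):
        raise np.linalg.LinAlgError("covariance contains non-finite entries")
    if scale is None:
        scale = float(np.mean(np.diag(cov))) or 1.0
    for j in _JITTERS:
        try:
            c, _ = cho_factor(cov + j * scale * np.eye(cov.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            continue
        if j > 0:
            log.debug("added diagonal jitter %.1e * %.3g for factorization", j, scale)
        return CholFactor(np.tril(c), j * scale)
    raise np.linalg.LinAlgError("covariance not factorizable even with jitter")


def mvn_logpdf(x: np.ndarray, mean: np.ndarray, chol: CholFactor) -> float:
    r = np.asarray(x, float) - np.asarray(mean, float)
    u = chol.half_solve(r)
    n = r.shape[0]
    return float(-0.5 * (n * np.log(2.0 * np.pi) + chol.logdet + u @ u))


def conditional_gaussian(
    prior_mean_f: np.ndarray,
    cross_cov: np.ndarray,
    prior_cov_f: np.ndarray | None,
    obs_chol: CholFactor,
    obs_resid: np.ndarray,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Posterior of a Gaussian vector f given jointly Gaussian observations y.

    Parameters are the prior mean of f, Cov(f, y), the prior covariance of
    f (``None`` to skip the posterior covariance), the Cholesky factor of
    Cov(y), and the observed residual ``y - E[y]``.  Returns the posterior
    mean, and the posterior covariance unless skipped.
    """
    alpha = obs_chol.solve(obs_resid)
    mean = prior_mean_f + cross_cov @ alpha
    if prior_cov_f is None:
        return mean, None
    v = obs_chol.half_solve(cross_cov.T)
    cov = prior_cov_f - v.T @ v
    return mean, cov


def loo_gaussian_moments(
    chol: CholFactor, resid: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact leave-one-out predictive moments of a joint Gaussian.

    For y ~ N(m, K) with residual ``resid = y - m``, returns per-entry
    conditional means and variances of y_j given all other entries —
    equivalent to refitting the Gaussian layer without observation j.
    Uses the precision-matrix identities mu_j = y_j - [K^{-1} r]_j / P_jj,
    var_j = 1 / P_jj with P = K^{-1}.
    """
    n = resid.shape[0]
    kinv = cho_solve((chol.lower, True), np.eye(n))
    pdiag = np.diag(kinv)
    alpha = kinv @ resid
    var = 1.0 / pdiag
    mean = (resid - alpha / pdiag)  # residual-scale conditional mean
    return mean, var
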