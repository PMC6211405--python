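"""Covariance kernels on 1-D day grids.

Two families are used throughout the package: the squared-exponential
kernel for smooth mean functions (seasonal averages, slowly varying
regression coefficients) and the exponential (Ornstein--Uhlenbeck)
kernel for rough, mean-reverting daily residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KernelSpec", "build_kernel_matrix", "se_kernel", "exponential_kernel"]

_FAMILIES = ("squared_exponential", "exponential")


@dataclass(frozen=True)
class KernelSpec:
    """A stationary covariance function on a day grid.

    Parameters
    ----------
    family : str
        ``"squared_exponential"`` or ``"exponential"``.
    variance : float
        Marginal variance (units of the modelled quantity, squared).
    length_scale : float
        Length-scale in days (the "range" of the exponential kernel).
    """

    family: str
    variance: float
    length_scale: float

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(
                f"unknown kernel family {self.family!r}; expected one of {_FAMILIES}"
            )
        if not self.variance >= 0:
            raise ValueError(f"kernel variance must be >= 0, got {self.variance}")
        if not self.length_scale > 0:
            raise ValueError(
                f"kernel length_scale must be > 0, got {self.length_scale}"
            )

    def __call__(self, grid: np.ndarray, grid2: np.ndarray | None = None) -> np.ndarray:
        return build_kernel_matrix(self, grid, grid2)


def se_kernel(variance: float, length_scale: float) -> KernelSpec:
    return KernelSpec("squared_exponential", variance, length_scale)


def exponential_kernel(variance: float, range_: float) -> KernelSpec:
    return KernelSpec("exponential", variance, range_)


def build_kernel_matrix(
    spec: KernelSpec, grid: np.ndarray, grid2: np.ndarray | None = None
) -> np.ndarray:
    """Evaluate the kernel on all pairs of ``grid`` x ``grid2`` points.

    With ``grid2 is None`` the result is the symmetric PSD covariance
    matrix of the process on ``grid``.  No jitter is added here; callers
    that factorize add it only on factorization failure (see
    :func:`denphen.gaussian.chol_with_jitter`).
    """
    t1 = np.asarray(grid, dtype=float)
    t2 = t1 if grid2 is None else np.asarray(grid2, dtype=float)
    if t1.ndim != 1 or t2.ndim != 1:
        raise ValueError("kernel grids must be one-dimensional")
    if not (np.all(np.isfinite(t1)) and np.all(np.isfinite(t2))):
        raise ValueError("kernel grids must be finite")
    d = t1[:, None] - t2[None, :]
    if spec.family == "squared_exponential":
        k = spec.variance * np.exp(-0.5 * (d / spec.length_scale) ** 2)
    else:
        k = spec.variance * np.exp(-np.abs(d) / spec.length_scale)
    return k
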