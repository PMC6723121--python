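"""Legendre-polynomial covariates for random-regression test-day models.

A longitudinal trait measured at T discrete time points is modelled as a
curve in a low-order polynomial basis.  Following standard test-day-model
practice the time axis is mapped affinely onto [-1, 1] and *normalized*
Legendre polynomials are used as covariates,

    phi_k(x) = sqrt((2k + 1) / 2) * P_k(x),

so that the basis is orthonormal on [-1, 1].  The T x (k+1) matrix of
covariates evaluated at the standardized time points is shared between the
phenotype simulator and the mixed-model design matrices, which keeps the
generating model and the fitted model in the same parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre as npleg

__all__ = [
    "TimeGrid",
    "standardize_times",
    "legendre_matrix",
    "trajectory_variance",
    "heritability_trajectory",
]


@dataclass(frozen=True)
class TimeGrid:
    """Ordered test time points and their standardized positions in [-1, 1]."""

    time_points: np.ndarray
    standardized: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        tp = np.asarray(self.time_points, dtype=float)
        object.__setattr__(self, "time_points", tp)
        object.__setattr__(self, "standardized", standardize_times(tp))

    def __len__(self) -> int:
        return len(self.time_points)


def standardize_times(time_points) -> np.ndarray:
    """Map ordered time points affinely onto [-1, 1].

    The earliest point maps to -1, the latest to +1; ordering is preserved.

    Raises
    ------
    ValueError
        If fewer than two distinct time points are supplied.
    """
    t = np.asarray(time_points, dtype=float)
    if t.ndim != 1 or np.unique(t).size < 2:
        raise ValueError("need at least 2 distinct time points to standardize")
    lo, hi = t.min(), t.max()
    return 2.0 * (t - lo) / (hi - lo) - 1.0


def legendre_matrix(grid, order: int = 1) -> np.ndarray:
    """Matrix of normalized Legendre covariates, one row per time point.

    Entry (t, k) is sqrt((2k+1)/2) * P_k(x_t) with x_t the standardized
    time.  Accepts a :class:`TimeGrid` or a vector of standardized times.
    """
    if order < 0:
        raise ValueError("polynomial order must be >= 0")
    x = grid.standardized if isinstance(grid, TimeGrid) else np.asarray(grid, dtype=float)
    cols = []
    for k in range(order + 1):
        coef = np.zeros(k + 1)
        coef[k] = 1.0
        cols.append(np.sqrt((2 * k + 1) / 2.0) * npleg.legval(x, coef))
    return np.column_stack(cols)


def trajectory_variance(C: np.ndarray, L: np.ndarray) -> np.ndarray:
    """Variance contributed by a coefficient covariance C along the trajectory.

    Element t is phi(x_t)' C phi(x_t).  C must be symmetric PSD.
    """
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1] or not np.allclose(C, C.T):
        raise ValueError("C must be a symmetric square matrix")
    L = np.asarray(L, dtype=float)
    return np.einsum("ti,ij,tj->t", L, C, L)


def heritability_trajectory(G, P, sigma_e2: float, L: np.ndarray) -> np.ndarray:
    """Heritability h2(t) = g(t) / (g(t) + p(t) + sigma_e2) at every time point."""
    if sigma_e2 <= 0:
        raise ValueError("residual variance must be positive")
    g = trajectory_variance(G, L)
    p = trajectory_variance(P, L)
    return g / (g + p + sigma_e2)
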