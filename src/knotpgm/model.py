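"""Linear-linear piecewise growth model (PGM) core.

A linear-linear PGM is a latent growth curve model whose mean trajectory
consists of two linear segments joined at a knot (changepoint) ``gamma``.
Each subject ``i`` observed at occasions ``t_1 < ... < t_J`` follows

.. math::

    y_i = \\Lambda(\\gamma)\\,\\eta_i + \\epsilon_i, \\qquad
    \\eta_i \\sim \\mathcal{N}(\\alpha, \\Omega_\\eta), \\qquad
    \\epsilon_i \\sim \\mathcal{N}(0, \\mathrm{diag}(\\sigma^2_\\epsilon)),

where the three growth factors in ``eta_i`` are the intercept, the
pre-knot slope and the post-knot slope, and row ``j`` of the loading
matrix is ``[1, min(t_j, gamma), max(t_j - gamma, 0)]``.

This module provides the loading matrix, the model-implied mean and
covariance of the observations, and the observed-data (marginal
multivariate normal) log-likelihood used to test the sampler.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class TimeGrid:
    """An ordered set of measurement occasions on the study time scale.

    Parameters
    ----------
    codes : array-like of float
        Strictly increasing time codes ``t_1 .. t_J``.  At least five
        occasions are required to identify a linear-linear PGM with a
        freely estimated knot.
    """

    codes: np.ndarray

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=float)
        if codes.ndim != 1:
            raise ValueError("time codes must be a 1-D vector")
        if codes.size < 5:
            raise ValueError(
                "a linear-linear piecewise growth model needs at least "
                f"five occasions; got {codes.size}"
            )
        if not np.all(np.diff(codes) > 0):
            raise ValueError("time codes must be strictly increasing")
        object.__setattr__(self, "codes", codes)

    @property
    def n_occasions(self) -> int:
        return self.codes.size

    @property
    def lower(self) -> float:
        return float(self.codes[0])

    @property
    def upper(self) -> float:
        return float(self.codes[-1])

    @classmethod
    def default(cls) -> "TimeGrid":
        """Seven equidistant occasions coded 0..6."""
        return cls(np.arange(7.0))

    def is_default(self) -> bool:
        return self.n_occasions == 7 and np.allclose(self.codes, np.arange(7.0))


@dataclass
class PGMParameters:
    """Population (or candidate) parameter values of the PGM.

    Attributes
    ----------
    alpha : (3,) ndarray
        Growth-factor means: intercept, pre-knot slope, post-knot slope.
    omega_eta : (3, 3) ndarray
        Symmetric positive-semidefinite growth-factor covariance.
    sigma2_eps : (J,) ndarray
        Residual variances, one per occasion (diagonal residual
        covariance; heteroscedastic by occasion).
    gamma : float
        Knot location on the time-code scale.
    """

    alpha: np.ndarray
    omega_eta: np.ndarray
    sigma2_eps: np.ndarray
    gamma: float

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float).reshape(3)
        self.omega_eta = np.asarray(self.omega_eta, dtype=float).reshape(3, 3)
        self.sigma2_eps = np.atleast_1d(np.asarray(self.sigma2_eps, dtype=float))
        self.gamma = float(self.gamma)

    def validate(self, grid: TimeGrid) -> None:
        """Check invariants against a time grid; raise ``ValueError`` if violated."""
        if self.sigma2_eps.size != grid.n_occasions:
            raise ValueError(
                "sigma2_eps must have one entry per occasion "
                f"({grid.n_occasions}); got {self.sigma2_eps.size}"
            )
        if np.any(self.sigma2_eps < 0):
            raise ValueError("residual variances must be non-negative")
        if not np.allclose(self.omega_eta, self.omega_eta.T, atol=1e-10):
            raise ValueError("omega_eta must be symmetric")
        if np.linalg.eigvalsh(self.omega_eta).min() < -1e-10:
            raise ValueError("omega_eta must be positive semidefinite")
        if not (grid.lower < self.gamma < grid.upper):
            raise ValueError(
                f"knot gamma={self.gamma} must lie strictly inside "
                f"({grid.lower}, {grid.upper}) for data generation"
            )


@dataclass
class LongitudinalDataset:
    """A wide-format longitudinal outcome matrix with a missingness mask.

    ``values[i, j]`` is subject ``i``'s outcome at occasion ``j``;
    ``mask[i, j]`` is True where the value is observed.  Unobserved cells
    hold ``NaN``.
    """

    values: np.ndarray
    mask: np.ndarray
    grid: TimeGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2 or self.values.shape != self.mask.shape:
            raise ValueError("values and mask must be matching n x J matrices")
        if self.values.shape[1] != self.grid.n_occasions:
            raise ValueError("column count must match the time grid")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("observed values must be finite")
        if self.n > 0 and not np.all(self.mask.any(axis=1)):
            bad = np.flatnonzero(~self.mask.any(axis=1))
            raise ValueError(
                f"every subject needs at least one observed occasion; "
                f"rows {bad.tolist()} have none"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_missing(self) -> int:
        return int((~self.mask).sum())

    def missing_fraction_by_occasion(self) -> np.ndarray:
        """Empirical fraction of missing values at each occasion."""
        return (~self.mask).mean(axis=0)


def build_loading_matrix(grid: TimeGrid, gamma: float) -> np.ndarray:
    """Build the J x 3 piecewise-linear loading matrix for knot ``gamma``.

    Row ``j`` is ``[1, min(t_j, gamma), max(t_j - gamma, 0)]``.  The knot
    may sit exactly on a grid boundary (needed by truncated knot priors);
    values outside the grid range are a domain error.

    Examples
    --------
    >>> lam = build_loading_matrix(TimeGrid.default(), 3.0)
    >>> lam[:, 1]
    array([0., 1., 2., 3., 3., 3., 3.])
    """
    gamma = float(gamma)
    if not (grid.lower <= gamma <= grid.upper):
        raise ValueError(
            f"knot gamma={gamma} outside the grid range "
            f"[{grid.lower}, {grid.upper}]"
        )
    t = grid.codes
    return np.column_stack(
        [np.ones_like(t), np.minimum(t, gamma), np.maximum(t - gamma, 0.0)]
    )


def implied_moments(
    params: PGMParameters, grid: TimeGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean vector and covariance matrix of ``y_i``.

    Returns
    -------
    mean : (J,) ndarray
        ``Lambda(gamma) @ alpha``.
    cov : (J, J) ndarray
        ``Lambda Omega_eta Lambda' + diag(sigma2_eps)``; positive
        definite whenever all residual variances are positive.
    """
    if np.linalg.eigvalsh(np.asarray(params.omega_eta, float)).min() < -1e-10:
        raise ValueError("omega_eta must be positive semidefinite")
    lam = build_loading_matrix(grid, params.gamma)
    mean = lam @ params.alpha
    cov = lam @ params.omega_eta @ lam.T + np.diag(params.sigma2_eps)
    return mean, cov


def observed_data_loglik(data: LongitudinalDataset, params: PGMParameters) -> float:
    """Marginal multivariate-normal log-likelihood of the observed entries.

    Each subject contributes the log density of their observed subvector
    under the implied moments restricted to observed occasions; missing
    entries are integrated out analytically.  Subjects are grouped by
    missingness pattern so each distinct pattern costs one density setup.
    """
    if data.n == 0:
        return 0.0
    mean, cov = implied_moments(params, data.grid)
    patterns, inverse = np.unique(data.mask, axis=0, return_inverse=True)
    total = 0.0
    for k, pattern in enumerate(patterns):
        if not pattern.any():
            raise ValueError("subject with zero observed occasions")
        rows = np.flatnonzero(inverse == k)
        obs = np.flatnonzero(pattern)
        sub = data.values[np.ix_(rows, obs)]
        total += float(
            stats.multivariate_normal.logpdf(
                sub, mean=mean[obs], cov=cov[np.ix_(obs, obs)]
            ).sum()
        )
    return total
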