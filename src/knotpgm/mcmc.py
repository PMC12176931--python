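"""Metropolis-within-Gibbs sampler for the Bayesian piecewise growth model.

All linear parameter blocks have conjugate full conditionals and are
updated by Gibbs steps; the knot location, whose full conditional is
nonstandard, is updated by a random-walk Metropolis step on the truncated
prior support.  Missing outcomes are treated as extra unknowns and drawn
from their conditional normal distributions each iteration (data
augmentation), so every other update sees complete data.

Update order within an iteration:

1. missing ``y_ij ~ N((Lambda eta_i)_j, sigma2_j)`` (data augmentation);
2. growth factors ``eta_i`` from their multivariate-normal conditional;
3. factor means ``alpha`` from their normal conditional;
4. factor covariance ``Omega_eta`` from its inverse-Wishart conditional;
5. each residual variance ``sigma2_j`` from its inverse-gamma conditional;
6. knot ``gamma`` by random-walk Metropolis against the complete-data
   likelihood times the knot prior; proposals outside the truncation
   support are rejected through the prior's ``-inf`` log density.

The proposal SD for the knot is adapted during burn-in only (targeting a
25-45% acceptance rate) and frozen afterwards, so the post-burn-in chain
is a valid time-homogeneous Markov chain.

Convergence is screened with the split-chain rank-normalized potential
scale reduction factor (R-hat) on the structural parameters only: the
three factor means, the six unique factor covariance entries, the J
residual variances and the knot.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .model import LongitudinalDataset, build_loading_matrix
from .priors import ModelPriors

_TRIL = np.tril_indices(3)
_TRIL_OFF = np.tril_indices(3, -1)


class SamplingError(RuntimeError):
    """Raised when the sampler encounters a non-finite likelihood."""


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    ``n_iter`` counts post-burn-in iterations per chain; every ``thin``-th
    of these is retained.  Defaults mirror a full-scale analysis (4 chains
    of 25,000 iterations after 5,000 burn-in, thinned by 10).  Use
    :meth:`scaled` for a desk-scale protocol.
    """

    n_chains: int = 4
    n_iter: int = 25_000
    burn_in: int = 5_000
    thin: int = 10
    seed: int | np.random.SeedSequence | None = None
    rhat_threshold: float = 1.1
    rhat_method: str = "rank"
    knot_proposal_sd: float = 0.2
    adapt_window: int = 50

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need at least two chains for R-hat screening")
        if self.thin < 1 or self.burn_in < 0 or self.n_iter < self.thin:
            raise ValueError("invalid iteration plan")

    @classmethod
    def scaled(cls, seed=None, **overrides) -> "MCMCConfig":
        """Reduced protocol: 2 chains, 1,000 burn-in, 4,000 kept, thin 1."""
        base = dict(n_chains=2, n_iter=4_000, burn_in=1_000, thin=1, seed=seed)
        base.update(overrides)
        return cls(**base)

    def with_seed(self, seed) -> "MCMCConfig":
        return replace(self, seed=seed)


@dataclass
class PosteriorResult:
    """Thinned post-burn-in draws plus diagnostics for one model fit."""

    draws: np.ndarray  # (n_chains, n_kept, n_params)
    param_names: list[str]
    rhat: np.ndarray  # per parameter
    converged: bool
    knot_acceptance: float
    config: MCMCConfig

    @property
    def pooled(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def gamma_draws(self) -> np.ndarray:
        return self.pooled[:, self.param_names.index("gamma")]

    def to_tidy(self) -> pd.DataFrame:
        """Long-format draws: chain, iteration, parameter, value."""
        n_chains, n_kept, n_par = self.draws.shape
        return pd.DataFrame(
            {
                "chain": np.repeat(np.arange(n_chains), n_kept * n_par),
                "iteration": np.tile(np.repeat(np.arange(n_kept), n_par), n_chains),
                "parameter": np.tile(self.param_names, n_chains * n_kept),
                "value": self.draws.reshape(-1),
            }
        )


def _param_names(n_occasions: int) -> list[str]:
    names = [f"alpha[{k}]" for k in (1, 2, 3)]
    names += [f"omega[{i + 1},{j + 1}]" for i, j in zip(*_TRIL)]
    names += [f"sigma2[{j}]" for j in range(1, n_occasions + 1)]
    names.append("gamma")
    return names


# ---------------------------------------------------------------------------
# closed-form 3x3 linear algebra: np.linalg call overhead dominates the
# sampler on these tiny matrices, so Cholesky and SPD inverses are spelled
# out explicitly
# ---------------------------------------------------------------------------


def _chol3(m: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor of a 3x3 SPD matrix."""
    # plain-float arithmetic: numpy scalar ops would dominate at this size
    a, b, c, d, e, f = (
        float(m[0, 0]),
        float(m[1, 0]),
        float(m[2, 0]),
        float(m[1, 1]),
        float(m[2, 1]),
        float(m[2, 2]),
    )
    if a <= 0:
        raise np.linalg.LinAlgError("matrix not positive definite")
    l11 = math.sqrt(a)
    l21 = b / l11
    l31 = c / l11
    t = d - l21 * l21
    if t <= 0:
        raise np.linalg.LinAlgError("matrix not positive definite")
    l22 = math.sqrt(t)
    l32 = (e - l31 * l21) / l22
    t = f - l31 * l31 - l32 * l32
    if t <= 0:
        raise np.linalg.LinAlgError("matrix not positive definite")
    l33 = math.sqrt(t)
    return np.array([[l11, 0.0, 0.0], [l21, l22, 0.0], [l31, l32, l33]])


def _tri_inv3(L: np.ndarray) -> np.ndarray:
    """Inverse of a 3x3 lower-triangular matrix."""
    l21, l31, l32 = float(L[1, 0]), float(L[2, 0]), float(L[2, 1])
    l22 = float(L[1, 1])
    k11, k22, k33 = 1.0 / float(L[0, 0]), 1.0 / l22, 1.0 / float(L[2, 2])
    k21 = -l21 * k11 * k22
    k32 = -l32 * k22 * k33
    k31 = (l21 * l32 - l31 * l22) * k11 * k22 * k33
    return np.array([[k11, 0.0, 0.0], [k21, k22, 0.0], [k31, k32, k33]])


def _spd_inv3(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(inverse, lower Cholesky factor of the inverse) of a 3x3 SPD matrix."""
    K = _tri_inv3(_chol3(m))  # m = L L', so m^-1 = K' K with K = L^-1
    inv = K.T @ K
    return inv, _chol3(inv)


# ---------------------------------------------------------------------------
# conjugate block updates (module-level so tests can exercise them directly)
# ---------------------------------------------------------------------------


def _draw_mvn_prec(rng, prec: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Draw from N(prec^-1 b, prec^-1)."""
    cov, chol = _spd_inv3(prec)
    return cov @ b + chol @ rng.standard_normal(3)


def _update_eta(rng, Y, lam, sigma2, omega_inv, alpha):
    """Vectorized draw of all subjects' growth factors."""
    lam_d = lam / sigma2[:, None]
    prec = lam.T @ lam_d + omega_inv
    cov, chol = _spd_inv3(prec)
    means = (Y @ lam_d + omega_inv @ alpha) @ cov
    return means + rng.standard_normal(means.shape) @ chol.T


_EYE3 = np.eye(3)


def _update_alpha(rng, eta, omega_inv, priors: ModelPriors):
    n = eta.shape[0]
    prec = n * omega_inv + _EYE3 / priors.sigma2_alpha
    b = omega_inv @ eta.sum(axis=0) + priors.mu_alpha / priors.sigma2_alpha
    return _draw_mvn_prec(rng, prec, b)


def _inv_wishart_rvs(rng, df: float, scale: np.ndarray):
    """Bartlett-decomposition draw from IW(scale, df); returns (Omega, Omega_inv).

    If M ~ Wishart(df, I) via the Bartlett construction and B B' equals
    the inverse of ``scale``, then B M B' ~ Wishart(df, scale^-1), whose
    inverse is the desired IW(scale, df) draw.
    """
    if df <= 2:
        raise ValueError("inverse-Wishart degrees of freedom too small")
    L = _chol3(scale)
    B = _tri_inv3(L).T  # B B' = scale^-1
    A = np.zeros((3, 3))
    A[0, 0], A[1, 1], A[2, 2] = np.sqrt(rng.chisquare(df - np.arange(3)))
    A[_TRIL_OFF] = rng.standard_normal(3)
    F = B @ A
    omega_inv = F @ F.T
    K = _tri_inv3(A) @ L.T  # F^-1; omega = F^-T F^-1
    omega = K.T @ K
    return omega, omega_inv


def _update_omega(rng, eta, alpha, priors: ModelPriors):
    zc = eta - alpha
    scale = priors.psi + zc.T @ zc
    return _inv_wishart_rvs(rng, priors.nu + eta.shape[0], scale)


def _update_sigma2(rng, rss: np.ndarray, n: int, priors: ModelPriors):
    shape = priors.a + 0.5 * n
    # with no data and a near-flat IG prior the draw may overflow to inf,
    # which is a legitimate (if extreme) value for a diffuse posterior
    with np.errstate(over="ignore"):
        return (priors.b + 0.5 * rss) / rng.gamma(shape, 1.0, size=rss.shape)


# ---------------------------------------------------------------------------
# chain driver
# ---------------------------------------------------------------------------


def _init_chain(rng, data: LongitudinalDataset, priors: ModelPriors):
    """Dispersed starting values from sample moments and the knot prior."""
    grid = data.grid
    J = grid.n_occasions
    gamma0 = priors.knot.ppf(rng.uniform(0.1, 0.9))
    # guard against boundary starts where the loading matrix is rank-deficient
    width = grid.upper - grid.lower
    gamma0 = min(max(gamma0, grid.lower + 0.02 * width), grid.upper - 0.02 * width)
    lam = build_loading_matrix(grid, gamma0)
    if data.n > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-missing columns yield NaN means
            occ_mean = np.nanmean(np.where(data.mask, data.values, np.nan), axis=0)
            occ_var = np.nanvar(np.where(data.mask, data.values, np.nan), axis=0)
        overall = np.nanmean(occ_mean)
        occ_mean = np.where(np.isfinite(occ_mean), occ_mean, overall)
        occ_var = np.where(np.isfinite(occ_var), occ_var, 1.0)
    else:
        occ_mean = np.zeros(J)
        occ_var = np.ones(J)
    alpha0, *_ = np.linalg.lstsq(lam, occ_mean, rcond=None)
    sigma2_0 = np.clip(occ_var, 1e-2, None)
    omega0 = np.diag([max(occ_var[0], 0.1), 0.5, 0.5])
    Y = np.where(data.mask, data.values, occ_mean)
    eta0 = np.tile(alpha0, (data.n, 1))
    return gamma0, lam, alpha0, sigma2_0, omega0, Y, eta0


def _run_chain(seed_seq, data, priors, config):
    rng = np.random.default_rng(seed_seq)
    grid = data.grid
    t = grid.codes
    J = grid.n_occasions
    n = data.n
    knot = priors.knot
    gamma, lam, alpha, sigma2, omega, Y, eta = _init_chain(rng, data, priors)
    omega_inv = np.linalg.inv(omega)
    lp_gamma = knot.log_density(gamma)
    rows_m, cols_m = np.where(~data.mask)
    n_miss = rows_m.size
    prop_sd = config.knot_proposal_sd
    max_sd = grid.upper - grid.lower

    n_kept = config.n_iter // config.thin
    out = np.empty((n_kept, 3 + 6 + J + 1))
    keep = 0
    acc_post = 0
    acc_window = 0
    ones = np.ones(J)

    total = config.burn_in + config.n_iter
    for s in range(total):
        # 1. data augmentation
        if n_miss:
            fitted = eta @ lam.T
            Y[rows_m, cols_m] = fitted[rows_m, cols_m] + rng.standard_normal(
                n_miss
            ) * np.sqrt(sigma2[cols_m])
        # 2-4. latent factors, means, covariance
        if n > 0:
            eta = _update_eta(rng, Y, lam, sigma2, omega_inv, alpha)
        alpha = _update_alpha(rng, eta, omega_inv, priors)
        omega, omega_inv = _update_omega(rng, eta, alpha, priors)
        # 5. residual variances
        resid = Y - eta @ lam.T
        rss = np.einsum("ij,ij->j", resid, resid)
        sigma2 = _update_sigma2(rng, rss, n, priors)
        # 6. knot by random-walk Metropolis
        ll_cur = -0.5 * float(np.sum(rss / sigma2))
        if not math.isfinite(ll_cur):
            raise SamplingError(f"non-finite likelihood at iteration {s}")
        cand = gamma + rng.normal(0.0, prop_sd)
        lp_cand = knot.log_density(cand)
        if lp_cand > -math.inf:
            lam_c = np.empty((J, 3))
            lam_c[:, 0] = 1.0
            np.minimum(t, cand, out=lam_c[:, 1])
            np.maximum(t - cand, 0.0, out=lam_c[:, 2])
            resid_c = Y - eta @ lam_c.T
            ll_cand = -0.5 * float(
                np.sum(np.einsum("ij,ij->j", resid_c, resid_c) / sigma2)
            )
            if math.log(rng.random()) < ll_cand + lp_cand - ll_cur - lp_gamma:
                gamma, lam, lp_gamma = cand, lam_c, lp_cand
                if s >= config.burn_in:
                    acc_post += 1
                else:
                    acc_window += 1
        # adapt the proposal during burn-in only
        if s < config.burn_in and (s + 1) % config.adapt_window == 0:
            rate = acc_window / config.adapt_window
            if rate < 0.25:
                prop_sd = max(prop_sd * 0.8, 1e-3)
            elif rate > 0.45:
                prop_sd = min(prop_sd * 1.25, max_sd)
            acc_window = 0
        # record
        if s >= config.burn_in and (s - config.burn_in) % config.thin == 0:
            if keep < n_kept:
                out[keep, :3] = alpha
                out[keep, 3:9] = omega[_TRIL]
                out[keep, 9 : 9 + J] = sigma2
                out[keep, 9 + J] = gamma
                keep += 1
    return out, acc_post / max(config.n_iter, 1)


def fit(
    data: LongitudinalDataset, priors: ModelPriors, config: MCMCConfig
) -> PosteriorResult:
    """Fit the Bayesian PGM to a longitudinal dataset.

    Runs ``config.n_chains`` independent chains from dispersed starting
    values, screens every structural parameter with R-hat against
    ``config.rhat_threshold``, and returns the retained draws with
    summaries and diagnostics.  Subjects must each have at least one
    observed occasion (enforced by :class:`LongitudinalDataset`).
    """
    seed = config.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    chain_seeds = ss.spawn(config.n_chains)
    draws = []
    acc = []
    for cs in chain_seeds:
        chain, rate = _run_chain(cs, data, priors, config)
        draws.append(chain)
        acc.append(rate)
    draws = np.stack(draws)
    names = _param_names(data.grid.n_occasions)
    rhat = np.array(
        [
            compute_rhat(draws[:, :, p], method=config.rhat_method)
            for p in range(draws.shape[-1])
        ]
    )
    converged = bool(np.all(rhat < config.rhat_threshold))
    return PosteriorResult(
        draws=draws,
        param_names=names,
        rhat=rhat,
        converged=converged,
        knot_acceptance=float(np.mean(acc)),
        config=config,
    )


# ---------------------------------------------------------------------------
# diagnostics and summaries
# ---------------------------------------------------------------------------


def _gelman_rubin(x: np.ndarray) -> float:
    """Classic potential scale reduction on pre-split chains (rows)."""
    m, n = x.shape
    within = x.var(axis=1, ddof=1).mean()
    between = n * x.mean(axis=1).var(ddof=1)
    if within <= 0:
        return 1.0
    var_hat = (n - 1) / n * within + between / n
    return float(np.sqrt(var_hat / within))


def _rank_normalize(x: np.ndarray) -> np.ndarray:
    ranks = rankdata(x, method="average", axis=None)
    z = ndtri((ranks - 0.375) / (x.size + 0.25))
    return z.reshape(x.shape)


def compute_rhat(chain_draws: np.ndarray, method: str = "rank") -> float:
    """Split-chain potential scale reduction factor.

    ``chain_draws`` is (n_chains, n_draws).  ``method="rank"`` (default)
    is the rank-normalized variant with folding, robust to heavy tails
    and scale differences; ``method="split"`` is the classic statistic on
    the raw draws.  Values near 1 indicate convergence.  Chains with zero
    total variance return 1 by convention (with a warning).
    """
    x = np.asarray(chain_draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 4:
        raise ValueError("need at least 2 chains with at least 4 draws each")
    half = x.shape[1] // 2
    split = np.vstack([x[:, :half], x[:, half : 2 * half]])
    if np.ptp(split) == 0:
        warnings.warn("zero-variance draws; R-hat set to 1 by convention")
        return 1.0
    if method == "split":
        return _gelman_rubin(split)
    if method != "rank":
        raise ValueError(f"unknown R-hat method {method!r}")
    bulk = _gelman_rubin(_rank_normalize(split))
    folded = _gelman_rubin(_rank_normalize(np.abs(split - np.median(split))))
    return max(bulk, folded)


def summarize(result: PosteriorResult) -> pd.DataFrame:
    """Per-parameter posterior summary over pooled retained draws.

    Columns: mean, median, sd, the equal-tailed 95% interval bounds
    (2.5th and 97.5th percentiles) and R-hat.
    """
    pooled = result.pooled
    q = np.percentile(pooled, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {
            "mean": pooled.mean(axis=0),
            "median": np.median(pooled, axis=0),
            "sd": pooled.std(axis=0, ddof=1),
            "ci_lower": q[0],
            "ci_upper": q[1],
            "rhat": result.rhat,
        },
        index=pd.Index(result.param_names, name="parameter"),
    )


def check_convergence(result: PosteriorResult, threshold: float | None = None) -> bool:
    """True iff every monitored parameter's R-hat is strictly below threshold."""
    if threshold is None:
        threshold = result.config.rhat_threshold
    return bool(np.all(result.rhat < threshold))
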