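"""Prior specifications: seven knot-prior presets plus nuisance priors.

The knot location gamma gets either a uniform prior over the study window
(the diffuse setting, DIF) or a normal prior truncated to the window.
Truncated-normal presets differ in where they are centered -- at the
hypothesized true knot (ATK), at the midpoint between the first occasion
and that center (PRK, "pre-knot"), or at the midpoint between that center
and the last occasion (PSK, "post-knot") -- and in how concentrated they
are: informative (I-) or weakly informative (WI-, variance 5x larger).

On the default 0..6 grid the presets use the canonical hyperparameters
verbatim (informative variance 0.146).  On any other grid the informative
variance is derived from a 10% overlap rule between adjacent informative
priors: with center spacing d = range/4, solve 2*Phi(-d/(2*sigma)) = 0.10.
On a 0..8.5 grid this yields variance 0.417 (weakly informative 2.085).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr, ndtri

from .model import TimeGrid

PRESET_NAMES = ("DIF", "I-ATK", "WI-ATK", "I-PRK", "WI-PRK", "I-PSK", "WI-PSK")

_DEFAULT_INFORMATIVE_VAR = 0.146
_WEAK_MULTIPLIER = 5.0
_Z95 = ndtri(0.95)  # 1.6449: solves 2*Phi(-d/(2*sigma)) = 0.10
_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class KnotPriorSpec:
    """A prior for the knot location on a given time window.

    ``family`` is "uniform" or "truncated_normal"; truncation bounds are
    always the first and last time codes.  ``mu_gamma``/``sigma2_gamma``
    apply to the truncated-normal family only.
    """

    family: str
    lower: float
    upper: float
    mu_gamma: float | None = None
    sigma2_gamma: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.family not in ("uniform", "truncated_normal"):
            raise ValueError(f"unknown prior family {self.family!r}")
        if self.upper <= self.lower:
            raise ValueError("upper bound must exceed lower bound")
        if self.family == "truncated_normal":
            if self.mu_gamma is None or self.sigma2_gamma is None:
                raise ValueError("truncated_normal needs mu_gamma and sigma2_gamma")
            if self.sigma2_gamma <= 0:
                raise ValueError("sigma2_gamma must be positive")

    # -- density -----------------------------------------------------------

    def _trunc_mass(self) -> float:
        s = math.sqrt(self.sigma2_gamma)
        a = (self.lower - self.mu_gamma) / s
        b = (self.upper - self.mu_gamma) / s
        return float(ndtr(b) - ndtr(a))

    def log_density(self, gamma: float) -> float:
        """Log prior density at ``gamma``; ``-inf`` outside the support."""
        if not (self.lower <= gamma <= self.upper):
            return -math.inf
        if self.family == "uniform":
            return -math.log(self.upper - self.lower)
        s2 = self.sigma2_gamma
        return (
            -0.5 * (gamma - self.mu_gamma) ** 2 / s2
            - 0.5 * (_LOG_2PI + math.log(s2))
            - math.log(self._trunc_mass())
        )

    def ppf(self, q: float) -> float:
        """Quantile function of the prior (used for dispersed chain starts)."""
        if self.family == "uniform":
            return self.lower + q * (self.upper - self.lower)
        s = math.sqrt(self.sigma2_gamma)
        a = ndtr((self.lower - self.mu_gamma) / s)
        b = ndtr((self.upper - self.mu_gamma) / s)
        return self.mu_gamma + s * ndtri(a + q * (b - a))

    def mean_sd(self) -> tuple[float, float]:
        """Prior mean and standard deviation (closed forms)."""
        if self.family == "uniform":
            width = self.upper - self.lower
            return (self.lower + self.upper) / 2.0, width / math.sqrt(12.0)
        from scipy.stats import truncnorm

        s = math.sqrt(self.sigma2_gamma)
        a = (self.lower - self.mu_gamma) / s
        b = (self.upper - self.mu_gamma) / s
        dist = truncnorm(a, b, loc=self.mu_gamma, scale=s)
        return float(dist.mean()), float(dist.std())


def knot_log_density(spec: KnotPriorSpec, gamma: float) -> float:
    """Functional alias for :meth:`KnotPriorSpec.log_density`."""
    return spec.log_density(gamma)


def informative_variance(grid: TimeGrid) -> float:
    """Informative knot-prior variance for a grid.

    The canonical 0.146 on the default 0..6 grid; otherwise derived from
    the 10% overlap rule with center spacing ``range/4``.
    """
    if grid.is_default():
        return _DEFAULT_INFORMATIVE_VAR
    spacing = (grid.upper - grid.lower) / 4.0
    sigma = spacing / (2.0 * _Z95)
    return sigma**2


def knot_prior_preset(name: str, grid: TimeGrid | None = None) -> KnotPriorSpec:
    """Build one of the seven named knot-prior presets on a grid.

    On the default 0..6 grid: DIF = U(0, 6); I-ATK = N(3, 0.146)T(0, 6);
    WI-ATK = N(3, 0.730)T(0, 6); I-PRK / WI-PRK center 1.5; I-PSK /
    WI-PSK center 4.5 (same variances).  On other grids the ATK center is
    the grid midpoint, PRK/PSK sit halfway between an endpoint and the
    midpoint, and variances follow the overlap rule.
    """
    grid = grid or TimeGrid.default()
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    lo, hi = grid.lower, grid.upper
    if name == "DIF":
        return KnotPriorSpec(family="uniform", lower=lo, upper=hi, name=name)
    mid = (lo + hi) / 2.0
    centers = {"ATK": mid, "PRK": (lo + mid) / 2.0, "PSK": (mid + hi) / 2.0}
    strength, position = name.split("-")
    var = informative_variance(grid)
    if strength == "WI":
        var *= _WEAK_MULTIPLIER
    return KnotPriorSpec(
        family="truncated_normal",
        lower=lo,
        upper=hi,
        mu_gamma=centers[position],
        sigma2_gamma=var,
        name=name,
    )


@dataclass
class ModelPriors:
    """Priors for all four parameter blocks of the Bayesian PGM.

    Growth-factor means: independent N(mu_alpha, sigma2_alpha).  Factor
    covariance: inverse-Wishart IW(Psi, nu) with density proportional to
    |Omega|^(-(nu+p+1)/2) exp(-tr(Psi Omega^-1)/2).  Residual variances:
    independent inverse-gamma IG(a, b) with density proportional to
    x^(-a-1) exp(-b/x).  Knot location: a :class:`KnotPriorSpec`.
    Defaults are the canonical diffuse settings.
    """

    mu_alpha: float = 0.0
    sigma2_alpha: float = 1e6
    psi: np.ndarray = field(default_factory=lambda: np.eye(3))
    nu: float = 3.0
    a: float = 0.001
    b: float = 0.001
    knot: KnotPriorSpec = field(
        default_factory=lambda: knot_prior_preset("DIF")
    )

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=float).reshape(3, 3)
        if self.nu < self.psi.shape[0]:
            raise ValueError("nu must be at least the dimension of Psi")
        if self.a <= 0 or self.b <= 0 or self.sigma2_alpha <= 0:
            raise ValueError("a, b and sigma2_alpha must be positive")


def default_nuisance_priors(
    knot: KnotPriorSpec | None = None, grid: TimeGrid | None = None
) -> ModelPriors:
    """The canonical diffuse priors: N(0, 1e6), IW(I3, 3), IG(0.001, 0.001)."""
    if knot is None:
        knot = knot_prior_preset("DIF", grid)
    return ModelPriors(knot=knot)
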