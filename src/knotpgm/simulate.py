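"""Synthetic longitudinal data: PGM population draws and MAR attrition.

The generator mirrors a typical seven-wave longitudinal study.  Complete
data are drawn from the linear-linear PGM population model; attrition-style
missingness is then imposed on occasions 2..J via per-occasion logistic
models whose only predictor is the standardized first-occasion outcome
(a missing-at-random mechanism): the log-odds that ``y_ij`` is missing is
``b0_j + b1 * z_i1``.  Intercepts ``b0_j`` are solved so that the marginal
missing fraction at each occasion matches a target schedule.

Three schedule shapes are supported, parameterized by the missing
fraction at the final occasion (``terminal_prop``):

* ``concen_s`` -- decelerated increase (missingness concentrated at the
  start of the study),
* ``constant`` -- linear increase,
* ``concen_e`` -- accelerated increase (concentrated at the end).

On the default 0..6 grid with terminal proportions 0.30 / 0.70 these
reproduce, in percent: -(5/6)(t-6)^2+30, 5t, (5/6)t^2, -(35/18)(t-6)^2+70,
(35/3)t and (35/18)t^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, roots_hermitenorm

from .model import LongitudinalDataset, PGMParameters, TimeGrid, build_loading_matrix

PATTERNS = ("complete", "concen_s", "constant", "concen_e")

#: Default logistic slope tying missingness to the standardized first outcome.
DEFAULT_B1 = 1.48

# Gauss-Hermite (probabilists') rule reused by every intercept solve.
_GH_NODES, _GH_WEIGHTS = roots_hermitenorm(101)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def missing_schedule(
    pattern: str, terminal_prop: float, grid: TimeGrid | None = None
) -> np.ndarray:
    """Target marginal missing fractions at each occasion.

    Only defined on the default 0..6 grid; other grids need an explicit
    user-supplied schedule.  ``terminal_prop`` is the missing fraction at
    the final occasion (0.30 and 0.70 are the canonical levels; any value
    in [0, 1) works).  The first occasion is always fully observed.
    """
    grid = grid or TimeGrid.default()
    if pattern == "complete":
        raise ValueError("the complete pattern has no missingness schedule")
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}; choose from {PATTERNS}")
    if not grid.is_default():
        raise ValueError(
            "schedule formulas are defined on the default 0..6 grid only; "
            "supply an explicit schedule for other grids"
        )
    if not 0.0 <= terminal_prop < 1.0:
        raise ValueError("terminal_prop must be in [0, 1)")
    t = grid.codes
    peak = 100.0 * terminal_prop  # formulas are stated in percent
    if pattern == "constant":
        pct = (peak / 6.0) * t
    elif pattern == "concen_s":
        pct = -(peak / 36.0) * (t - 6.0) ** 2 + peak
    else:  # concen_e
        pct = (peak / 36.0) * t**2
    return pct / 100.0


def _marginal_missing_prob(b0: float, b1: float) -> float:
    """E[expit(b0 + b1 Z)] over standard-normal Z, by quadrature."""
    return float(_GH_WEIGHTS @ expit(b0 + b1 * _GH_NODES))


def solve_logit_intercepts(schedule: np.ndarray, b1: float = DEFAULT_B1) -> np.ndarray:
    """Solve the per-occasion logistic intercepts hitting a target schedule.

    For each occasion with target fraction ``p_j > 0``, finds ``b0_j``
    such that the missing probability averaged over the standard-normal
    predictor equals ``p_j`` (root finding on a 101-point Gauss-Hermite
    quadrature, tolerance well below 1e-8).  Occasions with ``p_j = 0``
    get ``NaN`` as a "no missingness" sentinel.
    """
    schedule = np.asarray(schedule, dtype=float)
    if np.any((schedule < 0) | (schedule >= 1)):
        raise ValueError("schedule entries must lie in [0, 1)")
    if not np.isfinite(b1):
        raise ValueError("b1 must be finite")
    out = np.full(schedule.shape, np.nan)
    for j, p in enumerate(schedule):
        if p > 0:
            out[j] = brentq(
                lambda b0: _marginal_missing_prob(b0, b1) - p,
                -40.0,
                40.0,
                xtol=1e-12,
            )
    return out


@dataclass
class MissingnessSpec:
    """A fully solved MAR attrition specification.

    Build with :meth:`from_pattern` for the canonical schedules, or pass
    an explicit ``schedule`` for custom designs.  ``monotone=True``
    additionally carries dropout forward (once missing, always missing);
    the default is the literal per-occasion Bernoulli generation, which
    reproduces the target marginal proportions exactly.
    """

    pattern: str
    terminal_prop: float
    b1: float = DEFAULT_B1
    schedule: np.ndarray | None = None
    intercepts: np.ndarray | None = None
    monotone: bool = False

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.pattern == "complete":
            return
        if self.schedule is None:
            raise ValueError("non-complete spec requires a schedule")
        self.schedule = np.asarray(self.schedule, dtype=float)
        if self.schedule[0] != 0.0:
            raise ValueError("the first occasion must be fully observed")
        if np.any(np.diff(self.schedule) < 0):
            raise ValueError("attrition schedules must be non-decreasing")
        if self.intercepts is None:
            self.intercepts = solve_logit_intercepts(self.schedule, self.b1)

    @classmethod
    def from_pattern(
        cls,
        pattern: str,
        terminal_prop: float = 0.0,
        grid: TimeGrid | None = None,
        b1: float = DEFAULT_B1,
        monotone: bool = False,
    ) -> "MissingnessSpec":
        if pattern == "complete" or terminal_prop == 0.0:
            return cls(pattern="complete", terminal_prop=0.0, b1=b1)
        sched = missing_schedule(pattern, terminal_prop, grid)
        return cls(
            pattern=pattern,
            terminal_prop=terminal_prop,
            b1=b1,
            schedule=sched,
            monotone=monotone,
        )


def default_population() -> PGMParameters:
    """The package's documented default population model.

    Knot at coded time 3 (the fourth of seven equidistant occasions);
    intercept mean 50 with variance 25; pre-knot slope mean 1.0 and
    post-knot slope mean 1.4, both with variance 0.25 and no factor
    covariances; residual variance 5 at every occasion.  The slope change
    of 0.4 against a slope SD of 0.5 is a Cohen-style large standardized
    effect (d = 0.8): the changepoint is real but not so sharp that the
    likelihood swamps every prior at small samples.
    """
    return PGMParameters(
        alpha=np.array([50.0, 1.0, 1.4]),
        omega_eta=np.diag([25.0, 0.25, 0.25]),
        sigma2_eps=np.full(7, 5.0),
        gamma=3.0,
    )


def _psd_factor(omega: np.ndarray) -> np.ndarray:
    """A matrix L with L L' = omega, valid for semidefinite omega."""
    try:
        return np.linalg.cholesky(omega)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(omega)
        vals = np.clip(vals, 0.0, None)
        return vecs * np.sqrt(vals)


def generate_complete(
    params: PGMParameters,
    n: int,
    grid: TimeGrid | None = None,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> LongitudinalDataset:
    """Draw ``n`` complete subjects from the PGM population model."""
    grid = grid or TimeGrid.default()
    if n < 1:
        raise ValueError("n must be at least 1")
    params.validate(grid)
    rng = np.random.default_rng(seed)
    lam = build_loading_matrix(grid, params.gamma)
    eta = params.alpha + rng.standard_normal((n, 3)) @ _psd_factor(params.omega_eta).T
    eps = rng.standard_normal((n, grid.n_occasions)) * np.sqrt(params.sigma2_eps)
    values = eta @ lam.T + eps
    mask = np.ones_like(values, dtype=bool)
    return LongitudinalDataset(values=values, mask=mask, grid=grid)


def apply_mar(
    data: LongitudinalDataset,
    spec: MissingnessSpec,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> LongitudinalDataset:
    """Impose MAR attrition missingness on a complete dataset.

    The missingness indicator for subject ``i`` at occasion ``j >= 2`` is
    Bernoulli with success probability ``expit(b0_j + b1 * z_i1)`` where
    ``z_i1`` standardizes the first-occasion outcome by its sample mean
    and SD.  Deleted cells become ``NaN``.  The first occasion is never
    touched, so every subject keeps at least one observation.
    """
    if not data.mask[:, 0].all():
        raise ValueError("apply_mar requires a fully observed first occasion")
    if spec.pattern == "complete":
        return LongitudinalDataset(
            values=data.values.copy(), mask=data.mask.copy(), grid=data.grid
        )
    rng = np.random.default_rng(seed)
    y1 = data.values[:, 0]
    z = (y1 - y1.mean()) / y1.std(ddof=1)
    probs = np.zeros((data.n, data.grid.n_occasions - 1))
    for j in range(1, data.grid.n_occasions):
        if spec.schedule[j] > 0:
            probs[:, j - 1] = expit(spec.intercepts[j] + spec.b1 * z)
    miss = rng.random(probs.shape) < probs
    if spec.monotone:
        miss = np.maximum.accumulate(miss, axis=1)
    mask = data.mask.copy()
    mask[:, 1:] &= ~miss
    values = data.values.copy()
    values[~mask] = np.nan
    return LongitudinalDataset(values=values, mask=mask, grid=data.grid)


def write_wide_csv(data: LongitudinalDataset, path) -> None:
    """Write a dataset as wide CSV: header row of time codes, empty cell = missing."""
    frame = pd.DataFrame(
        np.where(data.mask, data.values, np.nan),
        columns=[format(c, "g") for c in data.grid.codes],
    )
    frame.to_csv(path, index=False)


def read_wide_csv(path, time_codes=None) -> LongitudinalDataset:
    """Read a wide-format CSV (one row per subject, empty cell = missing).

    Time codes are taken from the header unless ``time_codes`` overrides
    them.  Rows with no observed value at all are rejected.
    """
    frame = pd.read_csv(path)
    if time_codes is None:
        try:
            codes = np.array([float(c) for c in frame.columns])
        except ValueError as exc:
            raise ValueError(
                "CSV header is not numeric; pass time_codes explicitly"
            ) from exc
    else:
        codes = np.asarray(time_codes, dtype=float)
        if codes.size != frame.shape[1]:
            raise ValueError("time_codes length must match the column count")
    values = frame.to_numpy(dtype=float)
    mask = np.isfinite(values)
    empty = np.flatnonzero(~mask.any(axis=1))
    if empty.size:
        raise ValueError(
            f"subjects with zero observations at rows {empty.tolist()}"
        )
    return LongitudinalDataset(values=values, mask=mask, grid=TimeGrid(codes))
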