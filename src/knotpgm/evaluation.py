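"""Monte Carlo outcome measures for knot-recovery studies.

Coverage, average bias and RMSE are computed over *converged*
replications only; the convergence rate is computed over all
replications.  With ``R_c`` converged replications, knot estimate
``est_s`` and 95% interval ``[L_s, U_s]`` at replication ``s``, and true
knot ``theta``:

* coverage  = (1/R_c) sum 1{theta in [L_s, U_s]}
* avg bias  = (1/R_c) sum (est_s - theta)
* RMSE      = sqrt((1/R_c) sum (est_s - theta)^2)
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

#: Default true knot location on the default grid (fourth occasion, coded 3).
DEFAULT_TRUTH = 3.0


@dataclass(frozen=True)
class ReplicationRecord:
    """One replication's knot summary: posterior mean, 95% interval, convergence."""

    estimate: float
    ci_lower: float
    ci_upper: float
    converged: bool
    replication: int = 0

    def __post_init__(self) -> None:
        if (
            math.isfinite(self.ci_lower)
            and math.isfinite(self.ci_upper)
            and self.ci_lower > self.ci_upper
        ):
            raise ValueError("ci_lower must not exceed ci_upper")


@dataclass(frozen=True)
class CellMetrics:
    """Aggregated outcome measures for one design cell."""

    convergence_rate: float
    coverage: float
    avg_bias: float
    rmse: float
    n_converged: int
    n_total: int


def _converged(records: Sequence[ReplicationRecord]) -> list[ReplicationRecord]:
    kept = [r for r in records if r.converged]
    if not kept:
        raise ValueError(
            "no converged replications; metrics over converged runs are undefined"
        )
    return kept


def coverage_rate(records: Sequence[ReplicationRecord], truth: float = DEFAULT_TRUTH) -> float:
    kept = _converged(records)
    hits = sum(1 for r in kept if r.ci_lower <= truth <= r.ci_upper)
    return hits / len(kept)


def average_bias(records: Sequence[ReplicationRecord], truth: float = DEFAULT_TRUTH) -> float:
    kept = _converged(records)
    return float(np.mean([r.estimate for r in kept]) - truth)


def rmse(records: Sequence[ReplicationRecord], truth: float = DEFAULT_TRUTH) -> float:
    kept = _converged(records)
    err = np.array([r.estimate for r in kept]) - truth
    return float(np.sqrt(np.mean(err**2)))


def convergence_rate(records: Sequence[ReplicationRecord]) -> float:
    if not records:
        raise ValueError("need at least one replication record")
    return sum(1 for r in records if r.converged) / len(records)


def cell_metrics(
    records: Sequence[ReplicationRecord], truth: float = DEFAULT_TRUTH
) -> CellMetrics:
    """All four outcome measures for one cell's replication records.

    If no replication converged, the converged-only metrics are reported
    as NaN (an undefined-result sentinel) rather than zero.
    """
    records = list(records)
    conv = convergence_rate(records)
    n_conv = sum(1 for r in records if r.converged)
    if n_conv == 0:
        cov = bias = err = float("nan")
    else:
        cov = coverage_rate(records, truth)
        bias = average_bias(records, truth)
        err = rmse(records, truth)
    return CellMetrics(
        convergence_rate=conv,
        coverage=cov,
        avg_bias=bias,
        rmse=err,
        n_converged=n_conv,
        n_total=len(records),
    )
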