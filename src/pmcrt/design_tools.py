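"""Design-stage utilities: pair-matched randomization and precision estimates.

The expected-precision calculation uses the standard unmatched
cluster-randomized approximation for the variance of a log risk ratio with
``c`` clusters of ``n`` respondents per arm and between-cluster coefficient
of variation ``k``:

    var(log RR) = (1/c) * [ (1-p1)/(p1*n) + k^2 ] + (1/c) * [ (1-p0)/(p0*n) + k^2 ]

with a normal 95% interval ``RR * exp(+/- 1.96 * sqrt(var))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DataError


@dataclass(frozen=True)
class DesignScenario:
    """One row of a design grid."""

    clusters_per_arm: int
    n_per_cluster: int
    control_prev: float
    rr: float
    k: float = 0.0
    confidence: float = 0.95

    def __post_init__(self):
        p1 = self.rr * self.control_prev
        if not (0.0 < self.control_prev < 1.0) or not (0.0 < p1 < 1.0):
            raise DataError(
                f"prevalences must lie in (0,1): p0={self.control_prev}, p1={p1}"
            )
        if self.clusters_per_arm < 2:
            raise DataError("need at least two clusters per arm")
        if self.k < 0:
            raise DataError("k must be non-negative")

    @property
    def intervention_prev(self) -> float:
        return self.rr * self.control_prev


@dataclass(frozen=True)
class PrecisionEstimate:
    rr: float
    ci_low: float
    ci_high: float
    var_log_rr: float
    var_sampling: float  # binomial component of the variance
    var_cluster: float  # between-cluster (k) component


def precision_estimate(sc: DesignScenario) -> PrecisionEstimate:
    """Expected confidence interval for the risk ratio under a design scenario."""
    c, n = sc.clusters_per_arm, sc.n_per_cluster
    p0, p1, k = sc.control_prev, sc.intervention_prev, sc.k
    var_sampling = ((1 - p1) / (p1 * n) + (1 - p0) / (p0 * n)) / c
    var_cluster = 2.0 * k**2 / c
    var = var_sampling + var_cluster
    z = stats.norm.ppf(0.5 + sc.confidence / 2.0)
    half = z * math.sqrt(var)
    return PrecisionEstimate(
        rr=sc.rr,
        ci_low=sc.rr * math.exp(-half),
        ci_high=sc.rr * math.exp(half),
        var_log_rr=var,
        var_sampling=var_sampling,
        var_cluster=var_cluster,
    )


def randomize_pairs(pairs: list[tuple[str, str]], seed: int) -> dict[str, str]:
    """Randomize one site of each pair to intervention, the other to control.

    A fair coin per pair, reproducible under ``seed``.  Returns a map
    site_id -> arm.
    """
    flat = [s for pair in pairs for s in pair]
    if len(set(flat)) != len(flat):
        raise DataError("duplicate site in pairs list")
    if not pairs:
        raise DataError("need at least one pair")
    rng = np.random.default_rng(seed)
    allocation: dict[str, str] = {}
    for a, b in pairs:
        if rng.random() < 0.5:
            allocation[a], allocation[b] = "intervention", "control"
        else:
            allocation[a], allocation[b] = "control", "intervention"
    return allocation
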