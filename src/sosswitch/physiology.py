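"""Growth-physiology arithmetic.

Unit conventions: cell-cycle periods (C, D, tau) are in minutes, rates are
per hour, doubling rates in doublings per hour. Conversions happen only at
the boundaries of this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CellCycleParams",
    "avg_replication_forks",
    "doubling_rate_to_exp_rate",
    "doubling_time_minutes",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class CellCycleParams:
    """Cooper–Helmstetter cell-cycle timing for a steady-state culture.

    Parameters
    ----------
    C : float
        Chromosome replication period, minutes (> 0).
    D : float
        Post-replication period (segregation/septation), minutes (>= 0).
    tau : float
        Population doubling time, minutes (> 0). When ``tau < C + D`` the
        culture runs overlapping (multifork) replication rounds.
    """

    C: float
    D: float
    tau: float

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ValueError(f"replication period C must be > 0, got {self.C}")
        if self.D < 0:
            raise ValueError(f"post-replication period D must be >= 0, got {self.D}")
        if not self.tau > 0:
            raise ValueError(f"doubling time tau must be > 0, got {self.tau}")


def avg_replication_forks(p: CellCycleParams) -> float:
    """Mean number of active replication forks per cell.

    Averages the instantaneous fork count over the steady-state cell-age
    distribution phi(a) = (2 ln2 / tau) * 2**(-a/tau) under the
    Cooper–Helmstetter model, which has the closed form

        F = 2 * (2**((C+D)/tau) - 2**(D/tau)).

    For fast growth (tau < C + D) overlapping rounds inherited from
    ancestor cells contribute, so F can exceed 2; for slow growth F -> 0
    as tau -> infinity.
    """
    return 2.0 * (2.0 ** ((p.C + p.D) / p.tau) - 2.0 ** (p.D / p.tau))


def forks_at_age(age: float, p: CellCycleParams) -> float:
    """Instantaneous fork count in a cell of the given age (minutes).

    A replication round destined for the division n generations ahead is
    initiated at age (n+1)*tau - (C+D) (possibly in an ancestor), runs for
    C minutes, and involves 2**n replicating units of 2 forks each. Used
    as the integrand of the brute-force age-distribution average that
    cross-checks :func:`avg_replication_forks`.
    """
    if not 0 <= age < p.tau:
        raise ValueError("age must lie in [0, tau)")
    total = 0.0
    n = 0
    while True:
        start = (n + 1) * p.tau - (p.C + p.D)
        if start >= p.tau:
            break
        if start <= age < start + p.C:
            total += 2.0 ** (n + 1)
        n += 1
    return total


def doubling_rate_to_exp_rate(mu: float) -> float:
    """Convert doublings per hour to the exponential rate ln2 * mu (1/h)."""
    if mu < 0:
        raise ValueError(f"doubling rate must be >= 0, got {mu}")
    return LN2 * mu


def doubling_time_minutes(mu: float) -> float:
    """Doubling time in minutes for a doubling rate in doublings per hour."""
    if not mu > 0:
        raise ValueError(f"doubling rate must be > 0, got {mu}")
    return 60.0 / mu
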