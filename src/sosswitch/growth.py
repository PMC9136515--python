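"""Growth-rate inference.

Two routes to the population growth rate:

* single-cell: the discrete Euler–Lotka condition
  ``(2/N) * sum_i exp(-lambda * tau_i) = 1`` applied to interdivision
  times from mother-cell lineages (censored cycles carry no interdivision
  time and are excluded — which biases the estimate toward the normally
  dividing low-SOS subpopulation, the rate the two-state model needs);
* batch: linear regression of log OD or log CFU/ml against time within an
  exponential-phase window.

Uncertainties are nonparametric bootstrap standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trajectories import CellCycle

LN2 = math.log(2.0)

__all__ = [
    "GrowthEstimate",
    "division_rates",
    "euler_lotka_growth_rate",
    "batch_growth_rate",
]


@dataclass
class GrowthEstimate:
    """Population growth-rate estimate.

    ``lam`` is the exponential rate (1/h); ``doubling_rate`` = lam/ln2
    (doublings/h). ``method`` is one of ``euler_lotka``, ``od_regression``,
    ``cfu_regression``. ``se`` is a bootstrap standard error on ``lam``
    (NaN when bootstrapping was disabled).
    """

    lam: float
    method: str
    n: int
    se: float = float("nan")

    @property
    def doubling_rate(self) -> float:
        return self.lam / LN2


def division_rates(cycles: list[CellCycle]) -> np.ndarray:
    """Single-cell division rates 1/tau (1/h) from complete cycles only."""
    taus = np.array([c.interdivision_time for c in cycles if not c.censored])
    if taus.size == 0:
        raise ValueError("no complete (non-censored) cycles")
    if np.any(taus <= 0):
        raise ValueError("non-positive interdivision time")
    return 1.0 / taus


def _euler_lotka_root(taus: np.ndarray, rel_tol: float = 1e-10) -> float:
    """Unique root of g(lambda) = 2 mean(exp(-lambda tau)) - 1 by bisection.

    g is strictly decreasing and brackets 1 on [ln2/max(tau), ln2/min(tau)]
    (each endpoint bounds every term by 1/2 from one side), so the root is
    unique and the bracket always valid.
    """
    lo = LN2 / float(np.max(taus))
    hi = LN2 / float(np.min(taus))
    if hi - lo <= rel_tol * lo:
        return 0.5 * (lo + hi)

    def g(lam: float) -> float:
        return 2.0 * float(np.mean(np.exp(-lam * taus))) - 1.0

    g_lo, g_hi = g(lo), g(hi)
    assert g_lo >= -1e-12 and g_hi <= 1e-12, "Euler-Lotka bracket violated"
    while hi - lo > rel_tol * lo:
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def euler_lotka_growth_rate(taus, n_bootstrap: int = 1000,
                            seed: int = 0) -> GrowthEstimate:
    """Population growth rate implied by an interdivision-time sample.

    Solves the discrete Euler–Lotka condition 2 E[exp(-lambda tau)] = 1 by
    bisection (relative tolerance 1e-10). With zero variance the solution
    is exactly ln2/tau. The standard error is a seeded nonparametric
    bootstrap over the interdivision-time sample (``n_bootstrap=0``
    disables it).
    """
    taus = np.asarray(taus, dtype=float)
    if taus.size == 0:
        raise ValueError("empty interdivision-time sample")
    if np.any(taus <= 0):
        raise ValueError("interdivision times must be positive")
    lam = _euler_lotka_root(taus)
    se = float("nan")
    if n_bootstrap > 0 and taus.size > 1:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            boots[b] = _euler_lotka_root(rng.choice(taus, size=taus.size))
        se = float(np.std(boots, ddof=1))
    return GrowthEstimate(lam, "euler_lotka", int(taus.size), se)


def batch_growth_rate(times, values, window: tuple[float, float] | None = None,
                      method: str = "od_regression") -> GrowthEstimate:
    """Exponential rate from a batch growth curve by log-linear regression.

    Fits ln(value) against time (hours) within ``window`` (inclusive; the
    whole curve if None). At least 3 points are required and all values
    must be positive.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape:
        raise ValueError("times and values must have the same shape")
    if window is not None:
        keep = (times >= window[0]) & (times <= window[1])
        times, values = times[keep], values[keep]
    if times.size < 3:
        raise ValueError("need at least 3 points in the regression window")
    if np.any(values <= 0):
        raise ValueError("growth-curve values must be positive")
    fit = stats.linregress(times, np.log(values))
    return GrowthEstimate(float(fit.slope), method, int(times.size),
                          float(fit.stderr))
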