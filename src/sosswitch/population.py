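"""Two-state population model of an expanding culture.

Cell counts in the low- and high-SOS states obey the linear system

    dn1/dt = (lambda1 - alpha) n1 + beta n2
    dn2/dt = alpha n1 + (lambda2 - beta) n2

with division rates lambda1 > lambda2 and switching rates alpha (low to
high) and beta (high to low, negligible in the data this models). The
steady-state high-SOS fraction f2 follows from the dominant eigenvector;
with beta = 0 and lambda1 - alpha > lambda2 it is exactly
alpha / (lambda1 - lambda2), and when lambda2 is also negligible it
reduces to alpha / lambda1. Because lambda1 rises steeply with nutrient
quality while alpha rises only mildly, f2 is larger in poor media even
though switching is faster in rich media.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .growth import GrowthEstimate
from .switching import SwitchingEstimate

__all__ = [
    "TwoStateParams",
    "PopulationPrediction",
    "f2_simple",
    "f2_corrected",
    "f2_exact",
    "two_state_ode_solve",
    "predict_fraction",
    "mutation_rate_correction",
]

DEFAULT_LAMBDA2 = 0.1  # 1/h; rare residual divisions of high-SOS cells


@dataclass(frozen=True)
class TwoStateParams:
    """Rates (1/h) of the two-state switching model."""

    alpha: float
    beta: float
    lambda1: float
    lambda2: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "lambda1", "lambda2"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be >= 0")

    @property
    def matrix(self) -> np.ndarray:
        return np.array([
            [self.lambda1 - self.alpha, self.beta],
            [self.alpha, self.lambda2 - self.beta],
        ])


@dataclass
class PopulationPrediction:
    """Steady-state high-SOS fraction under the three model variants.

    ``f2_simple`` = alpha/lambda1 (high-state divisions neglected),
    ``f2_corrected`` = alpha/(lambda1 - lambda2), ``f2_exact`` from the
    dominant eigenvector. ``dominant_rate`` is the population growth rate
    (dominant eigenvalue, 1/h). ``high_dominant`` flags the regime where
    the high-SOS state outgrows the low state (lambda1 - alpha <= lambda2)
    and the approximations break down. ``clipped`` marks formula values
    that had to be clipped into [0, 1].
    """

    f2_simple: float
    f2_corrected: float
    f2_exact: float
    dominant_rate: float
    high_dominant: bool = False
    clipped: bool = False
    intervals: dict | None = None


def _clip_fraction(x: float) -> tuple[float, bool]:
    if 0.0 <= x <= 1.0:
        return x, False
    return min(max(x, 0.0), 1.0), True


def f2_simple(alpha: float, lambda1: float) -> float:
    """First-order steady-state fraction alpha/lambda1, clipped to [0, 1]."""
    if lambda1 <= 0:
        raise ValueError("lambda1 must be positive")
    return _clip_fraction(alpha / lambda1)[0]


def f2_corrected(alpha: float, lambda1: float, lambda2: float) -> float:
    """Competition-corrected fraction alpha/(lambda1 - lambda2).

    Equals f2_simple * 1/(1 - lambda2/lambda1); requires lambda1 > lambda2.
    """
    if lambda2 >= lambda1:
        raise ValueError("requires lambda1 > lambda2")
    if lambda1 <= 0:
        raise ValueError("lambda1 must be positive")
    return _clip_fraction(alpha / (lambda1 - lambda2))[0]


def f2_exact(params: TwoStateParams) -> PopulationPrediction:
    """Steady-state fraction from the dominant eigenvector of the rate matrix."""
    A = params.matrix
    vals, vecs = np.linalg.eig(A)
    i = int(np.argmax(vals.real))
    lam_dom = float(vals[i].real)
    v = vecs[:, i].real
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    frac = float(v[1] / v.sum()) if v.sum() > 0 else float("nan")
    high_dominant = params.lambda1 - params.alpha <= params.lambda2

    simple = f2_simple(params.alpha, params.lambda1) if params.lambda1 > 0 else float("nan")
    clipped = not (0.0 <= params.alpha / params.lambda1 <= 1.0) if params.lambda1 > 0 else False
    if params.lambda2 < params.lambda1:
        corrected = f2_corrected(params.alpha, params.lambda1, params.lambda2)
        clipped = clipped or not (
            0.0 <= params.alpha / (params.lambda1 - params.lambda2) <= 1.0)
    else:
        corrected = float("nan")
    return PopulationPrediction(simple, corrected, frac, lam_dom,
                                high_dominant=high_dominant, clipped=clipped)


def two_state_ode_solve(params: TwoStateParams, n1_0: float, n2_0: float,
                        t_grid) -> tuple[np.ndarray, np.ndarray]:
    """Exact solution of the linear two-state system via matrix exponentials."""
    if n1_0 < 0 or n2_0 < 0:
        raise ValueError("initial counts must be non-negative")
    t_grid = np.asarray(t_grid, dtype=float)
    A = params.matrix
    n0 = np.array([n1_0, n2_0], dtype=float)
    out = np.array([expm(A * t) @ n0 for t in t_grid])
    return out[:, 0], out[:, 1]


def predict_fraction(alpha_est: SwitchingEstimate, growth_est: GrowthEstimate,
                     lambda2: float = DEFAULT_LAMBDA2) -> PopulationPrediction:
    """Combine a switching-rate and a growth-rate estimate into f2 predictions.

    The switching-rate confidence interval is propagated through each
    formula by monotone interval mapping (every variant is increasing in
    alpha). When lambda2 >= lambda1 only the first-order formula is
    defined; the others are reported as NaN with the regime flag set.
    """
    alpha, lam1 = alpha_est.alpha, growth_est.lam
    if lam1 <= 0:
        raise ValueError("growth rate must be positive")
    pred = f2_exact(TwoStateParams(alpha, 0.0, lam1, lambda2))
    intervals = {}
    for lo, hi, key in [(alpha_est.ci_low, alpha_est.ci_high, None)]:
        intervals["f2_simple"] = (f2_simple(lo, lam1), f2_simple(hi, lam1))
        if lambda2 < lam1:
            intervals["f2_corrected"] = (f2_corrected(lo, lam1, lambda2),
                                         f2_corrected(hi, lam1, lambda2))
            exact_lo = f2_exact(TwoStateParams(lo, 0.0, lam1, lambda2)).f2_exact
            exact_hi = f2_exact(TwoStateParams(hi, 0.0, lam1, lambda2)).f2_exact
            intervals["f2_exact"] = (exact_lo, exact_hi)
    pred.intervals = intervals
    return pred


def mutation_rate_correction(apparent_rate: float, f2: float) -> float:
    """Rescale a population-level mutation rate to the high-SOS subpopulation.

    If mutants arise predominantly in the high-SOS fraction f2, the
    per-cell rate in that subpopulation is the apparent rate divided by
    f2 — a factor of 20 or more when f2 <= 0.05.
    """
    if not 0.0 < f2 <= 1.0:
        raise ValueError("f2 must lie in (0, 1]")
    return apparent_rate / f2
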