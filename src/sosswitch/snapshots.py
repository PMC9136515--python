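"""Population-snapshot statistics of per-cell fluorescence distributions.

A snapshot dataset is a DataFrame with columns ``intensity`` (a.u./area,
>= 0), ``replicate`` and ``condition``. Error bars are always standard
errors across biological replicates, never across cells; single-replicate
datasets report an SEM of 0 with a flag where it is undefined. Threshold
comparisons are strict (``>``): a cell exactly at the threshold belongs to
the lower class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ReplicateSummary",
    "MixtureFit",
    "rescale_by_reference",
    "fraction_above",
    "top_percent_mean",
    "bottom_percent_mean",
    "log_binned_histogram",
    "fit_two_gaussians",
]


@dataclass
class ReplicateSummary:
    """A per-replicate statistic with its across-replicate mean and SEM."""

    per_replicate: pd.Series
    mean: float
    sem: float
    sem_defined: bool


def _aggregate(per_rep: pd.Series) -> ReplicateSummary:
    m = float(per_rep.mean())
    if per_rep.size > 1:
        sem = float(per_rep.std(ddof=1) / math.sqrt(per_rep.size))
        return ReplicateSummary(per_rep, m, sem, True)
    return ReplicateSummary(per_rep, m, 0.0, False)


def _check(data: pd.DataFrame) -> None:
    for col in ("intensity", "replicate"):
        if col not in data.columns:
            raise ValueError(f"snapshot table is missing column {col!r}")
    if data.empty:
        raise ValueError("empty snapshot dataset")


def rescale_by_reference(values, reference_mean: float):
    """Divide intensities by a reference-strain mean (per-medium rescaling)."""
    if not reference_mean > 0:
        raise ValueError("reference mean must be positive")
    return np.asarray(values, dtype=float) / reference_mean


def fraction_above(data: pd.DataFrame, threshold: float) -> ReplicateSummary:
    """Fraction of cells strictly above the intensity threshold, per replicate."""
    _check(data)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    per = data.groupby("replicate")["intensity"].apply(
        lambda v: float(np.mean(v.to_numpy() > threshold)))
    return _aggregate(per)


def _slice_mean(values: np.ndarray, percent: float, top: bool) -> float:
    n = values.size
    m = math.ceil(percent * n / 100.0)  # nearest-rank: top 1% of 100 cells is 1 cell
    v = np.sort(values)
    return float(np.mean(v[-m:] if top else v[:m]))


def top_percent_mean(data: pd.DataFrame, percent: float) -> ReplicateSummary:
    """Mean intensity of the highest-expressing ``percent`` of cells."""
    _check(data)
    if not 0 < percent < 100:
        raise ValueError("percent must lie in (0, 100)")
    per = data.groupby("replicate")["intensity"].apply(
        lambda v: _slice_mean(v.to_numpy(dtype=float), percent, top=True))
    return _aggregate(per)


def bottom_percent_mean(data: pd.DataFrame, percent: float) -> ReplicateSummary:
    """Mean intensity of the lowest-expressing ``percent`` of cells."""
    _check(data)
    if not 0 < percent < 100:
        raise ValueError("percent must lie in (0, 100)")
    per = data.groupby("replicate")["intensity"].apply(
        lambda v: _slice_mean(v.to_numpy(dtype=float), percent, top=False))
    return _aggregate(per)


def log_binned_histogram(data: pd.DataFrame, n_bins: int = 50,
                         value_range: tuple[float, float] | None = None) -> pd.DataFrame:
    """Geometric-bin frequency histogram with replicate mean and SEM per bin.

    Frequencies are normalized per replicate (they sum to 1), then averaged
    across replicates. Returns a DataFrame with bin edges, centers, mean
    frequency, SEM (0 with ``sem_defined=False`` for a single replicate).
    """
    _check(data)
    v = data["intensity"].to_numpy(dtype=float)
    if value_range is None:
        pos = v[v > 0]
        if pos.size == 0:
            raise ValueError("no positive intensities to bin")
        value_range = (float(pos.min()), float(pos.max()))
    lo, hi = value_range
    if not (lo > 0 and hi > lo):
        raise ValueError("range limits must be positive and increasing")
    edges = np.geomspace(lo, hi, n_bins + 1)
    reps = sorted(data["replicate"].unique())
    freq = np.zeros((len(reps), n_bins))
    for i, r in enumerate(reps):
        vals = data.loc[data["replicate"] == r, "intensity"].to_numpy(dtype=float)
        counts, _ = np.histogram(vals, bins=edges)
        total = counts.sum()
        if total == 0:
            raise ValueError(f"replicate {r!r} has no cells inside the range")
        freq[i] = counts / total
    mean = freq.mean(axis=0)
    if len(reps) > 1:
        sem = freq.std(axis=0, ddof=1) / math.sqrt(len(reps))
        sem_defined = True
    else:
        sem = np.zeros(n_bins)
        sem_defined = False
    return pd.DataFrame({
        "bin_left": edges[:-1], "bin_right": edges[1:],
        "bin_center": np.sqrt(edges[:-1] * edges[1:]),
        "frequency": mean, "sem": sem,
        "sem_defined": sem_defined,
    })


@dataclass
class MixtureFit:
    """Two-component Gaussian mixture fit (EM).

    ``means``/``sds`` are in the fit space (log-intensity by default).
    ``collapsed`` flags fits whose components ended within one pooled
    standard deviation of each other (effectively a single population).
    """

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    fit_space: str
    log_likelihood: float
    converged: bool
    n_iter: int
    collapsed: bool

    @property
    def mean_ratio(self) -> float:
        """Ratio of component locations on the linear-intensity scale."""
        if self.fit_space == "log":
            return float(np.exp(self.means[1] - self.means[0]))
        return float(self.means[1] / self.means[0])


def _normal_logpdf(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return -0.5 * ((x - mu) / sd) ** 2 - math.log(sd) - 0.5 * math.log(2 * math.pi)


def fit_two_gaussians(data: pd.DataFrame, fit_space: str = "log",
                      tol: float = 1e-8, max_iter: int = 500) -> MixtureFit:
    """Fit a two-component Gaussian mixture by EM.

    Intensities are log-transformed first unless ``fit_space="linear"``.
    Components are initialized at the 15th and 85th percentiles with
    weights 0.85/0.15 (a main population plus a high shoulder), and the
    log-likelihood is asserted non-decreasing at every iteration.
    Components are ordered by mean in the result.
    """
    _check(data)
    if fit_space not in ("log", "linear"):
        raise ValueError("fit_space must be 'log' or 'linear'")
    x = data["intensity"].to_numpy(dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 cells for a mixture fit")
    if fit_space == "log":
        if np.any(x <= 0):
            raise ValueError("log-space fit requires positive intensities")
        x = np.log(x)
    if np.std(x) == 0:
        raise ValueError("degenerate data: zero variance")

    mu = np.percentile(x, [15.0, 85.0]).astype(float)
    if mu[0] == mu[1]:
        mu[1] = mu[0] + np.std(x)
    sd = np.full(2, float(np.std(x)))
    w = np.array([0.85, 0.15])
    sd_floor = 1e-6 * max(np.std(x), 1.0)

    ll_old = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        logp = np.stack([np.log(w[j]) + _normal_logpdf(x, mu[j], sd[j])
                         for j in range(2)])
        m = logp.max(axis=0)
        lse = m + np.log(np.exp(logp - m).sum(axis=0))
        ll = float(lse.sum())
        assert ll >= ll_old - 1e-9 * max(1.0, abs(ll_old)), \
            "EM log-likelihood decreased"
        resp = np.exp(logp - lse)
        nk = resp.sum(axis=1)
        w = nk / x.size
        mu = (resp @ x) / nk
        sd = np.sqrt(np.maximum(
            (resp @ x**2) / nk - mu**2, sd_floor**2))
        if ll - ll_old < tol * max(1.0, abs(ll)):
            converged = True
            break
        ll_old = ll

    order = np.argsort(mu)
    mu, sd, w = mu[order], sd[order], w[order]
    pooled_sd = float(np.sqrt(w @ sd**2))
    collapsed = abs(mu[1] - mu[0]) < pooled_sd
    return MixtureFit(w, mu, sd, fit_space, ll, converged, n_iter, collapsed)
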