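"""Synthetic single-cell data generators.

Three generators emulate the experiment types the inference stack consumes:

* :func:`simulate_mother_machine` — a fixed set of mother-cell lineages in a
  microfluidic device, observed at regular frame intervals. Each lineage is
  a single renewing unit: at division the proximal cell is retained and the
  sister discarded, so the number of tracked lineages is constant. Cells
  start in a low-SOS state (normal division, exponential elongation) and
  switch at rate ``alpha`` to a high-SOS state in which division is rare
  (rate ``lambda2``), elongation collapses, and the GFP reporter ramps to a
  high plateau. Observation is right-censored at the experiment end.
* :func:`simulate_branching_population` — an exact (Gillespie) stochastic
  simulation of the expanding two-type population with division rates
  ``lambda1``/``lambda2`` and switching rates ``alpha``/``beta``.
* :func:`simulate_snapshot` — per-cell fluorescence snapshots drawn from a
  two-component lognormal mixture, emulating batch-culture distributions
  with a main low-fluorescence population and a high-fluorescence shoulder.

All generators are deterministic under a fixed seed. Mother-machine
lineages use per-lineage substreams spawned from the master seed, so
changing ``n_lineages`` leaves existing lineages unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

LN2 = math.log(2.0)

#: Elongation rate (1/h) toward which high-SOS cells collapse; filamenting
#: cells keep adding a little mass but stay well below 0.1/h.
HIGH_STATE_ELONGATION = 0.05

__all__ = [
    "SimulationConfig",
    "MotherMachineResult",
    "BranchingResult",
    "simulate_mother_machine",
    "simulate_branching_population",
    "simulate_snapshot",
    "CONDITION_PRESETS",
    "lineage_growth_rate",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for the mother-machine simulator.

    Rates are per hour, the frame interval is in minutes, the duration in
    hours, fluorescence in arbitrary units per area. ``interdivision_cv``
    is the coefficient of variation of low-state interdivision times
    (gamma-distributed, mean ``ln2 / lambda1``). ``gfp_rise_time`` is the
    time constant of the GFP ramp after a switch; 0 gives an instantaneous
    jump so that threshold crossings coincide with switch events (up to
    frame quantization). ``noise_model`` is the standard deviation of
    multiplicative lognormal measurement noise on both channels.
    """

    alpha: float = 0.03
    beta: float = 0.0
    lambda1: float = LN2
    lambda2: float = 0.1
    interdivision_cv: float = 0.2
    frame_interval: float = 5.0
    duration: float = 24.0
    n_lineages: int = 200
    gfp_low_mean: float = 1.4
    gfp_low_sd: float = 0.15
    gfp_high_mean: float = 9.0
    gfp_high_sd: float = 1.0
    gfp_rise_time: float = 0.5
    noise_model: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "lambda1", "lambda2"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be >= 0")
        if self.n_lineages < 1:
            raise ValueError("n_lineages must be >= 1")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be > 0 minutes")
        if not self.duration > 0:
            raise ValueError("duration must be > 0 hours")
        if self.frame_interval / 60.0 >= self.duration:
            raise ValueError("frame interval must be shorter than the experiment")
        if self.gfp_high_mean <= self.gfp_low_mean:
            raise ValueError("gfp_high_mean must exceed gfp_low_mean")
        if self.interdivision_cv < 0:
            raise ValueError("interdivision_cv must be >= 0")


@dataclass(frozen=True)
class ConditionPreset:
    """Per-growth-medium defaults.

    ``mu_batch_wt`` is the batch doubling rate of the undamaged reference
    strain (doublings/h); ``lambda1``/``alpha``/``lambda2`` parameterize
    the damaged strain's two-state dynamics in that medium. Frame interval
    (minutes) and duration (hours) follow the imaging protocol of each
    condition (slow media are imaged less often but for longer).
    """

    name: str
    mu_batch_wt: float
    lambda1: float
    alpha: float
    lambda2: float
    frame_interval: float
    duration: float

    def config(self, **overrides) -> SimulationConfig:
        base = SimulationConfig(
            alpha=self.alpha,
            lambda1=self.lambda1,
            lambda2=self.lambda2,
            frame_interval=self.frame_interval,
            duration=self.duration,
        )
        return replace(base, **overrides) if overrides else base


#: Growth-condition presets. The damaged-strain division rates lambda1 are
#: taken from mother-machine-scale doubling rates (lower than batch WT),
#: and alpha is chosen so that the steady-state high-SOS fractions span the
#: observed few-percent range, with alpha larger in richer media while
#: lambda1 grows faster still — the combination that inverts the fraction
#: ordering across conditions.
CONDITION_PRESETS: dict[str, ConditionPreset] = {
    "M9-gly": ConditionPreset("M9-gly", 0.60, 0.208, 0.0163, 0.1, 12.0, 42.0),
    "M9-glu": ConditionPreset("M9-glu", 1.04, 0.603, 0.0357, 0.1, 10.0, 24.0),
    "M9-glu+aa": ConditionPreset("M9-glu+aa", 1.61, 0.679, 0.0357, 0.1, 5.0, 16.0),
}


@dataclass
class MotherMachineResult:
    """Simulated lineage table plus generative ground truth.

    ``frames`` holds per-frame records with columns
    ``time_h, lineage_id, length, gfp, mkate, division``.
    ``switch_times`` has one entry per lineage (NaN if the lineage never
    switched within the observation window); ``division_times`` the exact
    continuous-time division times per lineage. Ground truth exists only
    because this is a simulation; it is used by oracle tests, never by the
    inference code.
    """

    frames: pd.DataFrame
    switch_times: np.ndarray
    division_times: list[np.ndarray]
    config: SimulationConfig


def _lineage_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(index,))))


def _draw_interdivision(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.full(size, mean)
    shape = 1.0 / cv**2
    return rng.gamma(shape, mean / shape, size=size)


def _simulate_lineage(cfg: SimulationConfig, rng: np.random.Generator):
    """Continuous-time event history for one mother lineage.

    Returns (division_times, state_changes) where state_changes is a list
    of (time, new_state) with state 1 = high-SOS, 0 = low-SOS.
    """
    T = cfg.duration
    mean_tau = LN2 / cfg.lambda1 if cfg.lambda1 > 0 else math.inf
    divisions: list[float] = []
    changes: list[tuple[float, int]] = []
    t = 0.0
    state = 0
    # division scheduled for the current cycle (timer model, independent cycles)
    next_div = t + (_draw_interdivision(rng, mean_tau, cfg.interdivision_cv, 1)[0]
                    if math.isfinite(mean_tau) else math.inf)
    next_switch = t + rng.exponential(1.0 / cfg.alpha) if cfg.alpha > 0 else math.inf
    while t < T:
        if state == 0:
            t_next = min(next_div, next_switch)
            if t_next >= T:
                break
            t = t_next
            if next_switch <= next_div:
                state = 1
                changes.append((t, 1))
                next_switch = math.inf
                next_div = t + (rng.exponential(1.0 / cfg.lambda2)
                                if cfg.lambda2 > 0 else math.inf)
                next_revert = t + rng.exponential(1.0 / cfg.beta) if cfg.beta > 0 else math.inf
            else:
                divisions.append(t)
                next_div = t + (_draw_interdivision(rng, mean_tau, cfg.interdivision_cv, 1)[0]
                                if math.isfinite(mean_tau) else math.inf)
        else:
            t_next = min(next_div, next_revert)
            if t_next >= T:
                break
            t = t_next
            if next_revert <= next_div:
                state = 0
                changes.append((t, 0))
                next_switch = t + rng.exponential(1.0 / cfg.alpha) if cfg.alpha > 0 else math.inf
                next_div = t + (_draw_interdivision(rng, mean_tau, cfg.interdivision_cv, 1)[0]
                                if math.isfinite(mean_tau) else math.inf)
            else:
                divisions.append(t)
                next_div = t + (rng.exponential(1.0 / cfg.lambda2)
                                if cfg.lambda2 > 0 else math.inf)
    return np.asarray(divisions), changes


def _growth_integral(times: np.ndarray, changes, cfg: SimulationConfig) -> np.ndarray:
    """Cumulative elongation integral G(t) = ∫ r(s) ds at the frame times.

    Low state elongates at lambda1. After entering the high state the rate
    relaxes from lambda1 toward HIGH_STATE_ELONGATION with time constant
    gfp_rise_time (instantaneously if 0), emulating the collapse of growth
    in filamenting high-SOS cells.
    """
    r_low = cfg.lambda1
    r_hi = HIGH_STATE_ELONGATION
    tau_relax = cfg.gfp_rise_time
    # interval boundaries: start in low state at t=0
    bounds = [0.0] + [t for t, _ in changes] + [times[-1] + 1e-9]
    states = [0] + [s for _, s in changes]
    G = np.zeros_like(times)
    for (t0, t1), s in zip(zip(bounds[:-1], bounds[1:]), states):
        dt = np.clip(times, t0, t1) - t0
        if s == 0:
            seg = r_low * dt
        elif tau_relax > 0:
            ramp = (r_low - r_hi) * tau_relax * (1.0 - np.exp(-dt / tau_relax))
            seg = r_hi * dt + ramp
        else:
            seg = r_hi * dt
        G = G + seg
    return G


def _gfp_trace(times: np.ndarray, changes, low_level: float, high_level: float,
               rise_time: float) -> np.ndarray:
    """Deterministic reporter concentration: plateaus with exponential ramps.

    After each state change the level relaxes exponentially from its value
    at the change time toward the new plateau; consecutive changes chain,
    each ramp starting where the previous one left off.
    """
    g = np.full_like(times, low_level)
    level_at_change = low_level
    prev_target = low_level
    prev_time = 0.0
    for t_c, s in changes:
        if rise_time > 0:
            level_at_change = prev_target + (level_at_change - prev_target) * math.exp(
                -(t_c - prev_time) / rise_time)
        else:
            level_at_change = prev_target
        target = high_level if s == 1 else low_level
        after = times >= t_c
        if rise_time > 0:
            g[after] = target + (level_at_change - target) * np.exp(
                -(times[after] - t_c) / rise_time)
        else:
            g[after] = target
        prev_target = target
        prev_time = t_c
    return g


def simulate_mother_machine(config: SimulationConfig) -> MotherMachineResult:
    """Simulate per-frame mother-machine trajectories for all lineages."""
    cfg = config
    dt = cfg.frame_interval / 60.0
    n_frames = int(math.floor(cfg.duration / dt + 1e-9)) + 1
    times = np.arange(n_frames) * dt

    n_total = cfg.n_lineages * n_frames
    col_time = np.tile(times, cfg.n_lineages)
    col_lid = np.repeat(np.arange(cfg.n_lineages), n_frames)
    col_len = np.empty(n_total)
    col_gfp = np.empty(n_total)
    col_mkate = np.empty(n_total)
    col_div = np.zeros(n_total, dtype=bool)
    switch_times = np.full(cfg.n_lineages, np.nan)
    division_log: list[np.ndarray] = []
    for i in range(cfg.n_lineages):
        rng = _lineage_rng(cfg.seed, i)
        low_level = max(0.05 * cfg.gfp_low_mean,
                        rng.normal(cfg.gfp_low_mean, cfg.gfp_low_sd))
        high_level = max(cfg.gfp_low_mean,
                         rng.normal(cfg.gfp_high_mean, cfg.gfp_high_sd))
        divisions, changes = _simulate_lineage(cfg, rng)
        division_log.append(divisions)
        first_switch = next((t for t, s in changes if s == 1), np.nan)
        switch_times[i] = first_switch

        G = _growth_integral(times, changes, cfg)
        n_div_before = np.searchsorted(divisions, times, side="right")
        length = np.exp(G - LN2 * n_div_before)
        gfp = _gfp_trace(times, changes, low_level, high_level, cfg.gfp_rise_time)
        mkate = np.ones_like(times)
        if cfg.noise_model > 0:
            s = cfg.noise_model
            gfp = gfp * np.exp(rng.normal(-0.5 * s * s, s, size=n_frames))
            mkate = mkate * np.exp(rng.normal(-0.5 * s * s, s, size=n_frames))
            length = length * np.exp(rng.normal(0.0, 0.2 * s, size=n_frames))
        sl = slice(i * n_frames, (i + 1) * n_frames)
        col_len[sl] = length
        col_gfp[sl] = gfp
        col_mkate[sl] = mkate
        if divisions.size:
            idx = np.searchsorted(times, divisions, side="left")
            idx = idx[idx < n_frames]
            col_div[i * n_frames + idx] = True
    table = pd.DataFrame({
        "time_h": col_time,
        "lineage_id": col_lid,
        "length": col_len,
        "gfp": col_gfp,
        "mkate": col_mkate,
        "division": col_div,
    })
    return MotherMachineResult(table, switch_times, division_log, cfg)


def lineage_growth_rate(config: SimulationConfig) -> float:
    """Exact population growth rate implied by the low-state interdivision law.

    The discrete Euler–Lotka condition 2 E[exp(-lambda tau)] = 1 has a
    closed form for gamma interdivision times with mean ln2/lambda1 and
    coefficient of variation c: lambda = lambda1 * (2**(c^2) - 1)/(c^2 ln2).
    For c -> 0 this reduces to lambda1; for c = 0.2 it exceeds lambda1 by
    about 1.4%. This is the ground-truth target for growth-rate recovery
    from simulated interdivision times.
    """
    c2 = config.interdivision_cv**2
    if c2 == 0:
        return config.lambda1
    mean_tau = LN2 / config.lambda1
    return (2.0**c2 - 1.0) / (c2 * mean_tau)


@dataclass
class BranchingResult:
    """Trajectory of the stochastic two-type branching population.

    ``times``/``n1``/``n2`` sample the counts on a regular grid;
    ``f2`` is the high-state fraction at ``t_end``; ``downsampled``
    counts how often the population was thinned back to the cap, and
    ``log_scale`` accumulates ln(factor) so the true population size is
    (n1 + n2) * exp(log_scale) at the end.
    """

    times: np.ndarray
    n1: np.ndarray
    n2: np.ndarray
    f2: float
    downsampled: int
    log_scale: float


def simulate_branching_population(params, t_end: float, n0: int, cap: int,
                                  seed: int, n_record: int = 200) -> BranchingResult:
    """Exact event-driven simulation of the expanding two-type population.

    ``params`` carries (alpha, beta, lambda1, lambda2) per hour (any object
    with those attributes, e.g. :class:`sosswitch.population.TwoStateParams`).
    All ``n0`` founders start in the low-SOS state. Division produces two
    cells of the parent's state; switching moves one cell between states.
    When the population exceeds ``cap`` it is hypergeometrically thinned to
    ``cap`` cells, preserving state proportions in expectation, and the
    discarded growth factor is accumulated in ``log_scale``.
    """
    alpha, beta = params.alpha, params.beta
    lam1, lam2 = params.lambda1, params.lambda2
    if n0 < 1:
        raise ValueError("n0 must be >= 1")
    if cap < n0:
        raise ValueError("cap must be >= n0")
    rng = np.random.default_rng(seed)
    n1, n2 = n0, 0
    t = 0.0
    rec_times = np.linspace(0.0, t_end, n_record + 1)
    rec_n1 = np.zeros(n_record + 1, dtype=float)
    rec_n2 = np.zeros(n_record + 1, dtype=float)
    rec_idx = 0
    downsampled = 0
    log_scale = 0.0
    while True:
        total = n1 * (lam1 + alpha) + n2 * (lam2 + beta)
        if total <= 0:
            t = t_end
        else:
            t += rng.exponential(1.0 / total)
        while rec_idx <= n_record and rec_times[rec_idx] <= t:
            rec_n1[rec_idx], rec_n2[rec_idx] = n1, n2
            rec_idx += 1
        if t >= t_end:
            break
        u = rng.random() * total
        if u < n1 * lam1:
            n1 += 1
        elif u < n1 * (lam1 + alpha):
            n1 -= 1
            n2 += 1
        elif u < n1 * (lam1 + alpha) + n2 * lam2:
            n2 += 1
        else:
            n2 -= 1
            n1 += 1
        n = n1 + n2
        if n > cap:
            keep1 = rng.hypergeometric(n1, n2, cap)
            log_scale += math.log(n / cap)
            n1, n2 = int(keep1), cap - int(keep1)
            downsampled += 1
    f2 = rec_n2[-1] / max(1.0, rec_n1[-1] + rec_n2[-1])
    return BranchingResult(rec_times, rec_n1, rec_n2, f2, downsampled, log_scale)


def simulate_snapshot(f2: float, n: int, low_dist: Sequence[float],
                      high_dist: Sequence[float], seed: int,
                      n_replicates: int = 1, condition: str = "sim") -> pd.DataFrame:
    """Per-cell snapshot intensities from a two-component lognormal mixture.

    ``low_dist`` and ``high_dist`` are (mean, sd) of log-intensity; the
    high component has weight ``f2``. Cells are split evenly across
    ``n_replicates`` replicate labels (emulating biological repeats).
    Returns a DataFrame with columns ``intensity, replicate, condition``.
    """
    if not 0.0 <= f2 <= 1.0:
        raise ValueError(f"f2 must lie in [0, 1], got {f2}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    is_high = rng.random(n) < f2
    logv = np.where(is_high,
                    rng.normal(high_dist[0], high_dist[1], size=n),
                    rng.normal(low_dist[0], low_dist[1], size=n))
    replicate = np.arange(n) % n_replicates
    return pd.DataFrame({
        "intensity": np.exp(logv),
        "replicate": replicate,
        "condition": condition,
    })
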