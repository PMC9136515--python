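"""Lineage-trajectory tables: I/O, cell-cycle segmentation, per-cycle metrics.

The on-disk format is a plain CSV with mandatory header
``time_h, lineage_id, length, gfp, mkate, division`` (UTF-8, '.' decimal):
one row per frame per lineage, times in hours, lengths in arbitrary units,
fluorescence in a.u. per area, ``division`` true on the first frame after a
division. Within a lineage, time must be non-decreasing.

Divisions are taken from the explicit flag; for tables lacking it a
fallback detector marks any length drop of more than 25% between
consecutive frames. The final open cycle of every lineage is
right-censored at the last observed frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "CellCycle",
    "LineageTrack",
    "ElongationFit",
    "read_trajectories",
    "write_trajectories",
    "tracks_from_frame",
    "extract_cell_cycles",
    "elongation_rate",
    "lineage_metrics",
    "detect_divisions_from_length",
]

REQUIRED_COLUMNS = ["time_h", "lineage_id", "length", "gfp", "mkate", "division"]


@dataclass
class CellCycle:
    """One cell cycle of a mother lineage.

    ``span`` (= end_time - birth_time) is the observed time t_m; it equals
    the interdivision time only when the cycle is complete (not censored).
    """

    lineage_id: object
    birth_time: float
    end_time: float
    censored: bool
    times: np.ndarray
    lengths: np.ndarray
    gfp: np.ndarray

    @property
    def span(self) -> float:
        return self.end_time - self.birth_time

    @property
    def interdivision_time(self) -> float:
        if self.censored:
            raise ValueError("censored cycle has no interdivision time")
        return self.span

    @property
    def min_length(self) -> float:
        return float(np.min(self.lengths))

    @property
    def max_length(self) -> float:
        return float(np.max(self.lengths))

    @property
    def max_gfp(self) -> float:
        return float(np.max(self.gfp))


@dataclass
class LineageTrack:
    """Ordered per-frame records for one mother-cell lineage."""

    lineage_id: object
    times: np.ndarray
    lengths: np.ndarray
    gfp: np.ndarray
    mkate: np.ndarray
    division: np.ndarray  # bool, True on the first frame after a division

    @property
    def span(self) -> float:
        return float(self.times[-1] - self.times[0])


def read_trajectories(path) -> list[LineageTrack]:
    """Read a trajectory CSV into per-lineage tracks, validating the schema."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory file {path} is missing columns: {missing}")
    return tracks_from_frame(df)


def tracks_from_frame(df: pd.DataFrame) -> list[LineageTrack]:
    """Split a per-frame table into :class:`LineageTrack` objects.

    Raises a format error naming the offending CSV row (header = line 1)
    if time decreases within a lineage or a length is non-positive.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory table is missing columns: {missing}")
    tracks = []
    for lid, g in df.groupby("lineage_id", sort=True):
        t = g["time_h"].to_numpy(dtype=float)
        bad = np.nonzero(np.diff(t) < 0)[0]
        if bad.size:
            row = g.index[bad[0] + 1] + 2  # +1 diff offset, +1 header line
            raise ValueError(
                f"time decreases within lineage {lid!r} at row {row}")
        lengths = g["length"].to_numpy(dtype=float)
        if np.any(lengths <= 0):
            row = g.index[int(np.argmax(lengths <= 0))] + 2
            raise ValueError(f"non-positive length in lineage {lid!r} at row {row}")
        tracks.append(LineageTrack(
            lid, t, lengths,
            g["gfp"].to_numpy(dtype=float),
            g["mkate"].to_numpy(dtype=float),
            g["division"].to_numpy(dtype=bool),
        ))
    return tracks


def write_trajectories(tracks: list[LineageTrack], path) -> None:
    """Write tracks back to the trajectory CSV schema."""
    parts = [pd.DataFrame({
        "time_h": tr.times, "lineage_id": tr.lineage_id, "length": tr.lengths,
        "gfp": tr.gfp, "mkate": tr.mkate, "division": tr.division,
    }) for tr in tracks]
    out = (pd.concat(parts, ignore_index=True) if parts
           else pd.DataFrame(columns=REQUIRED_COLUMNS))
    out.to_csv(path, index=False)


def detect_divisions_from_length(lengths: np.ndarray, drop: float = 0.25) -> np.ndarray:
    """Fallback division detector: flag frames after a length drop > ``drop``."""
    flags = np.zeros(lengths.size, dtype=bool)
    flags[1:] = lengths[1:] < (1.0 - drop) * lengths[:-1]
    return flags


def extract_cell_cycles(track: LineageTrack) -> list[CellCycle]:
    """Segment a track into cell cycles at division flags.

    Cycles are contiguous: each complete cycle runs from its first frame to
    the first frame of the next cycle (the division frame), so the sum of
    spans equals the lineage observation span. The final open cycle is
    censored at the last observed frame. A single-frame track yields one
    censored cycle of zero span.
    """
    if track.times.size == 0:
        raise ValueError("empty track")
    div_idx = np.nonzero(track.division)[0]
    div_idx = div_idx[div_idx > 0]  # a flag on the very first frame opens no cycle
    starts = np.concatenate(([0], div_idx))
    ends = np.concatenate((div_idx, [track.times.size - 1]))
    cycles = []
    for k, (a, b) in enumerate(zip(starts, ends)):
        censored = k == len(starts) - 1
        # the division-flag frame is post-division: it opens the next cycle,
        # so a complete cycle's samples exclude it (the censored tail keeps
        # its last frame, which is still the same cell)
        if censored:
            sl = slice(a, b + 1)
        else:
            sl = slice(a, b) if b > a else slice(a, a + 1)
        cycles.append(CellCycle(
            track.lineage_id,
            float(track.times[a]), float(track.times[b]), censored,
            track.times[sl], track.lengths[sl], track.gfp[sl],
        ))
    return cycles


@dataclass
class ElongationFit:
    """Result of the per-cycle exponential elongation fit."""

    rate: float | None
    reason: str | None = None

    @property
    def accepted(self) -> bool:
        return self.rate is not None


def elongation_rate(cycle: CellCycle) -> ElongationFit:
    """Least-squares slope of ln(length) versus time within one cycle.

    Cycles with fewer than 3 frames are rejected (reason ``"min-points"``),
    as are negative fitted slopes (reason ``"negative-slope"``), mirroring
    standard curation of single-cell elongation fits.
    """
    if np.any(cycle.lengths <= 0):
        raise ValueError("non-positive cell length in cycle")
    if cycle.times.size < 3:
        return ElongationFit(None, "min-points")
    slope = np.polyfit(cycle.times, np.log(cycle.lengths), 1)[0]
    if slope < 0:
        return ElongationFit(None, "negative-slope")
    return ElongationFit(float(slope))


def lineage_metrics(track: LineageTrack, variant: str = "ratio") -> pd.DataFrame:
    """Per-cycle summary metrics: observed time, peak GFP, elongation proxy.

    For each cycle (censored ones included, with t_m the observed span) the
    elongation proxy is ln(l_m / l_0) / t_m by default (``variant="ratio"``,
    an exponential-rate estimate from the length extremes). The
    ``"difference"`` variant computes ln(l_m - l_0) / t_m instead and flags
    cycles where it is undefined (l_m <= l_0).
    """
    if variant not in ("ratio", "difference"):
        raise ValueError(f"unknown proxy variant {variant!r}")
    rows = []
    for cyc in extract_cell_cycles(track):
        t_m = cyc.span
        l0, lm = cyc.min_length, cyc.max_length
        undefined = False
        if t_m <= 0:
            proxy, undefined = np.nan, True
        elif variant == "ratio":
            proxy = math.log(lm / l0) / t_m
        elif lm > l0:
            proxy = math.log(lm - l0) / t_m
        else:
            proxy, undefined = np.nan, True
        rows.append({
            "lineage_id": cyc.lineage_id, "t_m": t_m, "max_gfp": cyc.max_gfp,
            "proxy_rate": proxy, "censored": cyc.censored, "undefined": undefined,
        })
    return pd.DataFrame(rows)
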