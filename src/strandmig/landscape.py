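"""Reduced-coordinate landscapes, strand-migration event detection, lifetimes
and occupancy statistics.

The reduced conformational space is the pair of per-frame averaged
hydrogen-bond fractions of the two competing helices, ``(f_P1, f_AT)``, each
in [0, 1].  A migration event is the first frame at which every P1 position
is simultaneously formed under a configurable criterion — by default the
binary hydrogen-bond cutoffs; alternatively a per-pair RMSD threshold
against the ideal pair templates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hbond import (BINARY_ANGLE_CUTOFF_DEG, BINARY_DISTANCE_CUTOFF,
                    DEFAULT_HBP, HBPParams, hbp_matrix)
from .metrics import base_pair_rmsd, ideal_pair_reference
from .registry import P1, ConstructRegistry, PairPosition
from .trajectory_io import Trajectory, span_duration

__all__ = [
    "ReducedCoord",
    "PopulationGrid",
    "EventRecord",
    "EventCriterion",
    "reduce_trajectory",
    "population_grid",
    "detect_full_p1",
    "pair_occupancy",
    "dwell_times",
]


@dataclass(frozen=True)
class ReducedCoord:
    frame: int
    f_p1: float
    f_at: float


@dataclass
class PopulationGrid:
    """2-D frame-count histogram over the reduced coordinates.

    ``counts[i, j]`` is the number of frames with ``f_p1`` in x-bin i and
    ``f_at`` in y-bin j; the display value is log(count) with empty bins
    masked (log-population colouring).
    """

    counts: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray

    @property
    def n_frames(self) -> int:
        return int(self.counts.sum())

    def log_population(self) -> np.ma.MaskedArray:
        masked = np.ma.masked_equal(self.counts, 0)
        return np.ma.log(masked)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.counts,
                     index=self.x_edges[:-1], columns=self.y_edges[:-1]
                     ).to_csv(path)


@dataclass(frozen=True)
class EventRecord:
    """A detected full-P1 formation with its contiguous lifetime run."""

    event_frame: int
    run_start: int
    run_end: int  # last frame of the contiguous run (inclusive)
    lifetime_ns: float
    criterion: str

    def __post_init__(self) -> None:
        if not self.run_start <= self.event_frame <= self.run_end:
            raise ValueError("event frame must lie inside its run")


@dataclass(frozen=True)
class EventCriterion:
    """Configuration of the per-position formation test.

    mode "hbond": all WC bonds of the position satisfy the binary cutoffs.
    mode "rmsd": the nucleobase RMSD against the ideal pair template is
    below ``rmsd_threshold``.
    """

    mode: str = "hbond"
    distance_cutoff: float = BINARY_DISTANCE_CUTOFF
    angle_cutoff_deg: float = BINARY_ANGLE_CUTOFF_DEG
    rmsd_threshold: float = 1.5

    def __post_init__(self) -> None:
        if self.mode not in ("hbond", "rmsd"):
            raise ValueError(f"unknown event criterion mode {self.mode!r}")

    @property
    def name(self) -> str:
        if self.mode == "hbond":
            return (f"hbond(d<{self.distance_cutoff:g}A,"
                    f"theta>{self.angle_cutoff_deg:g}deg)")
        return f"rmsd(<{self.rmsd_threshold:g}A)"


def reduce_trajectory(traj: Trajectory, registry: ConstructRegistry,
                      params: HBPParams = DEFAULT_HBP,
                      binary: bool = False) -> pd.DataFrame:
    """Per-frame generalized coordinates ``(f_p1, f_at)``.

    Both columns are averaged bond statistics over the full master bond list
    of the respective helix, bounded in [0, 1].
    """
    f_p1 = hbp_matrix(traj, registry, params, helix="P1", binary=binary).mean(axis=1)
    f_at = hbp_matrix(traj, registry, params, helix="AT", binary=binary).mean(axis=1)
    return pd.DataFrame({"frame": np.arange(traj.n_frames),
                         "f_p1": f_p1.to_numpy(), "f_at": f_at.to_numpy()})


def population_grid(series: pd.DataFrame | np.ndarray, n_bins: int = 50,
                    bounds: tuple[float, float] = (0.0, 1.0)) -> PopulationGrid:
    """Bin the reduced-coordinate series into an ``n_bins x n_bins`` grid.

    The total count always equals the number of frames (values at the upper
    bound fall in the last bin).
    """
    if isinstance(series, pd.DataFrame):
        x, y = series["f_p1"].to_numpy(), series["f_at"].to_numpy()
    else:
        arr = np.asarray(series, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    if len(x) == 0:
        raise ValueError("empty coordinate series")
    edges = np.linspace(bounds[0], bounds[1], n_bins + 1)
    counts, xe, ye = np.histogram2d(x, y, bins=(edges, edges))
    return PopulationGrid(counts.astype(int), xe, ye)


def _position_formed_matrix(traj: Trajectory, registry: ConstructRegistry,
                            criterion: EventCriterion,
                            positions: list[PairPosition]) -> np.ndarray:
    """Boolean (n_frames, n_positions): position satisfies the criterion."""
    out = np.empty((traj.n_frames, len(positions)), dtype=bool)
    if criterion.mode == "hbond":
        for j, pos in enumerate(positions):
            out[:, j] = _binary_position(traj, registry, pos, criterion)
    else:
        for j, pos in enumerate(positions):
            ref = ideal_pair_reference(registry, pos)
            vals = np.array([base_pair_rmsd(traj.frame(f), pos, ref)
                             for f in range(traj.n_frames)])
            out[:, j] = vals < criterion.rmsd_threshold
    return out


def _binary_position(traj: Trajectory, registry: ConstructRegistry,
                     pos: PairPosition, criterion: EventCriterion) -> np.ndarray:
    bonds = registry.bonds(pos.helix, pos.ordinal)
    ok = np.ones(traj.n_frames, dtype=bool)
    for b in bonds:
        dpos = traj.atom_series((b.donor_res, b.donor_atom))
        hpos = traj.atom_series((b.donor_res, b.h_atom))
        apos = traj.atom_series((b.acceptor_res, b.acceptor_atom))
        v1, v2 = dpos - hpos, apos - hpos
        n1 = np.linalg.norm(v1, axis=1)
        n2 = np.linalg.norm(v2, axis=1)
        theta = np.degrees(np.arccos(
            np.clip((v1 * v2).sum(axis=1) / (n1 * n2), -1.0, 1.0)))
        ok &= (n2 < criterion.distance_cutoff) & (theta > criterion.angle_cutoff_deg)
    return ok


def detect_full_p1(traj: Trajectory, registry: ConstructRegistry,
                   criterion: EventCriterion | None = None) -> EventRecord | None:
    """First frame at which all six P1 positions are simultaneously formed.

    Returns ``None`` when no frame qualifies.  The reported run is the
    maximal contiguous block of qualifying frames containing the event, and
    the lifetime is its end-minus-start duration at the trajectory's
    recording interval.
    """
    criterion = criterion or EventCriterion()
    positions = list(registry.positions(P1))
    formed = _position_formed_matrix(traj, registry, criterion, positions)
    full = formed.all(axis=1)
    if not full.any():
        return None
    event = int(np.argmax(full))
    run_end = event
    while run_end + 1 < len(full) and full[run_end + 1]:
        run_end += 1
    return EventRecord(event, event, run_end,
                       span_duration(event, run_end, traj.recording_interval_ps),
                       criterion.name)


def pair_occupancy(traj: Trajectory, position: PairPosition,
                   window: tuple[int, int],
                   criterion: EventCriterion | None = None,
                   registry: ConstructRegistry | None = None) -> tuple[int, float]:
    """Frames in ``[start, stop)`` where a position satisfies the criterion.

    Returns ``(count, count / window size)``.
    """
    criterion = criterion or EventCriterion()
    start, stop = window
    if not (0 <= start < stop <= traj.n_frames):
        raise ValueError(f"window {window} empty or outside trajectory")
    if registry is None:
        from .registry import build_default_registry
        registry = build_default_registry()
    formed = _position_formed_matrix(traj, registry, criterion, [position])[:, 0]
    count = int(formed[start:stop].sum())
    return count, count / (stop - start)


def dwell_times(state_series) -> list[int]:
    """Lengths of maximal True-runs, in order of occurrence."""
    arr = np.asarray(state_series, dtype=bool)
    if arr.size == 0:
        raise ValueError("empty state series")
    runs: list[int] = []
    current = 0
    for v in arr:
        if v:
            current += 1
        elif current:
            runs.append(current)
            current = 0
    if current:
        runs.append(current)
    return runs
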