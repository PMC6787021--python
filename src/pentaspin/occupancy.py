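"""Nano-pocket occupancy and contact counting over coordinate trajectories.

A lipid acyl chain is counted as resident in a pocket when at least
``min_atoms_in`` of its atoms lie within ``cutoff`` (default 5 A, boundary
inclusive) of any of the pocket's reference atoms.  A chain satisfying the
criterion for several pockets is assigned to the nearest one (minimum of
minimum distances), so the per-frame assignment is a partition.  Inputs are
assumed whole/unwrapped: no periodic-boundary handling is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "Frame",
    "TrajectoryFrames",
    "OccupancySettings",
    "OccupancySeries",
    "count_occupancy",
    "contact_timeseries",
    "occupancy_correlation",
]


@dataclass
class Frame:
    """One trajectory frame: pocket reference atoms and chain atoms, A."""

    time: float
    pockets: Dict[str, np.ndarray]
    chains: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, grp in list(self.pockets.items()) + list(self.chains.items()):
            arr = np.asarray(grp, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"group {name!r} must be an (n, 3) array")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"group {name!r} has non-finite coordinates")
        self.pockets = {k: np.asarray(v, dtype=float)
                        for k, v in self.pockets.items()}
        self.chains = {k: np.asarray(v, dtype=float)
                       for k, v in self.chains.items()}


@dataclass
class TrajectoryFrames:
    """Ordered trajectory frames with consistent pocket ids."""

    frames: list

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory has no frames")
        times = np.array([f.time for f in self.frames])
        if times.size >= 2 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")
        ids = set(self.frames[0].pockets)
        for f in self.frames:
            if set(f.pockets) != ids:
                raise ValueError("pocket ids differ between frames")
            for pid, arr in f.pockets.items():
                if arr.shape[0] == 0:
                    raise ValueError(f"pocket {pid!r} has no reference atoms")

    @property
    def pocket_ids(self) -> list:
        return sorted(self.frames[0].pockets)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


@dataclass(frozen=True)
class OccupancySettings:
    """Residency criterion: distance cutoff (A) and atom quorum."""

    cutoff: float = 5.0
    min_atoms_in: int = 1

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.min_atoms_in < 1:
            raise ValueError("min_atoms_in must be >= 1")


@dataclass
class OccupancySeries:
    """Per-frame resident-chain counts, total and per pocket."""

    times: np.ndarray
    counts: np.ndarray
    per_pocket: np.ndarray  # (n_frames, n_pockets)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        self.per_pocket = np.asarray(self.per_pocket, dtype=int)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.array_equal(self.per_pocket.sum(axis=1), self.counts):
            raise ValueError("per-pocket counts must sum to the total")

    @property
    def mean_occupancy(self) -> float:
        """Time-averaged total resident-chain count."""
        return float(np.mean(self.counts))


def _frame_assignment(frame: Frame, settings: OccupancySettings,
                      pocket_ids: list) -> dict:
    """Map chain id -> pocket index (or -1) for one frame."""
    assign = {}
    for cid, coords in frame.chains.items():
        best_pocket = -1
        best_dist = np.inf
        for p, pid in enumerate(pocket_ids):
            d = cdist(coords, frame.pockets[pid])
            n_in = int((d <= settings.cutoff).any(axis=1).sum())
            if n_in >= settings.min_atoms_in:
                dmin = float(d.min())
                if dmin < best_dist:
                    best_dist = dmin
                    best_pocket = p
        assign[cid] = best_pocket
    return assign


def count_occupancy(traj: TrajectoryFrames,
                    settings: OccupancySettings | None = None
                    ) -> OccupancySeries:
    """Count resident chains per pocket per frame (<= cutoff criterion)."""
    settings = settings or OccupancySettings()
    pids = traj.pocket_ids
    per_pocket = np.zeros((len(traj.frames), len(pids)), dtype=int)
    for k, frame in enumerate(traj.frames):
        assign = _frame_assignment(frame, settings, pids)
        for p in assign.values():
            if p >= 0:
                per_pocket[k, p] += 1
    return OccupancySeries(times=traj.times,
                           counts=per_pocket.sum(axis=1),
                           per_pocket=per_pocket)


def contact_timeseries(traj: TrajectoryFrames,
                       settings: OccupancySettings | None = None
                       ) -> np.ndarray:
    """(chain-atom, reference-atom) pairs within cutoff, per pocket per frame.

    Returns an (n_frames, n_pockets) integer array.
    """
    settings = settings or OccupancySettings()
    pids = traj.pocket_ids
    out = np.zeros((len(traj.frames), len(pids)), dtype=int)
    for k, frame in enumerate(traj.frames):
        if frame.chains:
            all_atoms = np.vstack(list(frame.chains.values()))
            for p, pid in enumerate(pids):
                d = cdist(all_atoms, frame.pockets[pid])
                out[k, p] = int((d <= settings.cutoff).sum())
    return out


def occupancy_correlation(series: OccupancySeries, metric: np.ndarray,
                          max_lag: int = 10) -> tuple[float, np.ndarray]:
    """Pearson correlation of occupancy with a per-frame scalar metric.

    Returns the lag-0 coefficient and the profile over lags -max_lag..+max_lag
    (positive lag: metric leads occupancy).  No significance claim attached.
    """
    metric = np.asarray(metric, dtype=float)
    counts = series.counts.astype(float)
    if metric.shape != counts.shape:
        raise ValueError("metric must align with the occupancy series")
    if counts.size < 10:
        raise ValueError("need at least 10 frames")
    if np.std(counts) == 0 or np.std(metric) == 0:
        raise ValueError("correlation undefined for a constant series")

    def _corr(a, b):
        if a.size < 3 or np.std(a) == 0 or np.std(b) == 0:
            return np.nan
        return float(np.corrcoef(a, b)[0, 1])

    lags = np.arange(-max_lag, max_lag + 1)
    profile = np.empty(lags.size)
    for i, lag in enumerate(lags):
        if lag >= 0:
            profile[i] = _corr(counts[lag:], metric[:counts.size - lag])
        else:
            profile[i] = _corr(counts[:counts.size + lag], metric[-lag:])
    r0 = profile[max_lag]
    return float(r0), profile
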