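"""Readers and writers for the plain-text formats used across the pipeline.

Time traces travel as two-column ASCII (comment lines prefixed ``#``, with
``# unit:`` and optional ``# tau_ns:`` headers) or as CSV with a
``t_us,amplitude`` / ``t_ns,amplitude`` header.  Trajectories travel as
extended XYZ with a sidecar YAML mapping atom indices to pockets and chains.
Distance distributions go out as CSV with per-bin bands and zone labels.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .dipolar import TimeTrace, estimate_noise_std
from .inversion import DistanceDistribution, zone_labels
from .occupancy import TrajectoryFrames, Frame, OccupancySeries

logger = logging.getLogger("pentaspin")

__all__ = [
    "read_trace",
    "write_trace",
    "write_distribution_csv",
    "write_report_json",
    "write_xyz_trajectory",
    "read_xyz_trajectory",
    "write_occupancy_csv",
]


def write_trace(path, trace: TimeTrace) -> None:
    """Write a trace as two-column ASCII with '#' headers."""
    path = Path(path)
    lines = [f"# unit: {trace.unit}"]
    for key in ("tau_ns", "label"):
        if key in trace.meta:
            lines.append(f"# {key}: {trace.meta[key]}")
    if trace.noise_std is not None:
        lines.append(f"# noise_std: {float(trace.noise_std)!r}")
    for ti, yi in zip(trace.t, trace.y):
        lines.append(f"{float(ti)!r} {float(yi)!r}")
    path.write_text("\n".join(lines) + "\n")


def read_trace(path, declared_unit: Optional[str] = None) -> TimeTrace:
    """Read a two-column ASCII/CSV trace, estimating noise if absent.

    Malformed rows raise with the offending line number; a third numeric
    column is ignored with a logged warning; '#' comment lines and blank
    lines are skipped, with comments preserved in ``meta``.
    """
    path = Path(path)
    meta: dict = {}
    unit = None
    noise_std = None
    ts, ys = [], []
    comments = []
    warned_extra = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            comments.append(line)
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                key, val = key.strip(), val.strip()
                if key == "unit":
                    unit = val
                elif key == "noise_std":
                    noise_std = float(val)
                else:
                    meta[key] = val
            continue
        fields = line.replace(",", " ").split()
        if lineno == 1 or (not ts and any(not _is_number(f) for f in fields)):
            # CSV header row like "t_us,amplitude"
            if all(not _is_number(f) for f in fields):
                if fields and fields[0].startswith("t_"):
                    unit = unit or fields[0][2:]
                continue
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected two numeric columns")
        if len(fields) > 2 and not warned_extra:
            logger.warning("%s:%d: extra columns ignored", path, lineno)
            warned_extra = True
        try:
            ts.append(float(fields[0]))
            ys.append(float(fields[1]))
        except ValueError:
            raise ValueError(f"{path}:{lineno}: malformed numeric row: {raw!r}")
    if not ts:
        raise ValueError(f"{path}: no data rows found")
    unit = unit or declared_unit or "us"
    if declared_unit is not None and unit != declared_unit:
        raise ValueError(f"{path}: header unit {unit!r} conflicts with "
                         f"declared unit {declared_unit!r}")
    if "tau_ns" in meta:
        meta["tau_ns"] = float(meta["tau_ns"])
    meta["comments"] = comments
    trace = TimeTrace(t=np.array(ts), y=np.array(ys), unit=unit,
                      noise_std=noise_std, meta=meta)
    if trace.noise_std is None and trace.t.size >= 4:
        trace = TimeTrace(trace.t, trace.y, trace.unit,
                          estimate_noise_std(trace.y), trace.meta)
    return trace


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_distribution_csv(path, dist: DistanceDistribution) -> None:
    """Write r_A, p, band_lo, band_hi, zone columns."""
    import pandas as pd

    n = dist.r.size
    zones = (zone_labels(dist.zones, dist.r) if dist.zones is not None
             else np.full(n, "", dtype=object))
    pd.DataFrame({
        "r_A": dist.r,
        "p": dist.p,
        "band_lo": dist.band_lo if dist.band_lo is not None else np.full(n, np.nan),
        "band_hi": dist.band_hi if dist.band_hi is not None else np.full(n, np.nan),
        "zone": zones,
    }).to_csv(path, index=False)


def write_report_json(path, report: dict) -> None:
    """Write a JSON report with deterministic key order."""
    Path(path).write_text(json.dumps(_sanitize(report), indent=2,
                                     sort_keys=True) + "\n")


def _sanitize(obj):
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_xyz_trajectory(path, map_path, traj: TrajectoryFrames) -> None:
    """Write frames as extended XYZ plus a YAML atom-index map.

    Atom order within a frame is all pocket groups (sorted id) then all
    chain groups (sorted id); the sidecar maps group ids to index ranges.
    """
    path, map_path = Path(path), Path(map_path)
    pids = sorted(traj.frames[0].pockets)
    cids = sorted(traj.frames[0].chains)
    mapping: dict = {"pockets": {}, "chains": {}}
    idx = 0
    for pid in pids:
        n = traj.frames[0].pockets[pid].shape[0]
        mapping["pockets"][pid] = list(range(idx, idx + n))
        idx += n
    for cid in cids:
        n = traj.frames[0].chains[cid].shape[0]
        mapping["chains"][cid] = list(range(idx, idx + n))
        idx += n
    n_atoms = idx
    lines = []
    for frame in traj.frames:
        lines.append(str(n_atoms))
        lines.append(f"time_ns={float(frame.time)!r}")
        for pid in pids:
            for xyz in frame.pockets[pid]:
                lines.append("P {0!r} {1!r} {2!r}".format(*map(float, xyz)))
        for cid in cids:
            for xyz in frame.chains[cid]:
                lines.append("C {0!r} {1!r} {2!r}".format(*map(float, xyz)))
    path.write_text("\n".join(lines) + "\n")
    map_path.write_text(yaml.safe_dump(mapping, sort_keys=True))


def read_xyz_trajectory(path, map_path) -> TrajectoryFrames:
    """Read an extended-XYZ trajectory with its YAML pocket/chain map."""
    path, map_path = Path(path), Path(map_path)
    mapping = yaml.safe_load(map_path.read_text())
    lines = path.read_text().splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n_atoms = int(lines[i].strip())
        comment = lines[i + 1]
        time = 0.0
        for tok in comment.split():
            if tok.startswith("time_ns="):
                time = float(tok.split("=", 1)[1])
        coords = np.empty((n_atoms, 3))
        for a in range(n_atoms):
            parts = lines[i + 2 + a].split()
            coords[a] = [float(v) for v in parts[1:4]]
        pockets = {pid: coords[idxs] for pid, idxs in mapping["pockets"].items()}
        chains = {cid: coords[idxs] for cid, idxs in mapping["chains"].items()}
        frames.append(Frame(time=time, pockets=pockets, chains=chains))
        i += 2 + n_atoms
    return TrajectoryFrames(frames=frames)


def write_occupancy_csv(path, series: OccupancySeries,
                        pocket_ids: Optional[list] = None) -> None:
    """Write time_ns, total and per-pocket occupancy columns."""
    import pandas as pd

    n_pockets = series.per_pocket.shape[1]
    names = pocket_ids or [f"pocket_{i + 1}" for i in range(n_pockets)]
    data = {"time_ns": series.times, "total": series.counts}
    for j, name in enumerate(names):
        data[name] = series.per_pocket[:, j]
    pd.DataFrame(data).to_csv(path, index=False)
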