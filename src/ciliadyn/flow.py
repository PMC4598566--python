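"""Bead-trajectory linking and flow statistics (velocity, tortuosity).

Cilia-driven fluid flow is read out by imaging fluorescent microspheres over
the epithelium. Per-frame bead detections are linked into trajectories;
each track yields

* **velocity** — total path length divided by elapsed time (µm/s), and
* **tortuosity** — total path length divided by the straight-line distance
  between first and last point (dimensionless, >= 1; 1 is perfectly
  straight).

Velocity is deliberately path-based so that velocity and tortuosity are
independent readouts of speed and directionality. Tracks whose net
displacement falls below a floor are excluded as non-motile. Conditions are
summarized as mean ± s.e.m. over tracks, as ratios relative to a control
condition, and compared with Welch's t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .imgio import ParameterError, warn
from .stats import sem, welch_t_test

__all__ = ["TrackSet", "FlowSummary", "link_tracks", "track_velocity",
           "track_tortuosity", "flow_summary"]


@dataclass
class TrackSet:
    """Ordered (frame, x, y) points per track, positions in µm."""

    tracks: dict[str, np.ndarray]
    frame_interval_s: float

    def __post_init__(self) -> None:
        if not (self.frame_interval_s > 0):
            raise ParameterError("frame_interval_s must be positive")
        for tid, arr in self.tracks.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ParameterError(f"track {tid!r} must be (n, 3)")
            if len(arr) >= 2 and np.any(np.diff(arr[:, 0]) <= 0):
                raise ParameterError(f"track {tid!r} frames not increasing")
            self.tracks[tid] = arr


@dataclass
class ConditionFlow:
    condition: str
    n_tracks: int
    mean_velocity_um_s: float
    sem_velocity_um_s: float
    mean_tortuosity: float
    sem_tortuosity: float
    relative_velocity: float = float("nan")
    relative_tortuosity: float = float("nan")
    velocity_t: float = float("nan")
    velocity_p: float = float("nan")
    tortuosity_t: float = float("nan")
    tortuosity_p: float = float("nan")


@dataclass
class FlowSummary:
    control: str
    conditions: dict[str, ConditionFlow] = field(default_factory=dict)
    per_track: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [vars(c) for _, c in sorted(self.conditions.items())]
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# linking
# --------------------------------------------------------------------------

def link_tracks(detections: Sequence[np.ndarray], max_disp_um: float,
                frame_interval_s: float) -> TrackSet:
    """Link per-frame detections into tracks by greedy mutual nearest
    neighbours.

    Between consecutive frames, pairs that are mutual nearest neighbours
    within ``max_disp_um`` are linked, closest pairs first (ties broken by
    lexicographic position). Unmatched detections start new tracks; a track
    that misses a frame ends, and a later detection starts a new id.
    """
    if len(detections) < 2:
        raise ParameterError("link_tracks needs at least two frames")
    detections = [np.asarray(d, dtype=float).reshape(-1, 2) for d in detections]
    next_id = 0
    # active[i] = track id owning detection i of the current frame
    points: dict[int, list[tuple[int, np.ndarray]]] = {}
    active: list[int] = []
    for i, p in enumerate(detections[0]):
        points[next_id] = [(0, p)]
        active.append(next_id)
        next_id += 1
    for t in range(1, len(detections)):
        prev, curr = detections[t - 1], detections[t]
        links: dict[int, int] = {}
        if len(prev) and len(curr):
            d = np.hypot(prev[:, None, 0] - curr[None, :, 0],
                         prev[:, None, 1] - curr[None, :, 1])
            cand = [(d[i, j], tuple(prev[i]), tuple(curr[j]), i, j)
                    for i in range(len(prev)) for j in range(len(curr))
                    if d[i, j] <= max_disp_um
                    and d[i, j] == d[i].min() and d[i, j] == d[:, j].min()]
            used_i: set[int] = set()
            used_j: set[int] = set()
            for dist, _, _, i, j in sorted(cand):
                if i not in used_i and j not in used_j:
                    links[j] = i
                    used_i.add(i)
                    used_j.add(j)
        new_active: list[int] = []
        for j, p in enumerate(curr):
            if j in links and links[j] < len(active):
                tid = active[links[j]]
            else:
                tid = next_id
                next_id += 1
                points[tid] = []
            points[tid].append((t, p))
            new_active.append(tid)
        active = new_active
    tracks = {f"track{tid:04d}": np.array([[f, p[0], p[1]] for f, p in pts])
              for tid, pts in points.items()}
    return TrackSet(tracks=tracks, frame_interval_s=frame_interval_s)


# --------------------------------------------------------------------------
# per-track statistics
# --------------------------------------------------------------------------

def _path_length(xy: np.ndarray) -> float:
    return float(np.hypot(*np.diff(xy, axis=0).T).sum())


def track_velocity(track: np.ndarray, frame_interval_s: float) -> float:
    """Path length divided by elapsed time, µm/s."""
    track = np.asarray(track, dtype=float)
    if len(track) < 2:
        warn("single-point track excluded from velocity")
        return float("nan")
    elapsed = (track[-1, 0] - track[0, 0]) * frame_interval_s
    return _path_length(track[:, 1:3]) / elapsed


def track_tortuosity(track: np.ndarray, min_net_disp_um: float = 0.1) -> float:
    """Path length over chord length; NaN (non-motile) when the net
    displacement is below ``min_net_disp_um``."""
    track = np.asarray(track, dtype=float)
    if len(track) < 2:
        warn("single-point track excluded from tortuosity")
        return float("nan")
    xy = track[:, 1:3]
    chord = float(np.hypot(*(xy[-1] - xy[0])))
    if chord <= min_net_disp_um:
        warn("non-motile track excluded from tortuosity")
        return float("nan")
    return _path_length(xy) / chord


def flow_summary(conditions: Mapping[str, TrackSet], control: str,
                 min_net_disp_um: float = 0.1) -> FlowSummary:
    """Condition-level velocity/tortuosity statistics relative to a control.

    Per condition: mean ± s.e.m. over tracks, the ratio of the condition mean
    to the control mean, and a two-sided Welch t-test against the control.
    Empty conditions are excluded with a warning.
    """
    if control not in conditions:
        raise ParameterError(f"control condition {control!r} not present")

    per_cond: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    track_rows = []
    for cond, ts in conditions.items():
        vels, torts = [], []
        for tid in sorted(ts.tracks):
            arr = ts.tracks[tid]
            if len(arr) < 2:
                continue
            v = track_velocity(arr, ts.frame_interval_s)
            tau = track_tortuosity(arr, min_net_disp_um)
            track_rows.append({"condition": cond, "track_id": tid,
                               "velocity_um_s": v, "tortuosity": tau})
            if np.isfinite(v):
                vels.append(v)
            if np.isfinite(tau):
                torts.append(tau)
        if not vels:
            warn(f"condition {cond!r} has no analyzable tracks; excluded")
            continue
        per_cond[cond] = (np.array(vels), np.array(torts))

    out = FlowSummary(control=control,
                      per_track=pd.DataFrame(track_rows))
    ctl_v, ctl_t = per_cond[control]
    for cond, (vels, torts) in per_cond.items():
        c = ConditionFlow(
            condition=cond, n_tracks=len(vels),
            mean_velocity_um_s=float(vels.mean()),
            sem_velocity_um_s=sem(vels),
            mean_tortuosity=float(torts.mean()) if len(torts) else float("nan"),
            sem_tortuosity=sem(torts) if len(torts) >= 2 else float("nan"),
        )
        c.relative_velocity = c.mean_velocity_um_s / ctl_v.mean()
        if len(torts) and len(ctl_t):
            c.relative_tortuosity = c.mean_tortuosity / ctl_t.mean()
        if cond != control:
            c.velocity_t, c.velocity_p = welch_t_test(vels, ctl_v)
            if len(torts) >= 2 and len(ctl_t) >= 2:
                c.tortuosity_t, c.tortuosity_p = welch_t_test(torts, ctl_t)
        out.conditions[cond] = c
    return out
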