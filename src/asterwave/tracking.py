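"""Plus-end comet tracks: frame-to-frame linking and velocity estimation.

Growing microtubule plus ends (EB1 comets in experiments) appear as moving
point detections; linking them into tracks gives the polymerization
velocity v_p and, downstream, the density and polarity profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import EmptyInputError, InvalidParameterError

__all__ = ["Track", "link_comets", "estimate_vp", "VpEstimate"]


@dataclass
class Track:
    """One plus-end trajectory: ordered samples (t, x, y)."""

    track_id: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    aster_id: int | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.t) < 2:
            raise InvalidParameterError("a track needs >= 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise InvalidParameterError("track times must strictly increase")
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise InvalidParameterError("t, x, y must have equal length")

    def __len__(self):
        return len(self.t)

    @property
    def displacements(self) -> np.ndarray:
        """Per-step displacement vectors, shape (n-1, 2)."""
        return np.column_stack([np.diff(self.x), np.diff(self.y)])

    @property
    def speeds(self) -> np.ndarray:
        """Per-step speeds |dr|/dt, µm/min."""
        dr = np.hypot(np.diff(self.x), np.diff(self.y))
        return dr / np.diff(self.t)


@dataclass(frozen=True)
class VpEstimate:
    v_p: float
    sem: float
    n_tracks: int


def link_comets(detections, max_disp: float):
    """Greedy nearest-neighbour linking of per-frame detections into tracks.

    Parameters
    ----------
    detections : sequence of (t, points)
        Time-ordered frames; ``points`` is an (n, 2) array of positions.
        Empty frames are allowed.
    max_disp : float
        Maximum frame-to-frame displacement, µm.  No gap closing: a track
        that finds no match within ``max_disp`` terminates, and unmatched
        detections start new tracks.

    Returns
    -------
    list of :class:`Track` (tracks with at least two samples).
    """
    next_id = 0
    store: dict[int, list] = {}    # id -> [(t, x, y), ...]
    prev_pts = np.empty((0, 2))
    prev_ids: list[int] = []
    for frame in detections:
        t, pts = frame[0], frame[1]
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        cur_ids: list[int | None] = [None] * len(pts)
        if len(prev_pts) and len(pts):
            tree = cKDTree(pts)
            pairs = []
            for i, p in enumerate(prev_pts):
                for j in tree.query_ball_point(p, max_disp):
                    d = float(np.hypot(p[0] - pts[j, 0], p[1] - pts[j, 1]))
                    pairs.append((d, i, j))
            taken_prev: set[int] = set()
            for d, i, j in sorted(pairs):
                if i in taken_prev or cur_ids[j] is not None:
                    continue
                taken_prev.add(i)
                tid = prev_ids[i]
                store[tid].append((t, pts[j, 0], pts[j, 1]))
                cur_ids[j] = tid
        for j in range(len(pts)):
            if cur_ids[j] is None:
                tid = next_id
                next_id += 1
                store[tid] = [(t, pts[j, 0], pts[j, 1])]
                cur_ids[j] = tid
        prev_pts = pts
        prev_ids = cur_ids
    tracks = []
    for tid in sorted(store):
        samples = store[tid]
        if len(samples) >= 2:
            arr = np.array(samples)
            tracks.append(Track(tid, arr[:, 0], arr[:, 1], arr[:, 2]))
    return tracks


def estimate_vp(tracks) -> VpEstimate:
    """Polymerization velocity from plus-end tracks.

    The mean frame-to-frame speed is computed per track, then averaged
    across tracks; the s.e.m. is taken across tracks.
    """
    per_track = [float(np.mean(tr.speeds)) for tr in tracks if len(tr) >= 2]
    if not per_track:
        raise EmptyInputError("no tracks with >= 2 samples")
    per_track = np.array(per_track)
    n = len(per_track)
    sem = float(per_track.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return VpEstimate(v_p=float(per_track.mean()), sem=sem, n_tracks=n)
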