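"""Identity-preserving linking of per-frame objects across time.

Centroids of the single-pixel-wide centerlines are linked frame to frame by
optimal bipartite assignment (Hungarian algorithm) minimizing the total
squared displacement, with matches farther than ``max_disp_px`` forbidden —
equivalent, at these instance sizes, to the Crocker–Grier minimization used
for colloidal particle tracking.  Objects that disappear may reappear within
``memory_frames`` frames and keep their identity (gap closing); unmatched
new objects start fresh tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .segmentation import Centerline

__all__ = ["ObjectRecord", "Track", "centroids", "link",
           "tracks_to_table", "table_to_tracks"]

_BIG = 1e30


@dataclass
class ObjectRecord:
    """One segmented object in one frame."""

    frame: int
    y: float
    x: float
    length_um: float = 0.0
    centerline: Centerline | None = None

    @property
    def position(self) -> np.ndarray:
        return np.array([self.y, self.x])


@dataclass
class Track:
    """One object's records across frames, gaps allowed."""

    track_id: int
    records: list[ObjectRecord] = field(default_factory=list)

    @property
    def frames(self) -> list[int]:
        return [r.frame for r in self.records]

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def last(self) -> ObjectRecord:
        return self.records[-1]

    @property
    def gap_count(self) -> int:
        f = self.frames
        return (f[-1] - f[0] + 1) - len(f)

    def lengths_um(self) -> np.ndarray:
        return np.array([r.length_um for r in self.records])

    def positions(self) -> np.ndarray:
        return np.array([[r.y, r.x] for r in self.records])


def centroids(centerlines: Sequence[Centerline]) -> list[ObjectRecord]:
    """Unweighted mean of centerline pixel coordinates, one record each."""
    out = []
    for c in centerlines:
        y, x = c.centroid()
        out.append(ObjectRecord(frame=c.frame, y=y, x=x,
                                length_um=c.length_um, centerline=c))
    return out


def _normalize(records_by_frame) -> dict[int, list[ObjectRecord]]:
    if isinstance(records_by_frame, Mapping):
        return {int(f): list(v) for f, v in records_by_frame.items()}
    return {f: list(v) for f, v in enumerate(records_by_frame)}


def link(records_by_frame,
         max_disp_px: float = 20.0,
         memory_frames: int = 2) -> list[Track]:
    """Link records into tracks.

    ``records_by_frame`` maps frame index to that frame's records (a mapping,
    or a sequence indexed by frame).  Per frame, candidates are all tracks
    last seen at most ``memory_frames + 1`` frames earlier; the assignment
    minimizes total squared displacement with per-match displacements capped
    at ``max_disp_px`` (a non-match carries the conventional
    ``max_disp_px**2`` penalty, so every feasible match is taken).  Exact
    cost ties break in favour of the lowest-id previous object.  Every input
    record ends up in exactly one track.
    """
    if max_disp_px <= 0:
        raise ValueError("max_disp_px must be > 0")
    if memory_frames < 0:
        raise ValueError("memory_frames must be >= 0")
    by_frame = _normalize(records_by_frame)
    tracks: list[Track] = []
    open_tracks: list[Track] = []
    d2max = float(max_disp_px) ** 2
    eps = 1e-9 * max(d2max, 1.0)
    for f in sorted(by_frame):
        recs = by_frame[f]
        open_tracks = [t for t in open_tracks
                       if f - t.last.frame <= memory_frames + 1]
        n, m = len(open_tracks), len(recs)
        if n == 0 or m == 0:
            for r in recs:
                t = Track(track_id=len(tracks), records=[r])
                tracks.append(t)
                open_tracks.append(t)
            continue
        C = np.full((n + m, n + m), _BIG)
        for i, t in enumerate(open_tracks):
            p = t.last.position
            for j, r in enumerate(recs):
                d2 = float(np.sum((p - r.position) ** 2))
                if d2 <= d2max:
                    C[i, j] = d2
            # dummy: track i goes unmatched; cheaper for high i so that the
            # lowest previous index wins exact ties for a real match
            C[i, m + i] = d2max - eps * i
        for j in range(m):
            C[n + j, j] = d2max
        C[n:, m:] = 0.0
        rows, cols = linear_sum_assignment(C)
        matched_new = set()
        for i, j in zip(rows, cols):
            if i < n and j < m and C[i, j] < _BIG:
                open_tracks[i].records.append(recs[j])
                matched_new.add(j)
        for j, r in enumerate(recs):
            if j not in matched_new:
                t = Track(track_id=len(tracks), records=[r])
                tracks.append(t)
                open_tracks.append(t)
    return tracks


def tracks_to_table(tracks: Sequence[Track]) -> pd.DataFrame:
    """Flat (frame, track_id, y, x, length_um) table; round-trips losslessly."""
    rows = [(r.frame, t.track_id, r.y, r.x, r.length_um)
            for t in tracks for r in t.records]
    return pd.DataFrame(rows, columns=["frame", "track_id", "y", "x",
                                       "length_um"]).sort_values(
        ["track_id", "frame"], ignore_index=True)


def table_to_tracks(df: pd.DataFrame) -> list[Track]:
    tracks = []
    for tid, grp in df.sort_values("frame").groupby("track_id"):
        recs = [ObjectRecord(frame=int(r.frame), y=float(r.y), x=float(r.x),
                             length_um=float(r.length_um))
                for r in grp.itertuples()]
        tracks.append(Track(track_id=int(tid), records=recs))
    return sorted(tracks, key=lambda t: t.track_id)
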