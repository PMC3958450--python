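"""Per-track morphology-dynamics statistics.

The central statistic is the *dynamic range* of an object's length series,

    100 * (max - min) / mean,

the single-number summary of how much a mitochondrion remodels over the
observation window (fission/fusion-active networks reach ~100% of their
length; fragmented, inactive mitochondria only ~15%).  Motion is summarized
by the net displacement, the total path length, and their ratio — the
confinement ratio, a standard directionality measure for organelle motion.

Condition-level summaries use median and interquartile range, which are
robust to the heterogeneous track lengths that survive gap closing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .tracking import Track

__all__ = ["DynamicsSummary", "dynamic_range", "net_displacement",
           "path_length", "directionality", "summarize"]

METRICS = ["n_records", "mean_length_um", "dynamic_range_pct",
           "net_displacement_um", "path_length_um", "directionality"]


@dataclass
class DynamicsSummary:
    """Per-track metrics plus per-condition medians and IQRs."""

    per_track: pd.DataFrame = field(repr=False)
    condition: dict = field(default_factory=dict)
    n_excluded_short: int = 0
    min_track_len: int = 3

    def median(self, metric: str) -> float:
        return self.condition[metric]["median"]


def dynamic_range(length_series: Sequence[float]) -> float:
    """Percent dynamic range ``100 (max - min) / mean`` of a length series."""
    x = np.asarray(length_series, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 2:
        raise ValueError("need at least 2 finite values")
    if np.any(x <= 0) or x.mean() <= 0:
        raise ValueError("length series must be positive")
    return float(100.0 * (x.max() - x.min()) / x.mean())


def net_displacement(track: Track, pixel_size_um: float) -> float:
    """Euclidean distance between first and last centroid, micrometres."""
    p = track.positions()
    if len(p) < 2:
        raise ValueError("need at least 2 records")
    return float(np.linalg.norm(p[-1] - p[0]) * pixel_size_um)


def path_length(track: Track, pixel_size_um: float) -> float:
    """Sum of consecutive centroid step distances, micrometres."""
    p = track.positions()
    if len(p) < 2:
        raise ValueError("need at least 2 records")
    return float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum() * pixel_size_um)


def directionality(track: Track) -> float:
    """Confinement ratio: net displacement / path length, in [0, 1].

    1 for straight monotone motion, 0 for a closed loop.  Undefined (error)
    for a strictly stationary track; :func:`summarize` reports 0 there.
    """
    p = track.positions()
    if len(p) < 2:
        raise ValueError("need at least 2 records")
    path = float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())
    if path <= 0:
        raise ValueError("path length is zero")
    return float(np.linalg.norm(p[-1] - p[0]) / path)


def summarize(tracks: Sequence[Track], pixel_size_um: float,
              min_track_len: int = 3) -> DynamicsSummary:
    """Per-track metrics for tracks with >= ``min_track_len`` records,
    plus condition-level median/IQR of each metric.

    Shorter tracks are excluded and counted, not deleted upstream.  A
    stationary track gets directionality 0 by convention (no motion to be
    directional about).
    """
    rows = []
    n_excluded = 0
    for t in tracks:
        if t.n_records < min_track_len:
            n_excluded += 1
            continue
        lengths = t.lengths_um()
        path = path_length(t, pixel_size_um)
        net = net_displacement(t, pixel_size_um)
        rows.append({
            "track_id": t.track_id,
            "n_records": t.n_records,
            "mean_length_um": float(lengths.mean()),
            "dynamic_range_pct": dynamic_range(lengths),
            "net_displacement_um": net,
            "path_length_um": path,
            "directionality": net / path if path > 0 else 0.0,
        })
    if not rows:
        raise ValueError(f"no tracks with >= {min_track_len} records")
    per_track = pd.DataFrame(rows)
    condition = {}
    for metric in METRICS:
        v = per_track[metric].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        condition[metric] = {"median": float(med), "iqr": float(q3 - q1)}
    return DynamicsSummary(per_track=per_track, condition=condition,
                           n_excluded_short=n_excluded,
                           min_track_len=min_track_len)
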