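import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odyn.segmentation import Centerline
from odyn.tracking import (ObjectRecord, Track, centroids, link,
                           table_to_tracks, tracks_to_table)


def make_records(positions_by_frame):
    return {f: [ObjectRecord(frame=f, y=float(y), x=float(x))
                for y, x in pos]
            for f, pos in positions_by_frame.items()}


def bruteforce_link(records_by_frame, max_disp_px, memory_frames):
    """Frame-sequential linker with exhaustive per-frame assignment.

    Enumerates every injective partial matching between open tracks and the
    new frame's records and picks the one minimizing
    sum(d^2) + max_disp^2 * (#unmatched on either side), the same objective
    the production linker optimizes with the Hungarian algorithm.
    """
    d2max = max_disp_px ** 2
    tracks, open_tracks = [], []
    for f in sorted(records_by_frame):
        recs = records_by_frame[f]
        open_tracks = [t for t in open_tracks
                       if f - t[-1].frame <= memory_frames + 1]
        n, m = len(open_tracks), len(recs)
        best, best_cost = None, np.inf
        for k in range(min(n, m) + 1):
            for rows in itertools.combinations(range(n), k):
                for cols in itertools.permutations(range(m), k):
                    cost = 0.0
                    ok = True
                    for i, j in zip(rows, cols):
                        d2 = np.sum((open_tracks[i][-1].position
                                     - recs[j].position) ** 2)
                        if d2 > d2max:
                            ok = False
                            break
                        cost += d2
                    if not ok:
                        continue
                    cost += d2max * ((n - k) + (m - k))
                    if cost < best_cost - 1e-12:
                        best_cost, best = cost, (rows, cols)
        rows, cols = best
        matched = set(cols)
        for i, j in zip(rows, cols):
            open_tracks[i].append(recs[j])
        for j, r in enumerate(recs):
            if j not in matched:
                t = [r]
                tracks.append(t)
                open_tracks.append(t)
    return tracks


def as_partition(tracks):
    """Canonical representation: set of tuples of (frame, y, x)."""
    out = set()
    for t in tracks:
        recs = t.records if isinstance(t, Track) else t
        out.add(tuple((r.frame, r.y, r.x) for r in recs))
    return out


class TestCentroids:
    def test_single_pixel(self):
        c = Centerline(frame=0, path=np.array([[5, 7]]), length_um=0.0)
        rec = centroids([c])[0]
        assert (rec.y, rec.x) == (5.0, 7.0)

    def test_axial_path(self):
        path = np.array([(0, x) for x in range(11)])
        rec = centroids([Centerline(0, path, 0.9)])[0]
        assert (rec.y, rec.x) == (0.0, 5.0)

    def test_l_shaped_path_matches_direct_mean(self):
        path = np.array([(0, 0), (0, 1), (0, 2), (0, 3), (0, 4),
                         (1, 4), (2, 4), (3, 4), (4, 4)])
        rec = centroids([Centerline(0, path, 1.0)])[0]
        np.testing.assert_allclose([rec.y, rec.x], path.mean(axis=0))


class TestLink:
    def test_single_drifting_object_is_one_track(self):
        recs = make_records({f: [(10.0, 10.0 + f)] for f in range(8)})
        tracks = link(recs, max_disp_px=5, memory_frames=0)
        assert len(tracks) == 1
        assert tracks[0].n_records == 8
        assert tracks[0].gap_count == 0

    def test_memory_closes_gap(self):
        pos = {f: [(10.0, 10.0 + f)] for f in range(8)}
        del pos[4]
        tracks = link(make_records(pos), max_disp_px=5, memory_frames=2)
        assert len(tracks) == 1
        assert tracks[0].gap_count == 1

    def test_no_memory_splits_at_gap(self):
        pos = {f: [(10.0, 10.0 + f)] for f in range(8)}
        del pos[4]
        tracks = link(make_records(pos), max_disp_px=5, memory_frames=0)
        assert len(tracks) == 2

    def test_jump_beyond_max_disp_starts_new_track(self):
        recs = make_records({0: [(10, 10)], 1: [(10, 40)]})
        assert len(link(recs, max_disp_px=5, memory_frames=0)) == 2

    def test_conflicting_candidates_match_bruteforce(self, rng):
        recs = make_records({
            0: [(10, 10), (10, 14)],
            1: [(10, 12), (10, 16)],
        })
        got = link(recs, max_disp_px=6, memory_frames=0)
        want = bruteforce_link(recs, 6, 0)
        assert as_partition(got) == as_partition(want)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(0, 2), st.integers(2, 5))
    def test_equivalence_with_exhaustive_assignment(self, s, memory, n_frames):
        r = np.random.default_rng(s)
        recs = {}
        for f in range(n_frames):
            k = int(r.integers(0, 5))
            recs[f] = [ObjectRecord(frame=f, y=float(y), x=float(x))
                       for y, x in r.uniform(0, 30, size=(k, 2))]
        got = link(recs, max_disp_px=10.0, memory_frames=memory)
        want = bruteforce_link(recs, 10.0, memory)
        assert as_partition(got) == as_partition(want)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_conservation_of_records(self, s):
        r = np.random.default_rng(s)
        recs = {f: [ObjectRecord(frame=f, y=float(y), x=float(x))
                    for y, x in r.uniform(0, 50, size=(int(r.integers(0, 6)), 2))]
                for f in range(6)}
        tracks = link(recs, max_disp_px=8.0, memory_frames=1)
        n_in = sum(len(v) for v in recs.values())
        assert sum(t.n_records for t in tracks) == n_in
        seen = [(r_.frame, r_.y, r_.x) for t in tracks for r_ in t.records]
        assert len(seen) == len(set(seen))

    def test_huge_max_disp_single_object_one_track(self, rng):
        recs = make_records({f: [tuple(rng.uniform(0, 100, 2))] for f in range(10)})
        assert len(link(recs, max_disp_px=1e6, memory_frames=0)) == 1

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            link({}, max_disp_px=0)
        with pytest.raises(ValueError):
            link({}, memory_frames=-1)


class TestTrackTable:
    def test_round_trip(self, rng):
        recs = {f: [ObjectRecord(frame=f, y=float(y), x=float(x),
                                 length_um=float(rng.uniform(1, 3)))
                    for y, x in rng.uniform(0, 50, size=(3, 2))]
                for f in range(4)}
        tracks = link(recs, max_disp_px=50, memory_frames=1)
        df = tracks_to_table(tracks)
        back = table_to_tracks(df)
        assert as_partition(back) == as_partition(tracks)
        for a, b in zip(sorted(tracks, key=lambda t: t.track_id), back):
            np.testing.assert_allclose(a.lengths_um(), b.lengths_um())
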