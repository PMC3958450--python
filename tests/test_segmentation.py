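import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skimage import morphology

from odyn import segmentation as seg
from tests.conftest import synthetic_tube


def midgrey_bruteforce(frame, radius, offset=0.0):
    """Independent per-pixel scan of the disk neighbourhood, reflect padding."""
    f = np.asarray(frame, dtype=float)
    padded = np.pad(f, radius, mode="reflect")
    dy, dx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    disk = (dy ** 2 + dx ** 2) <= radius ** 2
    offs = np.argwhere(disk) - radius
    out = np.zeros_like(f, dtype=bool)
    for y in range(f.shape[0]):
        for x in range(f.shape[1]):
            vals = [padded[y + radius + oy, x + radius + ox] for oy, ox in offs]
            out[y, x] = f[y, x] > (min(vals) + max(vals)) / 2.0 - offset
    return out


class TestMidgrey:
    def test_constant_image_is_all_background(self):
        mask = seg.midgrey_threshold(np.full((20, 20), 100), radius=3)
        assert not mask.data.any()

    def test_single_bright_pixel_is_foreground(self):
        img = np.zeros((21, 21))
        img[10, 10] = 255
        mask = seg.midgrey_threshold(img, radius=3)
        assert mask.data[10, 10]

    def test_matches_bruteforce_on_random_image(self, rng):
        img = rng.integers(0, 256, size=(32, 32))
        got = seg.midgrey_threshold(img, radius=3).data
        np.testing.assert_array_equal(got, midgrey_bruteforce(img, 3))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(1, 3),
           st.integers(6, 20), st.integers(6, 20))
    def test_bruteforce_equivalence_property(self, s, radius, h, w):
        img = np.random.default_rng(s).integers(0, 256, size=(h, w))
        got = seg.midgrey_threshold(img, radius=radius).data
        np.testing.assert_array_equal(got, midgrey_bruteforce(img, radius))

    def test_offset_shifts_threshold(self):
        img = np.zeros((15, 15))
        img[7, 7] = 100
        # neighbours of the peak see threshold 50; offset pushes them over
        assert not seg.midgrey_threshold(img, 3, offset=0).data[7, 8]
        assert seg.midgrey_threshold(img, 3, offset=60).data[7, 8]

    def test_oversized_radius_rejected(self):
        with pytest.raises(ValueError):
            seg.midgrey_threshold(np.zeros((10, 10)), radius=11)


class TestCleanMask:
    def test_zero_min_area_is_identity(self, rng):
        m = rng.random((20, 20)) > 0.5
        np.testing.assert_array_equal(seg.clean_mask(m, 0).data, m)

    def test_small_component_removed(self):
        m = np.zeros((20, 40), dtype=bool)
        m[2, 2:5] = True          # area 3
        m[10:15, 10:20] = True    # area 50
        out = seg.clean_mask(m, 5).data
        assert not out[2, 3] and out[12, 15]
        assert out.sum() == 50

    def test_checkerboard_is_one_component_under_8_connectivity(self):
        m = np.indices((8, 8)).sum(axis=0) % 2 == 0
        np.testing.assert_array_equal(seg.clean_mask(m, 2).data, m)


class TestMedialAxisCenterlines:
    def test_empty_mask_gives_empty_list(self):
        assert seg.medial_axis_centerlines(np.zeros((10, 10), bool)) == []

    def test_solid_bar_gives_single_axis(self):
        m = np.zeros((9, 60), dtype=bool)
        m[3:6, 5:55] = True       # 50 x 3 bar
        cls = seg.medial_axis_centerlines(m)
        assert len(cls) == 1
        assert 47 <= cls[0].n_pixels <= 50

    def test_two_bars_give_two_centerlines(self):
        m = np.zeros((30, 60), dtype=bool)
        m[5:8, 5:55] = True
        m[20:23, 5:55] = True
        assert len(seg.medial_axis_centerlines(m)) == 2

    def test_spur_pruned_from_t_shape(self):
        m = np.zeros((30, 40), dtype=bool)
        m[14:17, 5:35] = True
        m[17:20, 19:22] = True    # 3-px stub off the bar
        cls = seg.medial_axis_centerlines(m, spur_length_px=4.0)
        assert len(cls) == 1
        # the retained path spans the bar, not the stub
        ys = cls[0].path[:, 0]
        assert ys.max() - ys.min() <= 4


class TestRidgeCenterlines:
    def test_blank_frame_gives_empty_list(self):
        assert seg.ridge_centerlines(np.zeros((40, 40))) == []

    def test_single_tubule_traced_close_to_truth(self):
        img, truth = synthetic_tube()
        cls = seg.ridge_centerlines(img, tubule_sigma_px=1.5)
        assert len(cls) == 1
        # every traced pixel within 2 px of the generating axis
        d = np.min(np.linalg.norm(
            cls[0].path[:, None, :].astype(float) - truth[None, :, :], axis=2),
            axis=1)
        assert d.max() <= 2.0

    def test_parallel_tubules_stay_separate(self):
        from scipy import ndimage as ndi

        img = np.zeros((60, 80))
        img[25, 10:70] = 1.0
        img[35, 10:70] = 1.0
        img = ndi.gaussian_filter(img, 1.3)
        assert len(seg.ridge_centerlines(img, tubule_sigma_px=1.5)) == 2

    def test_non_positive_scale_rejected(self):
        with pytest.raises(ValueError):
            seg.ridge_centerlines(np.zeros((20, 20)), tubule_sigma_px=0)


class TestMeasureLength:
    def test_axial_path(self):
        path = np.array([(5, x) for x in range(11)])
        assert seg.measure_length(path, 0.09) == pytest.approx(0.90)

    def test_diagonal_path(self):
        path = np.array([(i, i) for i in range(11)])
        assert seg.measure_length(path, 0.09) == pytest.approx(10 * np.sqrt(2) * 0.09)

    def test_single_pixel_has_zero_length(self):
        assert seg.measure_length(np.array([[3, 4]]), 0.09) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            seg.measure_length(np.empty((0, 2)), 0.09)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_reversal_and_rotation_invariance(self, s):
        r = np.random.default_rng(s)
        steps = r.integers(-1, 2, size=(15, 2))
        path = np.cumsum(np.vstack([[[5, 5]], steps]), axis=0)
        length = seg.measure_length(path, 0.09)
        assert seg.measure_length(path[::-1], 0.09) == pytest.approx(length)
        rot = np.column_stack([path[:, 1], -path[:, 0]])  # 90 degree rotation
        assert seg.measure_length(rot, 0.09) == pytest.approx(length)

    def test_growing_component_never_shortens_longest_path(self):
        m = np.zeros((9, 60), dtype=bool)
        m[3:6, 5:40] = True
        base = seg.medial_axis_centerlines(m)[0]
        m2 = m.copy()
        m2[3:6, 5:55] = True
        longer = seg.medial_axis_centerlines(m2)[0]
        assert seg.measure_length(longer.path, 1.0) >= seg.measure_length(base.path, 1.0)


class TestCenterlineInvariants:
    def test_paths_are_single_pixel_wide(self):
        img, _ = synthetic_tube()
        for c in seg.ridge_centerlines(img):
            # within the stored path, no pixel may have more than 2 path
            # neighbours in the 8-neighbourhood
            pset = set(map(tuple, c.path))
            for (y, x) in pset:
                n = sum((y + dy, x + dx) in pset
                        for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                        if (dy, dx) != (0, 0))
                assert n <= 2

    def test_centerline_close_to_independent_skeleton(self):
        # independent route: every path pixel must lie inside the mask and
        # within 1 px of the (deterministic) scikit-image skeleton
        m = np.zeros((40, 40), dtype=bool)
        m[10:14, 5:35] = True
        cls = seg.medial_axis_centerlines(m)
        skel = np.argwhere(morphology.skeletonize(m))
        for y, x in cls[0].path:
            assert m[y, x]
            assert np.min(np.abs(skel - [y, x]).max(axis=1)) <= 1
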