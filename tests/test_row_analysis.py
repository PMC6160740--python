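"""Row-line creation (buffer/median/cluster/connect/smooth) and row statistics."""

import numpy as np
import pytest

from standcount import row_analysis as ra
from standcount.raster_io import LabelImage
from standcount.segmentation import SeedlingObjectSet


def _objects_from_blobs(blobs, shape=(80, 80), gsd=1.0):
    """Build an object set from (row0, col0, h, w) pixel rectangles."""
    lab = np.zeros(shape, np.int32)
    for k, (r0, c0, h, w) in enumerate(blobs, 1):
        lab[r0:r0 + h, c0:c0 + w] = k
    return SeedlingObjectSet(LabelImage(lab, gsd))


class TestBuildRowPoints:
    def test_equal_areas_none_eliminated(self):
        objs = _objects_from_blobs([(5, 5, 4, 4), (5, 40, 4, 4), (40, 5, 4, 4)])
        pts = ra.build_row_points(objs, buffer_cm=1.0)
        assert len(pts) == 3

    def test_below_median_area_eliminated(self):
        # areas ~1, 2, 9 units: the smallest falls below the median
        objs = _objects_from_blobs([(5, 5, 2, 2), (5, 40, 2, 4), (40, 20, 6, 6)])
        pts = ra.build_row_points(objs, buffer_cm=0.5)
        assert len(pts) == 2

    def test_overlapping_buffers_fuse_to_one_centroid(self):
        # two 4x4 blobs 3 px apart; 2 cm buffers overlap (gsd = 1 cm/px)
        objs = _objects_from_blobs([(10, 10, 4, 4), (10, 17, 4, 4),
                                    (50, 50, 4, 4), (50, 57, 4, 4)])
        pts = ra.build_row_points(objs, buffer_cm=2.0)
        assert len(pts) == 2

    def test_empty_set_rejected(self):
        objs = _objects_from_blobs([])
        with pytest.raises(ValueError):
            ra.build_row_points(objs)


class TestAssignRowLabels:
    def test_three_clean_groups(self, rng):
        xs = np.concatenate([10 + rng.uniform(-0.5, 0.5, 20),
                             30 + rng.uniform(-0.5, 0.5, 20),
                             50 + rng.uniform(-0.5, 0.5, 20)])
        pts = np.column_stack([xs, rng.uniform(0, 100, 60)])
        labels = ra.assign_row_labels(pts, 3, 20.0)
        truth = np.repeat([1, 2, 3], 20)
        assert np.array_equal(labels, truth)

    def test_single_row(self, rng):
        pts = np.column_stack([rng.normal(10, 1, 15), rng.uniform(0, 50, 15)])
        assert (ra.assign_row_labels(pts, 1, 20.0) == 1).all()

    def test_fewer_points_than_rows_rejected(self):
        pts = np.array([[1.0, 2.0], [3.0, 4.0]])
        with pytest.raises(ValueError, match="fewer points"):
            ra.assign_row_labels(pts, 5, 20.0)

    def test_jittered_rows_recovered(self, rng):
        """Points at 1 cm jitter around known rows: >= 95 % labeled right."""
        true_x = 10 + 20.0 * np.arange(5)
        labels_true = rng.integers(0, 5, 200)
        xs = true_x[labels_true] + rng.normal(0, 1.0, 200)
        pts = np.column_stack([xs, rng.uniform(0, 200, 200)])
        labels = ra.assign_row_labels(pts, 5, 20.0)
        assert np.mean(labels == labels_true + 1) >= 0.95


class TestConnectSmooth:
    def test_collinear_points_unchanged(self):
        pts = np.column_stack([np.full(11, 5.0), np.arange(11.0)])
        lines = ra.connect_and_smooth(pts, np.ones(11, int), window=5)
        np.testing.assert_allclose(lines.lines[1][:, 0], 5.0, atol=1e-12)

    def test_slanted_line_is_fixed_point(self):
        y = np.arange(11.0)
        pts = np.column_stack([2.0 + 0.3 * y, y])
        lines = ra.connect_and_smooth(pts, np.ones(11, int), window=5)
        np.testing.assert_allclose(lines.lines[1][:, 0], 2.0 + 0.3 * y, atol=1e-12)

    def test_outlier_attenuated_by_window(self):
        """+3 cm spike in a straight line shrinks to 3/5 = 0.6 with window 5."""
        x = np.full(11, 10.0)
        x[5] += 3.0
        pts = np.column_stack([x, np.arange(11.0)])
        lines = ra.connect_and_smooth(pts, np.ones(11, int), window=5)
        assert abs(lines.lines[1][5, 0] - 10.0) <= 0.6 + 1e-12

    def test_smoothing_reduces_curvature(self, rng):
        y = np.arange(0.0, 100.0, 4.0)
        x = 20.0 + rng.normal(0, 1.0, len(y))
        pts = np.column_stack([x, y])
        raw = ra.connect_and_smooth(pts, np.ones(len(y), int), window=1)
        smooth = ra.connect_and_smooth(pts, np.ones(len(y), int), window=5)

        def curvature(v):
            d = np.diff(v, axis=0)
            ang = np.arctan2(d[:, 0], d[:, 1])
            return np.abs(np.diff(ang)).sum()

        assert curvature(smooth.lines[1]) < curvature(raw.lines[1])

    def test_single_point_label_flagged_degenerate(self):
        pts = np.array([[5.0, 1.0], [5.0, 2.0], [25.0, 1.5]])
        lines = ra.connect_and_smooth(pts, np.array([1, 1, 2]))
        assert lines.degenerate == [2]


class TestSpacingStats:
    def _parallel_lines(self, xs, y_max=100.0):
        lines = {i + 1: np.column_stack([np.full(5, x), np.linspace(0, y_max, 5)])
                 for i, x in enumerate(xs)}
        return ra.RowLineSet(lines)

    def test_perfect_parallel_lines(self):
        st = ra.row_spacing_stats(self._parallel_lines([0.0, 20.0, 40.0]), 20.0)
        assert st.cv_rs == pytest.approx(0.0, abs=1e-12)
        assert st.e_rs == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic_18_22(self):
        st = ra.row_spacing_stats(self._parallel_lines([0.0, 18.0, 40.0]), 20.0)
        assert st.spacings == pytest.approx([18.0, 22.0])
        assert st.mean_spacing == pytest.approx(20.0)
        assert st.sd_spacing == pytest.approx(2.0)
        assert st.cv_rs == pytest.approx(10.0)
        assert st.e_rs == pytest.approx(0.0)

    def test_hand_arithmetic_21_21(self):
        st = ra.row_spacing_stats(self._parallel_lines([0.0, 21.0, 42.0]), 20.0)
        assert st.e_rs == pytest.approx(5.0)

    def test_matches_closed_form_on_random_spacings(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 9))
            xs = np.cumsum(rng.uniform(15, 25, n))
            st = ra.row_spacing_stats(self._parallel_lines(xs), 20.0)
            sp = np.diff(xs)
            assert st.mean_spacing == pytest.approx(sp.mean(), abs=1e-9)
            assert st.sd_spacing == pytest.approx(sp.std(ddof=0), abs=1e-9)
            assert st.cv_rs == pytest.approx(100 * sp.std(ddof=0) / sp.mean(), abs=1e-9)
            assert st.e_rs == pytest.approx(100 * (sp.mean() - 20.0) / 20.0, abs=1e-9)

    def test_no_overlap_rejected(self):
        lines = ra.RowLineSet({
            1: np.column_stack([np.zeros(3), [0.0, 5.0, 10.0]]),
            2: np.column_stack([np.full(3, 20.0), [50.0, 55.0, 60.0]]),
        })
        with pytest.raises(ValueError, match="overlap"):
            ra.row_spacing_stats(lines, 20.0)

    def test_degenerate_rows_excluded(self):
        lines = self._parallel_lines([0.0, 20.0, 40.0])
        lines.lines[4] = np.array([[60.0, 50.0]])
        lines.degenerate.append(4)
        st = ra.row_spacing_stats(lines, 20.0)
        assert len(st.spacings) == 2


class TestSeedlingUniformity:
    def _lines(self, xs):
        return ra.RowLineSet({i + 1: np.column_stack(
            [np.full(3, x), [0.0, 50.0, 100.0]]) for i, x in enumerate(xs)})

    def test_uniform_counts_zero_cv(self):
        lines = self._lines([0.0, 20.0, 40.0, 60.0])
        cents = np.array([[x, 50.0] for x in (0, 20, 40, 60)])
        su = ra.seedling_uniformity(cents, np.full(4, 10.0), lines)
        assert su.row_counts == [10.0, 10.0, 10.0, 10.0]
        assert su.cv_su == pytest.approx(0.0)

    def test_hand_arithmetic_4_6(self):
        """u = {4, 6}: mean 5, SD 1 (divisor N), CV 20 %."""
        lines = self._lines([0.0, 20.0])
        cents = np.array([[0.0, 50.0], [20.0, 50.0]])
        su = ra.seedling_uniformity(cents, np.array([4.0, 6.0]), lines)
        assert su.mean_count == pytest.approx(5.0)
        assert su.sd_count == pytest.approx(1.0)
        assert su.cv_su == pytest.approx(20.0)

    def test_far_object_contributes_nowhere(self):
        lines = self._lines([0.0, 20.0])
        cents = np.array([[10.0, 50.0], [0.5, 50.0]])  # first is 9+ cm from both
        su = ra.seedling_uniformity(cents, np.array([5.0, 3.0]), lines,
                                    max_dist_cm=8.0)
        assert sum(su.row_counts) == pytest.approx(3.0)

    def test_nearest_line_wins_ties_to_lower_index(self):
        lines = self._lines([0.0, 10.0])
        cents = np.array([[5.0, 50.0]])  # equidistant
        su = ra.seedling_uniformity(cents, np.array([2.0]), lines)
        assert su.row_counts == [2.0, 0.0]

    def test_matches_closed_form_on_random_counts(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 8))
            lines = self._lines(20.0 * np.arange(n))
            counts = rng.uniform(1, 30, n)
            cents = np.column_stack([20.0 * np.arange(n), np.full(n, 50.0)])
            su = ra.seedling_uniformity(cents, counts, lines)
            assert su.mean_count == pytest.approx(counts.mean(), abs=1e-9)
            assert su.sd_count == pytest.approx(counts.std(ddof=0), abs=1e-9)
            assert su.cv_su == pytest.approx(
                100 * counts.std(ddof=0) / counts.mean(), abs=1e-9)
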