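"""Segmentation chain: filters, seeds, contour tracking, graph search,
borders and mask extraction, on both constructed images and phantoms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivdt2.phantom import PhantomSpec, render_echo_stack
from ivdt2.segmentation import (
    DiscBorderError,
    MaskOverlapError,
    SegmentationParams,
    SpineNotFoundError,
    detect_endplate_seeds,
    dijkstra_boundary,
    extract_disc_masks,
    find_ap_borders,
    locate_spine_centre,
    pair_disc_contours,
    propagate_support_points,
    segment_slice,
    segment_stack,
    track_endplate_contours,
    vertical_median_filter,
)

PARAMS = SegmentationParams()


# ---------------------------------------------------------------- median


class TestVerticalMedianFilter:
    def test_constant_image_unchanged(self):
        img = np.full((40, 10), 7.0)
        np.testing.assert_array_equal(vertical_median_filter(img), img)

    def test_single_bright_row_suppressed(self):
        img = np.zeros((40, 6))
        img[20, :] = 300.0
        out = vertical_median_filter(img)
        assert np.all(out[20] == 0.0)

    def test_eight_row_run(self):
        """An 8-row run of 100s: every run row sees >=8 bright values in its
        15-row window (median 100); the rows just outside fall back to 0."""
        col = np.zeros(60)
        col[20:28] = 100.0
        img = np.tile(col[:, None], (1, 3))
        out = vertical_median_filter(img)[:, 1]
        assert np.all(out[20:28] == 100.0)
        assert out[19] == 0.0 and out[28] == 0.0

    def test_rejects_short_image(self):
        with pytest.raises(ValueError, match="rows"):
            vertical_median_filter(np.zeros((10, 10)))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_sliding_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 300, size=(25, 4)).astype(float)
        out = vertical_median_filter(img, height=5)
        padded = np.pad(img, ((2, 2), (0, 0)), mode="symmetric")
        for r in range(25):
            for c in range(4):
                assert out[r, c] == np.median(padded[r : r + 5, c])


# ---------------------------------------------------------------- locate


class TestLocateSpineCentre:
    def _images(self, counts):
        img = np.zeros((50, len(counts)))
        for c, n in enumerate(counts):
            img[:n, c] = 200.0
        return img, np.zeros_like(img)

    def test_max_count_column(self):
        img, med = self._images([5, 30, 4, 2])
        assert locate_spine_centre(img, med, PARAMS) == 1

    def test_tie_breaks_to_smallest_column(self):
        img, med = self._images([0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0,
                                 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0,
                                 7, 7])
        assert locate_spine_centre(img, med, PARAMS) == 40

    def test_no_structure_raises(self):
        img = np.zeros((20, 20))
        with pytest.raises(SpineNotFoundError):
            locate_spine_centre(img, img, PARAMS)

    def test_signed_difference(self):
        """A column darker than its median must not qualify."""
        img = np.zeros((30, 2))
        med = np.zeros_like(img)
        med[:, 0] = 500.0  # image - median = -500: no qualifying pixels
        img[:3, 1] = 150.0
        assert locate_spine_centre(img, med, PARAMS) == 1

    def test_threshold_monotonicity(self, rng):
        img = rng.uniform(0, 300, (60, 30))
        med = vertical_median_filter(img)
        counts_lo = ((img - med) >= 80).sum(axis=0)
        counts_hi = ((img - med) >= 120).sum(axis=0)
        assert np.all(counts_hi <= counts_lo)

    def test_phantom_centre_inside_disc_span(self, noiseless_session):
        stack, truth = noiseless_session
        second = stack.data[2, 1]
        c = locate_spine_centre(second, vertical_median_filter(second), PARAMS)
        disc_cols = np.nonzero((truth.disc_masks[2] > 0).any(axis=0))[0]
        assert disc_cols[0] <= c <= disc_cols[-1]


# ---------------------------------------------------------------- seeds


class TestEndplateSeeds:
    def _col_image(self, profile):
        return np.tile(np.asarray(profile, float)[:, None], (1, 3))

    def test_two_minima(self):
        img = self._col_image([200, 120, 200, 140, 200])
        assert detect_endplate_seeds(img, 1, PARAMS) == [1, 3]

    def test_all_above_threshold_empty(self):
        img = self._col_image([200, 160, 200, 155, 200])
        assert detect_endplate_seeds(img, 0, PARAMS) == []

    def test_plateau_reports_lower_middle(self):
        img = self._col_image([200, 120, 120, 200])
        assert detect_endplate_seeds(img, 0, PARAMS) == [1]
        img = self._col_image([200, 120, 120, 120, 200])
        assert detect_endplate_seeds(img, 0, PARAMS) == [2]

    def test_border_plateaus_excluded(self):
        img = self._col_image([0, 0, 200, 120, 200, 0, 0])
        assert detect_endplate_seeds(img, 0, PARAMS) == [3]

    def test_phantom_two_seeds_per_disc(self, noiseless_session):
        stack, truth = noiseless_session
        second = stack.data[2, 1]
        c = locate_spine_centre(second, vertical_median_filter(second), PARAMS)
        seeds = detect_endplate_seeds(second, c, PARAMS)
        assert len(seeds) == 2 * 6  # superior + inferior endplate per disc


# ---------------------------------------------------------------- tracking


class TestContourTracking:
    def test_dark_band_tracked_full_width(self):
        img = np.full((30, 50), 400.0)
        img[14:17, :] = 100.0
        contours = track_endplate_contours(img, [15], PARAMS, centre_column=25)
        assert len(contours) == 1
        cols = contours[0][:, 1]
        assert cols.min() == 0 and cols.max() == 49
        assert np.all(np.abs(contours[0][:, 0] - 15) <= 1)

    def test_isolated_dark_pixel_discarded(self):
        img = np.full((30, 30), 400.0)
        img[15, 15] = 50.0
        with pytest.warns(UserWarning, match="discarding"):
            contours = track_endplate_contours(img, [15], PARAMS, centre_column=15)
        assert contours == []

    def test_phantom_one_contour_per_interface(self, noiseless_session):
        stack, _ = noiseless_session
        second = stack.data[2, 1]
        c = locate_spine_centre(second, vertical_median_filter(second), PARAMS)
        seeds = detect_endplate_seeds(second, c, PARAMS)
        contours = track_endplate_contours(second, seeds, PARAMS, centre_column=c)
        assert len(contours) == 12  # two vertebra-disc interfaces per disc


# ---------------------------------------------------------------- dijkstra


def _bellman_ford_cost(node_cost, src, dst):
    """Independent shortest-path oracle: repeated relaxation over all
    8-neighbour edges, edge weight = target node cost."""
    h, w = node_cost.shape
    dist = np.full((h, w), np.inf)
    dist[src] = 0.0
    for _ in range(h * w):
        prev = dist.copy()
        for r in range(h):
            for c in range(w):
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == dc == 0:
                            continue
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w:
                            nd = dist[r, c] + node_cost[rr, cc]
                            if nd < dist[rr, cc]:
                                dist[rr, cc] = nd
        if np.array_equal(prev, dist):
            break
    return dist[dst]


class TestDijkstraBoundary:
    def test_uniform_image_minimal_path_length(self):
        img = np.full((20, 20), 5.0)
        path, _ = dijkstra_boundary(img, [(3, 2), (10, 14)], PARAMS)
        cheb = max(abs(10 - 3), abs(14 - 2))
        assert path.shape[0] == cheb + 1

    def test_zero_cost_corridor_followed(self):
        # grey=0 corridor in a bright image, flat gradients inside
        img = np.full((15, 30), 1000.0)
        img[7, :] = 0.0
        params = SegmentationParams(cost_weight_gradient=0.0, cost_weight_grey=1.0,
                                    dijkstra_window_pad=None)
        path, cost = dijkstra_boundary(img, [(7, 2), (7, 27)], params)
        assert np.all(path[:, 0] == 7)
        assert cost == 0.0

    def test_matches_bruteforce_oracle_exactly(self, rng):
        """Path cost equals an independent Bellman-Ford oracle on the same
        <=400-node cost field."""
        from ivdt2.segmentation import _node_costs

        for _ in range(5):
            img = rng.uniform(0, 300, (15, 15))
            p, q = (2, 1), (12, 13)
            params = SegmentationParams(dijkstra_window_pad=None)
            cost_field = _node_costs(img, np.array(p), np.array(q), params)
            path, cost = dijkstra_boundary(img, [p, q], params)
            oracle = _bellman_ford_cost(cost_field, p, q)
            assert cost == pytest.approx(oracle, abs=1e-12)
            # returned path really has that cost
            walked = sum(cost_field[r, c] for r, c in path[1:])
            assert walked == pytest.approx(cost, abs=1e-9)

    def test_support_points_outside_image_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            dijkstra_boundary(np.zeros((10, 10)), [(2, 2), (20, 5)], PARAMS)


# ---------------------------------------------------------------- propagation


class TestPropagation:
    def test_identical_slice_keeps_points(self, rng):
        img = rng.uniform(0, 300, (40, 40))
        pts = np.array([[10, 10], [25, 30]])
        out = propagate_support_points(img, img, pts)
        np.testing.assert_array_equal(out, pts)

    def test_shifted_slice_shifts_points(self):
        rng = np.random.default_rng(0)
        img = np.cumsum(rng.uniform(0, 10, (50, 50)), axis=0)
        shifted = np.roll(img, 2, axis=0)
        pts = np.array([[20, 20], [30, 35]])
        out = propagate_support_points(img, shifted, pts)
        np.testing.assert_array_equal(out, pts + np.array([2, 0]))

    def test_flat_adjacent_slice_warns_and_keeps(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 300, (30, 30))
        flat = np.full((30, 30), 100.0)
        with pytest.warns(UserWarning, match="no gradients"):
            out = propagate_support_points(img, flat, np.array([[15, 15]]))
        np.testing.assert_array_equal(out, [[15, 15]])


# ---------------------------------------------------------------- borders


class TestApBorders:
    def test_direct_scan(self):
        avg = np.zeros((10, 120))
        med = np.zeros_like(avg)
        avg[:, 40] = 90.0
        avg[:, 90] = 85.0
        out = find_ap_borders(avg, med, 60, [(2, 7)], PARAMS)
        assert np.all(out[0].anterior == 40)
        assert np.all(out[0].posterior == 90)

    def test_degenerate_centre_hit_flagged(self):
        avg = np.zeros((6, 50))
        med = np.zeros_like(avg)
        avg[:, 25] = 100.0
        with pytest.warns(UserWarning, match="degenerate"):
            out = find_ap_borders(avg, med, 25, [(0, 5)], PARAMS)
        assert np.all(out[0].anterior == 25)
        assert np.all(out[0].posterior == 25)
        assert out[0].degenerate.all()

    def test_unresolved_rows_inherit_nearest(self):
        avg = np.zeros((6, 60))
        med = np.zeros_like(avg)
        avg[0:2, 10] = 100.0
        avg[0:2, 50] = 100.0
        out = find_ap_borders(avg, med, 30, [(0, 5)], PARAMS)
        assert np.all(out[0].anterior == 10)
        assert np.all(out[0].posterior == 50)

    def test_fully_unresolved_span_raises(self):
        avg = np.zeros((8, 40))
        with pytest.raises(DiscBorderError):
            find_ap_borders(avg, avg, 20, [(0, 7)], PARAMS)

    def test_phantom_borders_near_true_extent(self, noiseless_session):
        stack, truth = noiseless_session
        seg = segment_slice(stack.data[2], PARAMS, slice_index=2)
        true_cols = np.nonzero((truth.disc_masks[2] > 0).any(axis=0))[0]
        for ant, post in seg.borders:
            assert abs(ant - true_cols[0]) <= 2
            assert abs(post - true_cols[-1]) <= 2


# ---------------------------------------------------------------- masks


class TestExtractDiscMasks:
    def _rect_pair(self, y_top, y_bot, x0, x1):
        cols = np.arange(x0, x1 + 1)
        upper = np.column_stack([np.full(cols.size, y_top), cols])
        lower = np.column_stack([np.full(cols.size, y_bot), cols])
        return upper, lower

    def test_rectangular_fill_count(self):
        pair = self._rect_pair(30, 50, 10, 50)
        masks = extract_disc_masks([pair], [(10, 50)], (80, 80))
        # 41 columns x 21 rows minus the two boundary rows
        assert masks[0].sum() == 41 * (21 - 2)

    def test_overlap_is_an_error(self):
        p1 = self._rect_pair(30, 50, 10, 50)
        p2 = self._rect_pair(40, 60, 10, 50)
        with pytest.raises(MaskOverlapError):
            extract_disc_masks([p1, p2], [(10, 50), (10, 50)], (80, 80))

    def test_empty_pair_warns_and_skips(self):
        pair = self._rect_pair(30, 31, 10, 50)  # nothing strictly between
        with pytest.warns(UserWarning, match="empty"):
            masks = extract_disc_masks([pair], [(10, 50)], (80, 80))
        assert masks == []


# ---------------------------------------------------------------- full chain


class TestFullSegmentation:
    def test_noiseless_phantom_perfect_dice(self, noiseless_session):
        stack, truth = noiseless_session
        seg = segment_stack(stack)
        assert seg.levels == list(truth.disc_labels)
        for s in range(stack.n_slices):
            for d in range(6):
                tm = truth.disc_masks[s] == d + 1
                m = seg.slices[s].masks[d]
                dice = 2 * (tm & m).sum() / (tm.sum() + m.sum())
                assert dice >= 0.95

    def test_masks_disjoint_and_ordered(self, noiseless_session):
        stack, _ = noiseless_session
        seg = segment_stack(stack)
        for sl in seg.slices:
            total = np.zeros(stack.shape, dtype=int)
            centroids = []
            for m in sl.masks:
                total += m
                centroids.append(np.nonzero(m)[0].mean())
            assert total.max() == 1
            assert centroids == sorted(centroids)

    def test_determinism(self, noisy_session):
        stack, _ = noisy_session
        a = segment_stack(stack)
        b = segment_stack(stack)
        for sa, sb in zip(a.slices, b.slices):
            for ma, mb in zip(sa.masks, sb.masks):
                np.testing.assert_array_equal(ma, mb)

    def test_noisy_phantom_dice(self, noisy_session):
        stack, truth = noisy_session
        seg = segment_stack(stack)
        dices = []
        for s in range(stack.n_slices):
            for d in range(6):
                tm = truth.disc_masks[s] == d + 1
                m = seg.slices[s].masks[d]
                dices.append(2 * (tm & m).sum() / (tm.sum() + m.sum()))
        assert np.median(dices) >= 0.90
        assert min(dices) >= 0.7
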