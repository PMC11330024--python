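"""Thresholding, spot labeling, fusion/correlation metrics, radial decay."""

from collections import deque

import numpy as np
import pytest

from harlequin import (
    label_spots,
    pattern_summary,
    radial_decay_check,
    relative_threshold,
    threshold_mask,
)


def flood_fill_labels(mask, connectivity=4, periodic=False):
    """Brute-force BFS labeling, independent of the library implementation."""
    n_rows, n_cols = mask.shape
    labels = np.zeros_like(mask, dtype=int)
    if connectivity == 4:
        moves = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        moves = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    current = 0
    for r0 in range(n_rows):
        for c0 in range(n_cols):
            if mask[r0, c0] and not labels[r0, c0]:
                current += 1
                queue = deque([(r0, c0)])
                labels[r0, c0] = current
                while queue:
                    r, c = queue.popleft()
                    for dr, dc in moves:
                        rr, cc = r + dr, c + dc
                        if periodic:
                            rr %= n_rows
                            cc %= n_cols
                        elif not (0 <= rr < n_rows and 0 <= cc < n_cols):
                            continue
                        if mask[rr, cc] and not labels[rr, cc]:
                            labels[rr, cc] = current
                            queue.append((rr, cc))
    return labels


def same_partition(a, b):
    """Two label maps describe the same components (up to renaming)."""
    if not np.array_equal(a > 0, b > 0):
        return False
    pairs = {(x, y) for x, y in zip(a.ravel(), b.ravel()) if x or y}
    return (len({x for x, _ in pairs}) == len(pairs)
            and len({y for _, y in pairs}) == len(pairs))


class TestThreshold:
    def test_all_below_threshold(self):
        assert threshold_mask(np.zeros((5, 5)), 2.0).sum() == 0

    def test_all_above_threshold(self):
        assert threshold_mask(np.full((5, 5), 3.0), 2.0).sum() == 25

    def test_boundary_is_strict(self):
        field = np.zeros((3, 3))
        field[1, 1] = 2.0
        assert threshold_mask(field, 2.0)[1, 1] == 0

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            threshold_mask(np.zeros((2, 2)), -1.0)


class TestRelativeThreshold:
    def test_proportion_of_max(self):
        A = np.array([[10.0, 0.0], [0.0, 0.0]])
        assert relative_threshold(A, GA_whi=2.8, GA_pur=7.0, basic=2.0) == \
            pytest.approx(4.0)

    def test_clamped_at_basic(self):
        A = np.array([[10.0]])
        assert relative_threshold(A, GA_whi=0.7, GA_pur=7.0, basic=2.0) == 2.0

    def test_degenerate_ratio_rejected(self):
        with pytest.raises(ValueError):
            relative_threshold(np.ones((2, 2)), GA_whi=7.0, GA_pur=7.0)

    def test_empty_field_rejected(self):
        with pytest.raises(ValueError):
            relative_threshold(np.empty((0,)), GA_whi=1.0, GA_pur=2.0)


class TestLabelSpots:
    def test_two_separate_squares(self):
        mask = np.zeros((8, 8), dtype=int)
        mask[1:3, 1:3] = 1
        mask[5:7, 5:7] = 1
        spots = label_spots(mask, periodic=False)
        assert spots.n_spots == 2
        assert sorted(spots.areas) == [4, 4]

    def test_full_width_stripe_wraps_to_one(self):
        mask = np.zeros((8, 8), dtype=int)
        mask[3, :] = 1
        assert label_spots(mask, periodic=True).n_spots == 1

    def test_corner_patch_wraps_across_both_edges(self):
        mask = np.zeros((6, 6), dtype=int)
        mask[0, 0] = mask[0, -1] = mask[-1, 0] = mask[-1, -1] = 1
        assert label_spots(mask, connectivity=4, periodic=True).n_spots == 1
        assert label_spots(mask, connectivity=4, periodic=False).n_spots == 4

    def test_diagonal_pair_depends_on_connectivity(self):
        mask = np.zeros((5, 5), dtype=int)
        mask[2, 2] = mask[3, 3] = 1
        assert label_spots(mask, connectivity=4, periodic=False).n_spots == 2
        assert label_spots(mask, connectivity=8, periodic=False).n_spots == 1

    @pytest.mark.parametrize("connectivity", [4, 8])
    @pytest.mark.parametrize("periodic", [False, True])
    def test_agrees_with_flood_fill_oracle(self, connectivity, periodic):
        rng = np.random.default_rng(77)
        for _ in range(100):
            mask = (rng.random((20, 20)) < 0.4).astype(int)
            spots = label_spots(mask, connectivity=connectivity,
                                periodic=periodic)
            oracle = flood_fill_labels(mask, connectivity, periodic)
            assert spots.n_spots == oracle.max()
            assert same_partition(spots.label_map, oracle)

    def test_areas_sum_to_mask_total(self):
        rng = np.random.default_rng(5)
        mask = (rng.random((30, 30)) < 0.3).astype(int)
        spots = label_spots(mask)
        assert spots.areas.sum() == mask.sum()
        assert sorted(np.unique(spots.label_map)[1:]) == \
            list(range(1, spots.n_spots + 1))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            label_spots(np.full((3, 3), 2))


class TestPatternSummary:
    def test_perfect_linear_relation(self):
        rng = np.random.default_rng(0)
        A = rng.random((10, 10))
        summary = pattern_summary(A, 2 * A, threshold=0.5)
        assert summary.ah_correlation == pytest.approx(1.0)

    def test_anti_phase_relation(self):
        rng = np.random.default_rng(0)
        A = rng.random((10, 10))
        summary = pattern_summary(A, 1.0 - A, threshold=0.5)
        assert summary.ah_correlation == pytest.approx(-1.0)

    def test_empty_mask_has_no_fusion_index(self):
        A = np.zeros((6, 6))
        H = np.random.default_rng(1).random((6, 6))
        summary = pattern_summary(A, H, threshold=2.0)
        assert summary.n_spots == 0
        assert summary.area_fraction == 0.0
        assert summary.fusion_index is None

    def test_fusion_index_is_largest_over_total(self):
        A = np.zeros((10, 10))
        A[0:2, 0:3] = 5.0   # area 6
        A[6:8, 6:8] = 5.0   # area 4
        H = A.copy()
        H[0, 0] += 0.1      # break degeneracy for correlation
        summary = pattern_summary(A, H, threshold=2.0, periodic=False)
        assert summary.n_spots == 2
        assert summary.fusion_index == pytest.approx(6 / 10)
        assert summary.max_area == 6
        assert summary.area_fraction == pytest.approx(0.1)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pattern_summary(np.zeros((4, 4)), np.zeros((5, 5)), 1.0)


class TestRadialDecay:
    def test_gaussian_bump_fully_monotone(self):
        n = 21
        y, x = np.mgrid[0:n, 0:n]
        A = 5.0 * np.exp(-((x - 10) ** 2 + (y - 10) ** 2) / 20.0)
        mask = threshold_mask(A, 0.5)
        spots = label_spots(mask, periodic=False, A=A)
        median, scores = radial_decay_check(A, spots, periodic=False)
        assert median == 1.0 and scores == [1.0]

    def test_flat_disk_ties_count_as_non_increasing(self):
        n = 15
        y, x = np.mgrid[0:n, 0:n]
        A = np.where((x - 7) ** 2 + (y - 7) ** 2 <= 25, 3.0, 0.0)
        spots = label_spots(threshold_mask(A, 1.0), periodic=False, A=A)
        median, _ = radial_decay_check(A, spots, periodic=False)
        assert median == 1.0

    def test_ring_increases_fail_the_check(self):
        # a crater: peak cell chosen at the rim-adjacent maximum still sees
        # an increasing ring somewhere
        n = 21
        y, x = np.mgrid[0:n, 0:n]
        r2 = (x - 10) ** 2 + (y - 10) ** 2
        A = np.where(r2 <= 49, 1.0 + 0.3 * np.sqrt(r2), 0.0)
        spots = label_spots(threshold_mask(A, 0.5), periodic=False, A=A)
        median, _ = radial_decay_check(A, spots, periodic=False)
        assert median < 1.0

    def test_requires_peaks(self):
        mask = np.ones((4, 4), dtype=int)
        spots = label_spots(mask)
        with pytest.raises(ValueError, match="peaks"):
            radial_decay_check(np.ones((4, 4)), spots)


class TestLabelingProperties:
    """Hypothesis-driven invariants of the spot labeling."""

    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra import numpy as hnp

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        mask=hnp.arrays(np.int64, (12, 12), elements=st.integers(0, 1)),
        connectivity=st.sampled_from([4, 8]),
        periodic=st.booleans(),
    )
    def test_partition_invariants_and_oracle_agreement(
            self, mask, connectivity, periodic):
        spots = label_spots(mask, connectivity=connectivity, periodic=periodic)
        assert spots.areas.sum() == mask.sum()
        present = np.unique(spots.label_map)
        assert sorted(present[present > 0]) == list(range(1, spots.n_spots + 1))
        oracle = flood_fill_labels(mask, connectivity, periodic)
        assert spots.n_spots == oracle.max()
        assert same_partition(spots.label_map, oracle)
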