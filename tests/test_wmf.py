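"""Unit and property tests for the guided weighted median filter."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icif import (
    NecklaceTable,
    affinity_weight,
    balance_at_cut,
    build_joint_histogram,
    column_weight_sum,
    guided_wmf,
    median_filter_truncated,
    weighted_median,
)
from icif.wmf import guidance_bin_centers, quantize_guidance, quantize_intensity

from conftest import random_intensity


class TestAffinityWeight:
    def test_equal_guidance_gives_unit_weight(self):
        assert affinity_weight(0.5, 0.5, 0.3) == 1.0

    def test_unit_gap_unit_bandwidth(self):
        assert affinity_weight(0.0, 1.0, 1.0) == pytest.approx(math.exp(-1))

    def test_monotone_decrease_in_gap(self):
        assert affinity_weight(0.1, 0.3, 0.2) > affinity_weight(0.1, 0.7, 0.2)

    @pytest.mark.parametrize("bad", [(0.1, 0.2, 0.0), (0.1, 0.2, -1.0),
                                     (math.nan, 0.2, 1.0), (0.1, math.inf, 1.0)])
    def test_invalid_parameters_raise(self, bad):
        with pytest.raises(ValueError):
            affinity_weight(*bad)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(fp=st.floats(0, 1), fq=st.floats(0, 1),
           bw=st.floats(0.01, 10))
    def test_symmetric_and_in_unit_interval(self, fp, fq, bw):
        w = affinity_weight(fp, fq, bw)
        assert w == affinity_weight(fq, fp, bw)
        assert 0.0 < w <= 1.0
        if fp == fq:
            assert w == 1.0


class TestWeightedMedian:
    @pytest.mark.parametrize("values,weights,expected", [
        ([1, 2, 3], [1, 1, 1], 2),       # uniform-weight median
        ([1, 2, 9], [3, 1, 1], 1),       # heavy low value wins at half mass
        ([5], [7.0], 5),                 # singleton
        ([9, 2, 1], [1, 1, 3], 1),       # order of input must not matter
    ])
    def test_hand_examples(self, values, weights, expected):
        assert weighted_median(values, weights) == expected

    def test_empty_or_invalid_input(self):
        with pytest.raises(ValueError):
            weighted_median([], [])
        with pytest.raises(ValueError):
            weighted_median([1, 2], [1])
        with pytest.raises(ValueError):
            weighted_median([1, 2], [1, 0])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 255),
                              st.floats(0.01, 10)), min_size=1, max_size=40))
    def test_matches_cumulative_half_rule(self, pairs):
        values = [v for v, _ in pairs]
        weights = [w for _, w in pairs]
        got = weighted_median(values, weights)
        assert got in values
        total = sum(w for _, w in pairs)
        # smallest value whose mass at-or-below reaches half the total
        for v in sorted(set(values)):
            mass = sum(w for u, w in pairs if u <= v)
            if mass >= 0.5 * total:
                assert got == v
                break


class TestJointHistogram:
    def test_single_pixel(self):
        h = build_joint_histogram([100.0], [0.5], 256, 32)
        assert h.n == 1
        assert h.counts[100, quantize_guidance(np.array([0.5]), 32)[0]] == 1
        assert h.counts.sum() == 1

    def test_identical_pixels_share_one_cell(self):
        h = build_joint_histogram([7.0] * 4, [0.25] * 4, 16, 8)
        assert h.counts.max() == 4
        assert np.count_nonzero(h.counts) == 1

    def test_count_conservation(self):
        rng = np.random.default_rng(3)
        iv = rng.uniform(0, 255, 200)
        fv = rng.uniform(0, 1, 200)
        h = build_joint_histogram(iv, fv, 64, 8)
        assert h.counts.sum() == h.n == 200
        assert (h.counts >= 0).all()

    def test_out_of_range_clamps_to_edge_bins(self):
        h = build_joint_histogram([-5.0, 300.0], [-0.2, 1.4], 256, 32)
        assert h.counts[0, 0] == 1
        assert h.counts[255, 31] == 1


class TestColumnWeightSum:
    def test_hand_weighted_sum(self):
        # two pixels in guidance bin 0 (weight 1), one in bin 1 (weight 1/2)
        bw = 0.5 / math.log(2.0)
        h = build_joint_histogram([1, 1, 1], [0.25, 0.25, 0.75], 4, 2)
        w = column_weight_sum(h, i=quantize_intensity(np.array([1.0]), 4)[0],
                              center_guidance=0.25, bandwidth=bw)
        assert w == pytest.approx(2.5, abs=1e-12)

    def test_empty_column_is_zero(self):
        h = build_joint_histogram([10.0], [0.5], 256, 8)
        assert column_weight_sum(h, 200, 0.5, 0.1) == 0.0

    def test_unit_weights_give_plain_count(self):
        # nf=1: single bin centred at 0.5, so all affinities equal 1
        h = build_joint_histogram([42.0] * 5, [0.1, 0.3, 0.5, 0.7, 0.9], 256, 1)
        assert column_weight_sum(h, 42, 0.5, 0.1) == 5.0


class TestBalanceAtCut:
    def test_all_mass_left_at_max_cut(self):
        rng = np.random.default_rng(5)
        iv = rng.uniform(0, 255, 50)
        fv = rng.uniform(0, 1, 50)
        h = build_joint_histogram(iv, fv, 32, 4)
        state = balance_at_cut(h, 31, 0.5, 0.2)
        total = sum(column_weight_sum(h, i, 0.5, 0.2) for i in range(32))
        assert state.balance == pytest.approx(total)

    def test_uniform_window_hand_count(self):
        # intensities {1,2,3}, uniform weights; cut at 2 -> left 2, right 1
        h = build_joint_histogram([1.0, 2.0, 3.0], [0.5] * 3, 256, 1)
        assert balance_at_cut(h, 2, 0.5, 0.1).balance == pytest.approx(1.0)

    def test_incremental_slide_matches_scratch(self):
        """BCB maintained across a window slide equals fresh recomputation."""
        rng = np.random.default_rng(7)
        ni, nf, bw, fp = 32, 8, 0.15, 0.4
        img = random_intensity(rng, (9, 12))
        gd = rng.random((9, 12))
        centers = guidance_bin_centers(nf)
        ib = quantize_intensity(img, ni)
        fb = quantize_guidance(gd, nf)
        cut = 13
        # window columns [0, 5) of all rows, then slide right one column
        B = np.zeros(nf, dtype=int)
        for x in range(5):
            for y in range(9):
                B[fb[y, x]] += 1 if ib[y, x] <= cut else -1
        for y in range(9):  # add column 5, drop column 0
            B[fb[y, 5]] += 1 if ib[y, 5] <= cut else -1
            B[fb[y, 0]] -= 1 if ib[y, 0] <= cut else -1
        b_incremental = math.fsum(
            float(B[f]) * affinity_weight(float(centers[f]), fp, bw)
            for f in range(nf))
        h2 = build_joint_histogram(img[:, 1:6].ravel(), gd[:, 1:6].ravel(), ni, nf)
        assert b_incremental == pytest.approx(
            balance_at_cut(h2, cut, fp, bw).balance, abs=1e-9)


class TestNecklaceTable:
    def test_ring_tracks_nonempty_bins(self):
        neck = NecklaceTable(8)
        assert len(neck) == 0 and list(neck) == []
        for f in (3, 1, 6):
            neck.insert(f)
        assert sorted(neck) == [1, 3, 6]
        neck.delete(3)
        assert sorted(neck) == [1, 6]
        with pytest.raises(ValueError):
            neck.delete(3)
        with pytest.raises(ValueError):
            neck.insert(1)

    def test_traversal_skips_empty_entries(self):
        neck = NecklaceTable(1000)
        neck.insert(999)
        neck.insert(0)
        assert sorted(neck) == [0, 999]
        assert len(neck) == 2


class TestGuidedWmf:
    def test_constant_image_is_fixed_point(self):
        img = np.full((10, 10), 77.0)
        gd = np.random.default_rng(0).random((10, 10))
        for mode in ("naive", "accelerated"):
            assert np.array_equal(guided_wmf(img, gd, radius=2, mode=mode), img)

    def test_constant_guidance_center_is_plain_median(self):
        img = np.arange(1.0, 10.0).reshape(3, 3)
        out = guided_wmf(img, np.full((3, 3), 0.5), radius=1)
        assert out[1, 1] == 5.0

    def test_selection_property(self):
        rng = np.random.default_rng(21)
        img = random_intensity(rng, (12, 12))
        gd = rng.random((12, 12))
        out = guided_wmf(img, gd, radius=2, nf=8)
        r = 2
        for y in range(12):
            for x in range(12):
                win = img[max(0, y - r):y + r + 1, max(0, x - r):x + r + 1]
                assert out[y, x] in win

    def test_single_guidance_bin_equals_constant_guidance(self):
        rng = np.random.default_rng(22)
        img = random_intensity(rng, (10, 10))
        gd = rng.random((10, 10))
        one_bin = guided_wmf(img, gd, radius=2, nf=1)
        flat = guided_wmf(img, np.zeros((10, 10)), radius=2, nf=32)
        assert np.array_equal(one_bin, flat)

    def test_constant_guidance_reduces_to_median_filter(self):
        rng = np.random.default_rng(23)
        for _ in range(5):
            img = random_intensity(rng, (11, 9))
            out = guided_wmf(img, np.full((11, 9), 0.7), radius=2)
            assert np.array_equal(out, median_filter_truncated(img, 2))

    def test_naive_center_matches_direct_weighted_median(self):
        """Dual route: the filter vs the bare cumulative-half-weight rule."""
        rng = np.random.default_rng(24)
        nf, bw = 16, 0.1
        centers = guidance_bin_centers(nf)
        for _ in range(20):
            img = random_intensity(rng, (5, 5))
            gd = rng.random((5, 5))
            out = guided_wmf(img, gd, radius=2, nf=nf, bandwidth=bw,
                             mode="naive")
            weights = [affinity_weight(
                float(centers[quantize_guidance(np.array([g]), nf)[0]]),
                float(gd[2, 2]), bw) for g in gd.ravel()]
            assert out[2, 2] == weighted_median(img.ravel(), weights)

    def test_backends_agree_on_random_inputs(self):
        rng = np.random.default_rng(25)
        for _ in range(6):
            img = random_intensity(rng, (14, 10))
            gd = rng.random((14, 10))
            a = guided_wmf(img, gd, radius=3, nf=8, mode="naive")
            b = guided_wmf(img, gd, radius=3, nf=8, mode="accelerated")
            assert np.array_equal(a, b)

    def test_backends_agree_on_non_integer_data(self):
        rng = np.random.default_rng(26)
        img = rng.random((12, 12)) * 255
        gd = rng.random((12, 12))
        a = guided_wmf(img, gd, radius=2, nf=8, mode="naive")
        b = guided_wmf(img, gd, radius=2, nf=8, mode="accelerated")
        assert np.array_equal(a, b)

    def test_errors(self):
        img = np.zeros((8, 8))
        with pytest.raises(ValueError):
            guided_wmf(img, np.zeros((8, 7)))
        with pytest.raises(ValueError):
            guided_wmf(img, np.zeros((8, 8)), radius=0)
        with pytest.raises(ValueError):
            guided_wmf(img, np.zeros((8, 8)), mode="warp")
        with pytest.raises(ValueError):
            guided_wmf(img, np.zeros((8, 8)), bandwidth=0.0)

    def test_radius_larger_than_image_truncates(self):
        rng = np.random.default_rng(27)
        img = random_intensity(rng, (4, 4))
        out = guided_wmf(img, np.full((4, 4), 0.5), radius=10)
        # every window is the whole image: lower median everywhere
        expected = np.sort(img, axis=None)[(img.size - 1) // 2]
        assert np.all(out == expected)
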