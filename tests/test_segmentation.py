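"""Multiresolution segmentation: stats, merge cost, and the merge engine."""

import numpy as np
import pytest
from scipy import ndimage

from forestseg import (
    MultibandScene,
    SegmentationParams,
    SegmentStats,
    init_segments,
    merge_cost,
    segment,
    segment_means,
)


def unit_stats(value, r=0, c=0):
    v = np.atleast_1d(np.asarray(value, dtype=float))
    return SegmentStats(n=1, band_sum=v.copy(), band_sumsq=v * v,
                        perimeter_l=4, bbox=(r, r, c, c))


def brute_stats(scene, mask):
    """Pixel-level recomputation of SegmentStats for a boolean mask."""
    rows, cols = np.nonzero(mask)
    n = len(rows)
    x = scene.pixels[mask]
    perim = 0
    h, w = mask.shape
    for r, c in zip(rows, cols):
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]:
                perim += 1
    return SegmentStats(
        n=n, band_sum=x.sum(axis=0), band_sumsq=(x * x).sum(axis=0),
        perimeter_l=perim,
        bbox=(rows.min(), rows.max(), cols.min(), cols.max()),
    )


class TestInitSegments:
    def test_one_segment_per_pixel(self, rng):
        scene = MultibandScene(rng.uniform(0, 10, (3, 3, 2)))
        sm = init_segments(scene)
        assert sm.n_segments == 9
        assert all(st.n == 1 and st.perimeter_l == 4 for st in sm.stats.values())

    def test_corner_has_two_neighbours(self, rng):
        scene = MultibandScene(rng.uniform(0, 10, (3, 3, 1)))
        sm = init_segments(scene)
        corner = int(sm.segment_ids[0, 0])
        assert len(sm.adjacency[corner]) == 2

    def test_pixel_count_conserved(self, rng):
        scene = MultibandScene(rng.uniform(0, 10, (5, 7, 3)))
        sm = init_segments(scene)
        assert sum(st.n for st in sm.stats.values()) == 35


class TestMergeCost:
    def test_identical_pixels_cost_zero(self):
        p = SegmentationParams(scale=10, w_color=1.0)
        assert merge_cost(unit_stats([3.0, 4.0]), unit_stats([3.0, 4.0], 0, 1),
                          p, shared_edges=1) == 0.0

    def test_color_cost_hand_computed(self):
        # one band, values 0 and 10: merged σ = 5 → Δh = 2·5 − 0 = 10
        p = SegmentationParams(scale=10, w_color=1.0)
        cost = merge_cost(unit_stats(0.0), unit_stats(10.0, 0, 1), p, shared_edges=1)
        assert cost == pytest.approx(10.0)

    def test_compactness_cost_hand_computed(self):
        # two horizontally adjacent unit pixels, pure compactness:
        # h each = 4/√1; merged l = 6, n = 2 → Δ = 2·6/√2 − 8 ≈ 0.4853
        p = SegmentationParams(scale=10, w_color=0.0, w_compact=1.0)
        cost = merge_cost(unit_stats(5.0), unit_stats(5.0, 0, 1), p, shared_edges=1)
        assert cost == pytest.approx(2 * 6 / np.sqrt(2) - 8, abs=1e-12)

    def test_smoothness_cost_hand_computed(self):
        # pure smoothness: h = l/bbox_perimeter; merged bbox 1×2 → b = 6
        # Δ = 2·(6/6) − (4/4 + 4/4) = 0
        p = SegmentationParams(scale=10, w_color=0.0, w_compact=0.0)
        cost = merge_cost(unit_stats(5.0), unit_stats(5.0, 0, 1), p, shared_edges=1)
        assert cost == pytest.approx(0.0, abs=1e-12)

    def test_matches_pixel_level_oracle_for_all_adjacent_pairs(self, rng):
        """merge_cost from incremental stats equals a from-pixels
        recomputation of the heterogeneity change for every 4-adjacent pair
        of a 6×6 random scene."""
        scene = MultibandScene(rng.uniform(0, 100, (6, 6, 3)))
        params = SegmentationParams(scale=50, w_color=0.7, w_compact=0.3)
        bw = np.ones(3)

        def h_color(mask):
            x = scene.pixels[mask]
            return float(np.dot(bw, x.std(axis=0) * mask.sum()))

        def shape_terms(mask):
            st = brute_stats(scene, mask)
            return (st.n * st.perimeter_l / np.sqrt(st.n),
                    st.n * st.perimeter_l / st.bbox_perimeter)

        for r in range(6):
            for c in range(6):
                for rr, cc in ((r + 1, c), (r, c + 1)):
                    if not (rr < 6 and cc < 6):
                        continue
                    a = np.zeros((6, 6), bool); a[r, c] = True
                    b = np.zeros((6, 6), bool); b[rr, cc] = True
                    m = a | b
                    d_color = h_color(m) - h_color(a) - h_color(b)
                    ca, sa = shape_terms(a)
                    cb, sb = shape_terms(b)
                    cm, sm = shape_terms(m)
                    expected = 0.7 * d_color + 0.3 * (
                        0.3 * (cm - ca - cb) + 0.7 * (sm - sa - sb)
                    )
                    got = merge_cost(brute_stats(scene, a), brute_stats(scene, b),
                                     params, shared_edges=1)
                    assert got == pytest.approx(expected, rel=1e-10)


class TestSegment:
    def test_constant_scene_collapses_to_one_segment(self):
        scene = MultibandScene(np.full((8, 8, 2), 7.0))
        sm = segment(scene, SegmentationParams(scale=5, w_color=1.0), rng_seed=0)
        assert sm.n_segments == 1

    def test_tiny_scale_equals_init_segments(self, rng):
        scene = MultibandScene(rng.uniform(0, 100, (6, 6, 2)))
        sm = segment(scene, SegmentationParams(scale=1e-6, w_color=1.0), rng_seed=0)
        assert sm.n_segments == 36

    def test_two_block_scene_recovered_exactly(self):
        px = np.zeros((8, 8, 1))
        px[:, 4:] = 100.0
        scene = MultibandScene(px)
        sm = segment(scene, SegmentationParams(scale=30, w_color=1.0), rng_seed=1)
        assert sm.n_segments == 2
        left = sm.segment_ids[:, :4]
        right = sm.segment_ids[:, 4:]
        assert len(np.unique(left)) == 1 and len(np.unique(right)) == 1

    def test_incremental_stats_match_pixel_recomputation(self, rng):
        scene = MultibandScene(rng.uniform(0, 500, (12, 12, 4)))
        sm = segment(scene, SegmentationParams(scale=40), rng_seed=2)
        for sid, st in sm.stats.items():
            ref = brute_stats(scene, sm.segment_ids == sid)
            assert st.n == ref.n
            np.testing.assert_allclose(st.band_sum, ref.band_sum, rtol=1e-8)
            np.testing.assert_allclose(st.band_sumsq, ref.band_sumsq, rtol=1e-8)
            assert st.perimeter_l == ref.perimeter_l
            assert st.bbox == ref.bbox

    def test_partition_and_connectivity(self, sim64):
        scene, _, _ = sim64
        sm = segment(scene, SegmentationParams(scale=60), rng_seed=3)
        assert sm.segment_ids.min() >= 1
        for sid in sm.ids():
            _, ncomp = ndimage.label(sm.segment_ids == sid)
            assert ncomp == 1

    def test_adjacency_symmetric_and_correct(self, sim64):
        scene, _, _ = sim64
        sm = segment(scene, SegmentationParams(scale=90), rng_seed=3)
        for sid, nbrs in sm.adjacency.items():
            for x in nbrs:
                assert sid in sm.adjacency[x]
        # spot-check against the raster
        ids = sm.segment_ids
        horiz = set(zip(ids[:, :-1].ravel(), ids[:, 1:].ravel()))
        vert = set(zip(ids[:-1].ravel(), ids[1:].ravel()))
        pairs = {(a, b) for a, b in horiz | vert if a != b}
        for a, b in pairs:
            assert b in sm.adjacency[a]

    def test_deterministic_under_fixed_seed(self, sim64):
        scene, _, _ = sim64
        p = SegmentationParams(scale=60)
        a = segment(scene, p, rng_seed=5)
        b = segment(scene, p, rng_seed=5)
        np.testing.assert_array_equal(a.segment_ids, b.segment_ids)

    def test_nodata_pixels_keep_id_zero(self, rng):
        px = rng.uniform(0, 10, (6, 6, 2))
        mask = np.zeros((6, 6), bool)
        mask[0, :3] = True
        scene = MultibandScene(px, nodata_mask=mask)
        sm = segment(scene, SegmentationParams(scale=100), rng_seed=0)
        assert np.all(sm.segment_ids[mask] == 0)
        assert np.all(sm.segment_ids[~mask] > 0)


class TestSegmentMeans:
    def test_single_pixel_segments_return_pixel_values(self, rng):
        scene = MultibandScene(rng.uniform(0, 9, (4, 4, 2)))
        sm = init_segments(scene)
        means = segment_means(sm, scene)
        for r in range(4):
            for c in range(4):
                np.testing.assert_allclose(
                    means[int(sm.segment_ids[r, c])], scene.pixels[r, c]
                )

    def test_matches_masked_average_oracle(self, rng):
        scene = MultibandScene(rng.uniform(0, 100, (8, 8, 3)))
        sm = segment(scene, SegmentationParams(scale=30), rng_seed=1)
        means = segment_means(sm, scene)
        for sid in sm.ids():
            ref = scene.pixels[sm.segment_ids == sid].mean(axis=0)
            np.testing.assert_allclose(means[sid], ref, rtol=1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        scene = MultibandScene(rng.uniform(0, 1, (4, 4, 1)))
        sm = init_segments(scene)
        other = MultibandScene(rng.uniform(0, 1, (5, 5, 1)))
        with pytest.raises(ValueError):
            segment_means(sm, other)
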