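import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as sp_dijkstra

from bbhmap import (
    SegmentationParams,
    VolumeGrid,
    classify_bbh_location,
    fast_marching_arrival,
    filter_significant,
    segment_hemorrhage,
)
from bbhmap.segmentation import speed_map


def dijkstra_arrival(cost, seeds):
    """Independent oracle: 6-connected shortest path with edge weight equal
    to the mean reciprocal speed of the incident voxels."""
    shape = cost.shape
    n = int(np.prod(shape))
    idx = np.arange(n).reshape(shape)
    c = cost.reshape(-1)
    rows, cols, w = [], [], []
    for ax in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(0, -1)
        sl_b[ax] = slice(1, None)
        a = idx[tuple(sl_a)].reshape(-1)
        b = idx[tuple(sl_b)].reshape(-1)
        rows.append(a)
        cols.append(b)
        w.append((c[a] + c[b]) / 2)
    rows, cols, w = map(np.concatenate, (rows, cols, w))
    g = coo_matrix(
        (np.concatenate([w, w]), (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(n, n),
    ).tocsr()
    d = sp_dijkstra(g, indices=[np.ravel_multi_index(s, shape) for s in seeds], min_only=True)
    return d.reshape(shape)


PARAMS = SegmentationParams()  # sigma 100, threshold 10


class TestArrival:
    def test_uniform_image_is_lattice_distance(self):
        img = VolumeGrid(np.full((15, 15, 15), 42.0), np.eye(4))
        T = fast_marching_arrival(img, [(7, 7, 7)], PARAMS).data
        assert T[7, 7, 7] == 0.0
        assert np.all(T >= 0)
        # monotone along each axis away from the single seed
        assert np.all(np.diff(T[7, 7, 7:]) > 0)
        assert np.all(np.diff(T[7:, 7, 7]) > 0)
        # axis-aligned arrival equals Euclidean distance at unit speed
        assert T[7, 7, 12] == pytest.approx(5.0, abs=1e-9)

    def test_zero_exactly_on_seeds(self, rng):
        img = VolumeGrid(rng.normal(100, 30, (10, 10, 10)), np.eye(4))
        seeds = [(2, 3, 4), (7, 1, 8)]
        T = fast_marching_arrival(img, seeds, PARAMS).data
        assert all(T[s] == 0.0 for s in seeds)
        assert (T == 0).sum() == len(seeds)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_graph_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = VolumeGrid(gaussian_filter(rng.normal(100, 60, (20, 20, 20)), 2), np.eye(4))
        seeds = [(5, 5, 5), (14, 12, 8)]
        T = fast_marching_arrival(img, seeds, PARAMS).data
        cost = 1.0 / speed_map(img, seeds, PARAMS)
        D = dijkstra_arrival(cost, seeds)
        cmax = cost.max()
        # upwind solution can only undercut the lattice path; the lattice
        # metric exceeds the continuous one by at most the sqrt(3) L1/L2 gap,
        # plus endpoint terms from the edge-averaged costs
        assert np.all(T <= D + cmax / 2 + 1e-9)
        assert np.all(D <= np.sqrt(3) * T + cmax + 1e-9)

    def test_no_seeds_rejected(self):
        img = VolumeGrid(np.zeros((5, 5, 5)), np.eye(4))
        with pytest.raises(ValueError, match="seed"):
            fast_marching_arrival(img, [], PARAMS)
        with pytest.raises(ValueError, match="outside"):
            fast_marching_arrival(img, [(9, 0, 0)], PARAMS)


class TestSegmentation:
    def _phantom(self, rng):
        shape = (24, 24, 24)
        ii, jj, kk = np.indices(shape)
        truth = (((ii - 12) / 8.0) ** 2 + ((jj - 12) / 6.0) ** 2 + ((kk - 12) / 7.0) ** 2) <= 1
        img = np.where(truth, 500.0, 0.0) + rng.normal(0, 15, shape)
        return VolumeGrid(img, np.eye(4)), truth

    def test_bright_ellipsoid_dice(self, rng):
        img, truth = self._phantom(rng)
        mask = segment_hemorrhage(img, [(12, 12, 12)], PARAMS).data.astype(bool)
        dice = 2 * (mask & truth).sum() / (mask.sum() + truth.sum())
        assert dice >= 0.90

    def test_zero_threshold_gives_seeds_only(self, rng):
        img = VolumeGrid(rng.normal(100, 10, (10, 10, 10)), np.eye(4))
        p = SegmentationParams(arrival_threshold=0.0)
        mask = segment_hemorrhage(img, [(4, 4, 4), (6, 2, 8)], p).data
        assert mask.sum() == 2 and mask[4, 4, 4] == 1 and mask[6, 2, 8] == 1

    def test_threshold_monotone(self, rng):
        img, _ = self._phantom(rng)
        small = segment_hemorrhage(img, [(12, 12, 12)], SegmentationParams(100, 6)).data
        large = segment_hemorrhage(img, [(12, 12, 12)], SegmentationParams(100, 12)).data
        assert np.all(large >= small)

    def test_deterministic(self, rng):
        img, _ = self._phantom(rng)
        a = segment_hemorrhage(img, [(12, 12, 12)], PARAMS).data
        b = segment_hemorrhage(img, [(12, 12, 12)], PARAMS).data
        np.testing.assert_array_equal(a, b)


class TestSignificance:
    def _mask_of(self, n, voxel=1.0):
        data = np.zeros((12, 12, 12), np.uint8)
        data.reshape(-1)[:n] = 1
        return VolumeGrid(data, np.diag([voxel] * 3 + [1.0]))

    def test_exactly_half_ml_is_significant(self):
        sig, vol = filter_significant(self._mask_of(500), SegmentationParams())
        assert sig and vol == pytest.approx(0.5)

    def test_just_below_is_not(self):
        sig, vol = filter_significant(self._mask_of(490), SegmentationParams())
        assert not sig and vol == pytest.approx(0.49)

    def test_empty_mask(self):
        sig, vol = filter_significant(self._mask_of(0), SegmentationParams())
        assert (sig, vol) == (False, 0.0)


class TestLocation:
    def _grids(self, bbh_sel, lesion_sel):
        b = np.zeros((10, 10, 10), np.uint8)
        l = np.zeros((10, 10, 10), np.uint8)
        b[bbh_sel] = 1
        l[lesion_sel] = 1
        return VolumeGrid(b, np.eye(4)), VolumeGrid(l, np.eye(4))

    def test_subset_is_intralesional(self):
        b, l = self._grids(np.s_[2:4, 2:4, 2:4], np.s_[1:6, 1:6, 1:6])
        assert classify_bbh_location(b, l) == "intralesional"

    def test_disjoint_is_extralesional(self):
        b, l = self._grids(np.s_[0:2, 0:2, 0:2], np.s_[5:8, 5:8, 5:8])
        assert classify_bbh_location(b, l) == "extralesional"

    def test_even_split_is_both(self):
        b = np.zeros((10, 10, 10), np.uint8)
        b[0:4, 0, 0] = 1
        l = np.zeros((10, 10, 10), np.uint8)
        l[0:2, 0, 0] = 1  # covers exactly half the bleed
        assert classify_bbh_location(VolumeGrid(b, np.eye(4)), VolumeGrid(l, np.eye(4))) == "both"

    def test_empty_bleed_rejected(self):
        b, l = self._grids(np.s_[0:0], np.s_[1:3, 1:3, 1:3])
        with pytest.raises(ValueError, match="empty"):
            classify_bbh_location(b, l)
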