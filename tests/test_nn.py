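"""Unit tests for the primitive network operations."""

import numpy as np
import pytest

from polypseg.architecture import (
    FeatureMap,
    PooledFeature,
    conv_block,
    dilated_pyramid,
    pool_with_indices,
    skip_merge,
    unpool_with_indices,
)
from polypseg.nn import functional as F


# ---------------------------------------------------------------------------
# convolution blocks
# ---------------------------------------------------------------------------

class TestConvBlock:
    def test_relu_clamps_negative_identity_kernel(self):
        x = FeatureMap(np.full((1, 1, 1), -5.0))
        w = np.ones((1, 1, 1, 1))
        out = conv_block(x, w, np.zeros(1))
        assert out.values[0, 0, 0] == 0.0

    def test_all_ones_kernel_center_value(self):
        # 3x3 ones input, 3x3 ones kernel, zero padding: the center output
        # is the full double sum = 9, edges see fewer taps
        x = FeatureMap(np.ones((1, 3, 3)))
        w = np.ones((1, 1, 3, 3))
        out = conv_block(x, w, np.zeros(1))
        assert out.values[0, 1, 1] == pytest.approx(9.0)
        assert out.values[0, 0, 0] == pytest.approx(4.0)

    @pytest.mark.parametrize("shape,k", [((3, 7, 5), 3), ((2, 8, 8), 5),
                                         ((1, 4, 9), 1)])
    def test_resolution_preserved(self, rng, shape, k):
        x = FeatureMap(rng.normal(size=shape))
        w = rng.normal(size=(4, shape[0], k, k))
        out = conv_block(x, w, rng.normal(size=4))
        assert out.resolution == x.resolution
        assert out.channels == 4
        assert (out.values >= 0).all()

    def test_channel_mismatch_rejected(self, rng):
        x = FeatureMap(rng.normal(size=(3, 4, 4)))
        w = rng.normal(size=(2, 5, 3, 3))
        with pytest.raises(ValueError, match="channel mismatch"):
            conv_block(x, w, np.zeros(2))

    def test_even_kernel_rejected(self, rng):
        x = FeatureMap(rng.normal(size=(1, 4, 4)))
        with pytest.raises(ValueError, match="odd"):
            conv_block(x, rng.normal(size=(1, 1, 2, 2)), np.zeros(1))


class TestConvGradients:
    """Backward passes agree with central finite differences."""

    def _num_grad(self, f, arr, eps=1e-2):
        ng = np.zeros(arr.shape)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            orig = arr[i]
            arr[i] = orig + eps
            fp = f()
            arr[i] = orig - eps
            fm = f()
            arr[i] = orig
            ng[i] = (fp - fm) / (2 * eps)
        return ng

    @pytest.mark.parametrize("dilation", [1, 2])
    def test_conv2d_backward(self, rng, dilation):
        x = rng.normal(size=(2, 3, 5, 4)).astype(np.float32)
        w = rng.normal(size=(2, 3, 3, 3)).astype(np.float32)
        b = rng.normal(size=2).astype(np.float32)
        out, xp = F.conv2d(x, w, b, dilation=dilation, return_cache=True)
        g = rng.normal(size=out.shape).astype(np.float32)
        gx, gw, gb = F.conv2d_backward(g, xp, w, dilation=dilation)
        f = lambda: float((F.conv2d(x, w, b, dilation=dilation) * g).sum())
        scale = max(np.abs(gx).max(), np.abs(gw).max(), 1.0)
        assert np.abs(gx - self._num_grad(f, x)).max() / scale < 2e-2
        assert np.abs(gw - self._num_grad(f, w)).max() / scale < 2e-2
        assert np.abs(gb - self._num_grad(f, b)).max() / scale < 2e-2

    def test_batchnorm_backward(self, rng):
        x = rng.normal(size=(2, 3, 4, 3)).astype(np.float32)
        gamma = rng.normal(size=3).astype(np.float32)
        beta = rng.normal(size=3).astype(np.float32)
        rm, rv = np.zeros(3, np.float32), np.ones(3, np.float32)
        y, cache = F.batchnorm(x, gamma, beta, rm.copy(), rv.copy(), True)
        g = rng.normal(size=y.shape).astype(np.float32)
        gx, gg, gb = F.batchnorm_backward(g, cache, gamma)

        def f():
            out, _ = F.batchnorm(x, gamma, beta, rm.copy(), rv.copy(), True)
            return float((out * g).sum())

        assert np.abs(gx - self._num_grad(f, x)).max() < 2e-2
        assert np.abs(gg - self._num_grad(f, gamma)).max() < 2e-2
        assert np.abs(gb - self._num_grad(f, beta)).max() < 2e-2


# ---------------------------------------------------------------------------
# pooling / unpooling
# ---------------------------------------------------------------------------

def brute_force_pool(x):
    """Reference 2x2 max pooling with row-major first-occurrence tie-break."""
    c, h, w = x.shape
    ph, pw = (h + 1) // 2, (w + 1) // 2
    pooled = np.zeros((c, ph, pw), dtype=x.dtype)
    idx = np.zeros((c, ph, pw), dtype=np.int64)
    for ci in range(c):
        for i in range(ph):
            for j in range(pw):
                best, best_flat = -np.inf, -1
                for dr in range(2):
                    for dc in range(2):
                        r, col = 2 * i + dr, 2 * j + dc
                        if r < h and col < w and x[ci, r, col] > best:
                            best = x[ci, r, col]
                            best_flat = r * w + col
                pooled[ci, i, j] = best
                idx[ci, i, j] = best_flat
    return pooled, idx


class TestPoolUnpool:
    def test_single_window(self):
        p = pool_with_indices(FeatureMap([[[1.0, 2.0], [3.0, 4.0]]]))
        assert p.pooled.values[0, 0, 0] == 4.0
        assert p.indices[0, 0, 0] == 3  # flat position of the 4

    def test_constant_map_tie_breaks_top_left(self):
        p = pool_with_indices(FeatureMap(np.ones((1, 4, 4))))
        assert (p.pooled.values == 1.0).all()
        expected = np.array([[0, 2], [8, 10]])
        np.testing.assert_array_equal(p.indices[0], expected)

    @pytest.mark.parametrize("shape", [(1, 8, 8), (3, 6, 4), (2, 5, 7)])
    def test_matches_brute_force(self, rng, shape):
        x = rng.uniform(0.1, 1.0, size=shape).astype(np.float32)
        p = pool_with_indices(FeatureMap(x))
        ref_pooled, ref_idx = brute_force_pool(x)
        np.testing.assert_array_equal(p.pooled.values, ref_pooled)
        np.testing.assert_array_equal(p.indices, ref_idx)

    def test_unpool_scatter(self):
        p = PooledFeature(pooled=FeatureMap([[[4.0]]]),
                          indices=np.array([[[3]]]), pre_pool_size=(2, 2))
        out = unpool_with_indices(p)
        np.testing.assert_array_equal(out.values[0], [[0, 0], [0, 4]])

    def test_round_trip_identity(self, rng):
        # pooling after unpooling restores the pooled map exactly
        # (positive maps, as everywhere after a ReLU)
        for _ in range(50):
            x = rng.uniform(0.01, 1.0, size=(2, 8, 8)).astype(np.float32)
            p = pool_with_indices(FeatureMap(x))
            p2 = pool_with_indices(unpool_with_indices(p))
            np.testing.assert_array_equal(p.pooled.values, p2.pooled.values)
            np.testing.assert_array_equal(p.indices, p2.indices)

    def test_sum_preserved(self, rng):
        x = rng.uniform(0.0, 1.0, size=(2, 6, 6)).astype(np.float32)
        p = pool_with_indices(FeatureMap(x))
        out = unpool_with_indices(p)
        assert out.values.sum() == pytest.approx(p.pooled.values.sum())

    def test_indices_unique_per_channel(self, rng):
        x = rng.uniform(size=(3, 8, 8)).astype(np.float32)
        p = pool_with_indices(FeatureMap(x))
        for c in range(3):
            flat = p.indices[c].ravel()
            assert len(np.unique(flat)) == flat.size

    def test_out_of_range_index_rejected(self):
        p = PooledFeature(pooled=FeatureMap([[[1.0]]]),
                          indices=np.array([[[7]]]), pre_pool_size=(2, 2))
        with pytest.raises(IndexError):
            unpool_with_indices(p)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pool_with_indices(FeatureMap(np.zeros((1, 0, 0))))


# ---------------------------------------------------------------------------
# dilated pyramid & skip merge
# ---------------------------------------------------------------------------

class TestDilatedPyramid:
    def test_resolution_preserved(self, rng):
        x = FeatureMap(rng.normal(size=(4, 6, 6)))
        branches = [(rng.normal(size=(4, 4, 3, 3)), rng.normal(size=4))
                    for _ in range(4)]
        proj = (rng.normal(size=(4, 16, 1, 1)), rng.normal(size=4))
        out = dilated_pyramid(x, branches, proj)
        assert out.resolution == x.resolution

    def test_dilation_one_branch_equals_plain_conv(self, rng):
        # with shared weights the l=1 branch is an ordinary conv block
        x = FeatureMap(rng.normal(size=(3, 5, 5)))
        w = rng.normal(size=(2, 3, 3, 3))
        b = rng.normal(size=2)
        plain = conv_block(x, w, b)
        branch = conv_block(x, w, b, dilation=1)
        np.testing.assert_array_equal(plain.values, branch.values)

    def test_effective_receptive_field_dilation6(self):
        # a 3x3 kernel at dilation 6 spans k + (k-1)(l-1) = 13 cells
        x = np.zeros((1, 1, 27, 27), dtype=np.float32)
        x[0, 0, 13, 13] = 1.0
        w = np.ones((1, 1, 3, 3), dtype=np.float32)
        out = F.conv2d(x, w, np.zeros(1, dtype=np.float32), dilation=6)
        rows = np.nonzero(out[0, 0].sum(axis=1))[0]
        cols = np.nonzero(out[0, 0].sum(axis=0))[0]
        assert rows.max() - rows.min() + 1 == 13
        assert cols.max() - cols.min() + 1 == 13

    def test_wrong_dilation_set_rejected(self, rng):
        x = FeatureMap(rng.normal(size=(1, 4, 4)))
        params = [(rng.normal(size=(1, 1, 3, 3)), np.zeros(1))] * 4
        proj = (rng.normal(size=(1, 4, 1, 1)), np.zeros(1))
        with pytest.raises(ValueError, match="dilation set"):
            dilated_pyramid(x, params, proj, dilations=[1, 2, 4, 8])


class TestSkipMerge:
    def test_additive_identity(self, rng):
        x = FeatureMap(rng.normal(size=(3, 4, 4)))
        z = FeatureMap(np.zeros((3, 4, 4)))
        np.testing.assert_array_equal(skip_merge(x, z, "add").values, x.values)

    def test_add_commutative(self, rng):
        x = FeatureMap(rng.normal(size=(2, 3, 3)))
        y = FeatureMap(rng.normal(size=(2, 3, 3)))
        np.testing.assert_array_equal(skip_merge(x, y, "add").values,
                                      skip_merge(y, x, "add").values)

    def test_concat_channel_count(self, rng):
        a = FeatureMap(rng.normal(size=(3, 4, 4)))
        b = FeatureMap(rng.normal(size=(5, 4, 4)))
        assert skip_merge(a, b, "concat").channels == 8

    def test_resolution_mismatch_rejected(self, rng):
        a = FeatureMap(rng.normal(size=(2, 4, 4)))
        b = FeatureMap(rng.normal(size=(2, 8, 8)))
        with pytest.raises(ValueError):
            skip_merge(a, b, "add")

    def test_add_channel_mismatch_rejected(self, rng):
        a = FeatureMap(rng.normal(size=(2, 4, 4)))
        b = FeatureMap(rng.normal(size=(3, 4, 4)))
        with pytest.raises(ValueError):
            skip_merge(a, b, "add")


def test_softmax_normalises_per_pixel(rng):
    x = rng.normal(size=(2, 2, 5, 5)).astype(np.float32) * 10
    p = F.softmax_channels(x)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
    assert (p >= 0).all()
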