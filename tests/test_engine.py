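"""The deterministic forward engine against brute-force loop oracles."""

import numpy as np
import pytest

import halotile as ht
from halotile import engine
from halotile.errors import ConstraintError, StructureError


# ---------------------------------------------------------------------------
# brute-force oracles: plain nested loops, no vectorisation
# ---------------------------------------------------------------------------

def conv2d_loops(x, kernel, bias, padding):
    k = kernel.shape[0]
    r = k // 2
    h, w, ci = x.shape
    co = kernel.shape[3]
    if padding == "SAME":
        xp = np.zeros((h + 2 * r, w + 2 * r, ci))
        xp[r:r + h, r:r + w] = x
        ho, wo = h, w
    else:
        xp = x
        ho, wo = h - 2 * r, w - 2 * r
    out = np.zeros((ho, wo, co))
    for y in range(ho):
        for z in range(wo):
            for o in range(co):
                acc = bias[o]
                for dy in range(k):
                    for dx in range(k):
                        for c in range(ci):
                            acc += xp[y + dy, z + dx, c] * kernel[dy, dx, c, o]
                out[y, z, o] = acc
    return out


def maxpool2_loops(x):
    h, w, c = x.shape
    out = np.empty((h // 2, w // 2, c))
    for y in range(h // 2):
        for z in range(w // 2):
            for ch in range(c):
                out[y, z, ch] = x[2 * y:2 * y + 2, 2 * z:2 * z + 2, ch].max()
    return out


def upconv2_loops(x, kernel, bias):
    k = kernel.shape[0]
    off = (k - 1) // 2
    h, w, ci = x.shape
    co = kernel.shape[3]
    out = np.zeros((2 * h, 2 * w, co)) + bias
    for py in range(h):
        for px in range(w):
            for dy in range(k):
                for dx in range(k):
                    ty, tx = 2 * py + dy - off, 2 * px + dx - off
                    if 0 <= ty < 2 * h and 0 <= tx < 2 * w:
                        for c in range(ci):
                            for o in range(co):
                                out[ty, tx, o] += x[py, px, c] * kernel[dy, dx, c, o]
    return out


class TestConv2d:
    def test_identity_1x1(self, rng):
        x = rng.standard_normal((6, 7, 3))
        kernel = np.eye(3)[None, None]
        out = engine.conv2d(x, kernel, np.zeros(3), "SAME")
        np.testing.assert_array_equal(out, x)

    def test_impulse_response_same(self):
        x = np.zeros((7, 7, 1))
        x[3, 3, 0] = 1.0
        out = engine.conv2d(x, np.ones((3, 3, 1, 1)), np.zeros(1), "SAME")
        assert out[2:5, 2:5, 0].sum() == 9.0 and out.sum() == 9.0

    def test_valid_shrinks_by_kernel_minus_one(self, rng):
        x = rng.standard_normal((10, 10, 1))
        out = engine.conv2d(x, rng.standard_normal((3, 3, 1, 2)), np.zeros(2), "VALID")
        assert out.shape == (8, 8, 2)

    @pytest.mark.parametrize("padding", ["SAME", "VALID"])
    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_matches_loop_oracle(self, rng, padding, k):
        x = rng.standard_normal((9, 11, 3))
        kernel = rng.standard_normal((k, k, 3, 2))
        bias = rng.standard_normal(2)
        got = engine.conv2d(x, kernel, bias, padding)
        want = conv2d_loops(x, kernel, bias, padding)
        np.testing.assert_allclose(got, want, atol=1e-10, rtol=0)

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ConstraintError):
            engine.conv2d(rng.standard_normal((4, 4, 2)),
                          rng.standard_normal((3, 3, 3, 1)), np.zeros(1))


class TestPooling:
    def test_constant_preserved(self):
        x = np.full((4, 6, 2), 3.5)
        np.testing.assert_array_equal(engine.maxpool2(x), np.full((2, 3, 2), 3.5))

    def test_2x2_example(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])[:, :, None]
        assert engine.maxpool2(x)[0, 0, 0] == 4.0

    def test_matches_loop_oracle(self, rng):
        x = rng.standard_normal((8, 12, 3))
        np.testing.assert_array_equal(engine.maxpool2(x), maxpool2_loops(x))

    def test_odd_dims_rejected(self, rng):
        with pytest.raises(ConstraintError, match="even"):
            engine.maxpool2(rng.standard_normal((5, 4, 1)))

    def test_avgpool_is_window_mean(self, rng):
        x = rng.standard_normal((6, 8, 2))
        want = x.reshape(3, 2, 4, 2, 2).mean(axis=(1, 3))
        np.testing.assert_allclose(engine.avgpool2(x), want, atol=1e-12)


class TestUpconv2:
    def test_doubles_dimensions(self, rng):
        x = rng.standard_normal((5, 7, 2))
        out = engine.upconv2(x, rng.standard_normal((2, 2, 2, 3)), np.zeros(3))
        assert out.shape == (10, 14, 3)

    def test_k2_identity_kernel_is_nearest_neighbour_upsample(self, rng):
        x = rng.standard_normal((4, 4, 1))
        out = engine.upconv2(x, np.ones((2, 2, 1, 1)), np.zeros(1))
        np.testing.assert_array_equal(out[:, :, 0], np.kron(x[:, :, 0], np.ones((2, 2))))

    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_scatter_oracle(self, rng, k):
        x = rng.standard_normal((4, 5, 2))
        kernel = rng.standard_normal((k, k, 2, 3))
        bias = rng.standard_normal(3)
        np.testing.assert_allclose(engine.upconv2(x, kernel, bias),
                                   upconv2_loops(x, kernel, bias),
                                   atol=1e-10, rtol=0)


class TestBatchnormSoftmax:
    def test_identity_stats(self, rng):
        x = rng.standard_normal((4, 4, 3))
        st = engine.BNStats(np.zeros(3), np.ones(3), np.ones(3), np.zeros(3), eps=0.0)
        np.testing.assert_array_equal(engine.batchnorm_inference(x, st), x)

    def test_shift_only(self, rng):
        x = rng.standard_normal((4, 4, 2))
        st = engine.BNStats(np.zeros(2), np.ones(2), np.ones(2),
                            np.array([1.0, -2.0]), eps=0.0)
        np.testing.assert_allclose(engine.batchnorm_inference(x, st),
                                   x + np.array([1.0, -2.0]), atol=1e-12)

    def test_matches_scalar_recomputation(self, rng):
        x = rng.standard_normal((5, 6, 3))
        st = engine.BNStats(rng.standard_normal(3), rng.uniform(0.1, 2, 3),
                            rng.standard_normal(3), rng.standard_normal(3))
        got = engine.batchnorm_inference(x, st)
        for c in range(3):
            want = (x[:, :, c] - st.mean[c]) / np.sqrt(st.var[c] + st.eps) \
                * st.scale[c] + st.shift[c]
            np.testing.assert_allclose(got[:, :, c], want, atol=1e-10)

    def test_negative_variance_rejected(self):
        with pytest.raises(ConstraintError):
            engine.BNStats(np.zeros(1), -np.ones(1), np.ones(1), np.zeros(1))

    def test_softmax_channels_sum_to_one(self, rng):
        s = engine.softmax(rng.standard_normal((6, 6, 4)) * 30)
        np.testing.assert_allclose(s.sum(axis=-1), 1.0, atol=1e-6)

    def test_argmax_tie_breaks_to_lowest_index(self):
        x = np.zeros((2, 2, 3))
        assert (engine.argmax_mask(x) == 0).all()


class TestSeededWeights:
    def test_same_seed_identical(self, unet_d2):
        w1, w2 = ht.seeded_weights(unet_d2, 7), ht.seeded_weights(unet_d2, 7)
        for i in w1.conv:
            np.testing.assert_array_equal(w1.conv[i][0], w2.conv[i][0])

    def test_different_seeds_differ(self, unet_d2):
        w1, w2 = ht.seeded_weights(unet_d2, 0), ht.seeded_weights(unet_d2, 1)
        i = next(iter(w1.conv))
        assert not np.array_equal(w1.conv[i][0], w2.conv[i][0])

    def test_noise_segmentation_is_nonconstant(self, unet_d2, unet_d2_weights):
        # fixture sanity: an untrained seeded model must produce a
        # non-trivial class map on a noise image
        mask = ht.argmax_mask(ht.forward(unet_d2, unet_d2_weights,
                                         ht.generate_noise_image(32, 32, 5)))
        assert len(np.unique(mask)) >= 2

    def test_save_load_round_trip(self, unet_d2, unet_d2_weights, tmp_path):
        path = tmp_path / "w.npz"
        ht.save_weights(unet_d2_weights, path)
        loaded = ht.load_weights(path, unet_d2)
        assert loaded.seed == unet_d2_weights.seed
        for i in unet_d2_weights.conv:
            np.testing.assert_array_equal(loaded.conv[i][0], unet_d2_weights.conv[i][0])

    def test_load_validates_shapes(self, unet_d2, unet_d2_weights, tmp_path):
        path = tmp_path / "w.npz"
        ht.save_weights(unet_d2_weights, path)
        with pytest.raises(StructureError):
            ht.load_weights(path, ht.build_unet(2, base_channels=8))


class TestForward:
    def test_zero_weights_give_uniform_softmax(self, unet_d2):
        w = ht.seeded_weights(unet_d2, 0)
        for i in w.conv:
            w.conv[i] = (np.zeros_like(w.conv[i][0]), w.conv[i][1])
        out = ht.forward(unet_d2, w, ht.generate_noise_image(16, 16, 0))
        np.testing.assert_allclose(out, 0.5, atol=1e-12)

    def test_same_mode_preserves_spatial_size(self, unet_d2, unet_d2_weights):
        out = ht.forward(unet_d2, unet_d2_weights, ht.generate_noise_image(24, 32, 3))
        assert out.shape == (24, 32, 2)

    def test_size_not_multiple_of_F_rejected(self, unet_d2, unet_d2_weights):
        with pytest.raises(ConstraintError, match="pad"):
            ht.forward(unet_d2, unet_d2_weights, ht.generate_noise_image(15, 16, 0))

    def test_linear_mode_is_homogeneous(self, unet_d2, unet_d2_weights):
        # biases are zero and batch-norm is identity, so the linear-mode
        # map must commute with scaling
        x = ht.generate_noise_image(16, 16, 2)
        a = -2.5
        fx = ht.forward(unet_d2, unet_d2_weights, x, mode="linear")
        fax = ht.forward(unet_d2, unet_d2_weights, a * x, mode="linear")
        np.testing.assert_allclose(fax, a * fx, atol=1e-9)

    def test_translation_by_F_shifts_output(self, unet_d3):
        # content shifted by F produces the identically shifted prediction
        # in the interior beyond the exact halo
        w = ht.seeded_weights(unet_d3, 4)
        F = ht.compute_F(unet_d3)
        halo = ht.exact_halo(unet_d3)
        big = ht.generate_noise_image(96, 96 + F, 11)
        out0 = ht.forward(unet_d3, w, big[:, :96])
        out1 = ht.forward(unet_d3, w, big[:, F:])
        sl = np.s_[halo:-halo]
        np.testing.assert_array_equal(out0[sl, F + halo:96 - halo],
                                      out1[sl, halo:96 - F - halo])
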