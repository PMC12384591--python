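"""Grad-CAM: exact gradients, pooling/weighting arithmetic, interpolation, CAM limit."""

import numpy as np
import pytest

from eegcam.gradcam import (
    class_gradients,
    gradcam,
    gradcam_batch,
    pool_gradients,
    target_layer_forward,
    upsample_to_input,
    weighted_map,
)
from eegcam.nn import EmotionNet, GapHeadNet, NetworkSpec, build_network


@pytest.fixture()
def small_net():
    spec = NetworkSpec.scaled(n_classes=2, width=1, input_shape=(16, 8))
    return EmotionNet(spec, seed=4, dtype=np.float64)


class TestTargetLayer:
    def test_canonical_activation_shape(self):
        net, _ = build_network(NetworkSpec.canonical(4))
        window = np.random.default_rng(0).normal(size=(32, 128))
        acts, logits = target_layer_forward(net, window)
        assert acts.shape == (64, 32, 128)  # H x W x K
        assert logits.shape == (4,)

    def test_zero_input_zero_activations(self, small_net):
        acts, _ = target_layer_forward(small_net, np.zeros((8, 16)))
        assert np.all(acts == 0.0)

    def test_identical_windows_identical_activations(self, small_net):
        w = np.random.default_rng(1).normal(size=(8, 16))
        a1, l1 = target_layer_forward(small_net, w)
        a2, l2 = target_layer_forward(small_net, w)
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(l1, l2)


class TestClassGradients:
    def test_matches_finite_differences(self, small_net):
        """Central differences on random activation coordinates, 1e-3 relative."""
        rng = np.random.default_rng(2)
        window = rng.normal(size=(8, 16))
        c = 1
        grads = class_gradients(small_net, window, c)  # (H, W, K)
        acts, _ = target_layer_forward(small_net, window)
        a6 = np.ascontiguousarray(acts.transpose(2, 0, 1))[None]  # (1, K, H, W)
        h, w, k = acts.shape
        eps = 1e-5
        # restrict to differentiable coordinates: skip max-pool ties, where the
        # one-sided derivatives differ and central differences are undefined
        coords = []
        while len(coords) < 20:
            y, x, kk = rng.integers(h), rng.integers(w), rng.integers(k)
            partner = y + 1 if y % 2 == 0 else y - 1
            if abs(acts[y, x, kk] - acts[partner, x, kk]) > 1e-3:
                coords.append((y, x, kk))
        for y, x, kk in coords:
            up, down = a6.copy(), a6.copy()
            up[0, kk, y, x] += eps
            down[0, kk, y, x] -= eps
            fd = (small_net.head_forward(up)[0, c] - small_net.head_forward(down)[0, c]) / (2 * eps)
            assert grads[y, x, kk] == pytest.approx(fd, rel=1e-3, abs=1e-8)

    def test_dead_feature_map_has_zero_gradient(self, small_net):
        """Zeroing the head weights that read feature k kills its gradient."""
        spec = small_net.spec
        k = 1
        h2, w = spec.input_shape[0] // 4, spec.input_shape[1]
        block = slice(k * h2 * w, (k + 1) * h2 * w)  # flatten layout is (K, H/2, W)
        small_net.fc1.W[:, block] = 0.0
        grads = class_gradients(small_net, np.random.default_rng(3).normal(size=(8, 16)), 0)
        np.testing.assert_allclose(grads[:, :, k], 0.0, atol=1e-14)

    def test_distinct_classes_distinct_gradients(self, small_net):
        window = np.random.default_rng(4).normal(size=(8, 16))
        g0 = class_gradients(small_net, window, 0)
        g1 = class_gradients(small_net, window, 1)
        assert not np.allclose(g0, g1)

    def test_invalid_class_rejected(self, small_net):
        with pytest.raises(ValueError, match="class index"):
            class_gradients(small_net, np.zeros((8, 16)), 5)


class TestPoolingAndWeighting:
    def test_pool_examples(self):
        assert pool_gradients(np.ones((2, 2, 1)))[0] == pytest.approx(1.0)
        slab = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(2, 2, 1)
        assert pool_gradients(slab)[0] == pytest.approx(2.5)
        np.testing.assert_array_equal(pool_gradients(np.zeros((3, 4, 5))), np.zeros(5))

    def test_weighted_map_relu_clamp(self):
        out = weighted_map(np.array([1.0]), np.array([[-1.0, 2.0]]).reshape(1, 2, 1))
        np.testing.assert_array_equal(out, [[0.0, 2.0]])

    def test_weighted_map_cancellation(self):
        acts = np.stack([np.full((1, 1), 3.0), np.full((1, 1), 5.0)], axis=-1)
        np.testing.assert_array_equal(weighted_map(np.array([1.0, -1.0]), acts), [[0.0]])

    def test_zero_weights_zero_map(self):
        acts = np.random.default_rng(0).normal(size=(4, 3, 6))
        np.testing.assert_array_equal(weighted_map(np.zeros(6), acts), np.zeros((4, 3)))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="feature maps"):
            weighted_map(np.zeros(3), np.zeros((2, 2, 4)))


def naive_bilinear(img, out_h, out_w):
    """Brute-force half-pixel bilinear interpolation (independent oracle)."""
    in_h, in_w = img.shape
    out = np.empty((out_h, out_w))
    for oy in range(out_h):
        for ox in range(out_w):
            sy = min(max((oy + 0.5) * in_h / out_h - 0.5, 0.0), in_h - 1.0)
            sx = min(max((ox + 0.5) * in_w / out_w - 0.5, 0.0), in_w - 1.0)
            y0, x0 = int(np.floor(sy)), int(np.floor(sx))
            y1, x1 = min(y0 + 1, in_h - 1), min(x0 + 1, in_w - 1)
            fy, fx = sy - y0, sx - x0
            top = img[y0, x0] * (1 - fx) + img[y0, x1] * fx
            bot = img[y1, x0] * (1 - fx) + img[y1, x1] * fx
            out[oy, ox] = top * (1 - fy) + bot * fy
    return out


class TestUpsampling:
    def test_constant_preserved(self):
        out = upsample_to_input(np.full((64, 32), 0.7))
        assert out.shape == (128, 32)
        np.testing.assert_allclose(out, 0.7, atol=1e-12)

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(5)
        img = rng.random((64, 32))
        np.testing.assert_allclose(
            upsample_to_input(img, (128, 32)), naive_bilinear(img, 128, 32), atol=1e-12
        )

    def test_column_two_point_example(self):
        col = np.array([[1.0], [3.0]])
        out = upsample_to_input(col, (4, 1))
        np.testing.assert_allclose(out[:, 0], naive_bilinear(col, 4, 1)[:, 0], atol=1e-12)
        np.testing.assert_allclose(out[:, 0], [1.0, 1.5, 2.5, 3.0])

    def test_nonnegativity_preserved(self):
        rng = np.random.default_rng(6)
        img = np.abs(rng.normal(size=(16, 8)))
        assert upsample_to_input(img, (128, 32)).min() >= 0.0


class TestGradCamComposition:
    def test_map_nonnegative_and_input_shaped(self, small_net):
        m = gradcam(small_net, np.random.default_rng(7).normal(size=(8, 16)), 0)
        assert m.shape == (16, 8)
        assert m.min() >= 0.0

    def test_canonical_map_is_128x32(self):
        net, _ = build_network(NetworkSpec.canonical(4))
        m = gradcam(net, np.random.default_rng(8).normal(size=(32, 128)), 2)
        assert m.shape == (128, 32)
        assert m.min() >= 0.0

    def test_cam_equivalence_in_gap_head_limit(self):
        """With a GAP+linear head the map equals ReLU(sum_k w_ck A^k) up to scale."""
        net = GapHeadNet(n_maps=5, n_classes=2, seed=9, input_shape=(8, 6))
        window = np.random.default_rng(10).normal(size=(6, 8))  # channels x time
        acts, _ = target_layer_forward(net, window)
        c = 1
        raw = weighted_map(pool_gradients(class_gradients(net, window, c)), acts)
        cam = np.maximum(np.einsum("hwk,k->hw", acts, net.head.W[c]), 0.0)
        assert raw.max() > 0
        np.testing.assert_allclose(raw / raw.max(), cam / cam.max(), atol=1e-6)

    def test_head_scale_covariance(self, small_net):
        """Scaling class-c head weights by lambda scales the map by lambda."""
        window = np.random.default_rng(11).normal(size=(8, 16))
        m1 = gradcam(small_net, window, 0)
        small_net.fc2.W[0] *= 3.0
        small_net.fc2.b[0] *= 3.0
        m2 = gradcam(small_net, window, 0)
        np.testing.assert_allclose(m2, 3.0 * m1, rtol=1e-9, atol=1e-12)

    def test_batch_matches_single(self, small_net):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(3, 8, 16))
        batch = gradcam_batch(small_net, X, classes=np.array([0, 1, 0]))
        for i, c in enumerate([0, 1, 0]):
            np.testing.assert_allclose(batch[i], gradcam(small_net, X[i], c), atol=1e-10)
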