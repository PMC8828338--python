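"""Dilated convolution operator, architecture, receptive field, prediction.

The reference for the convolution is a literal nested-sum oracle of the
d-dilated definition out(p) = sum_{s + d t = p} f(s) r(t), evaluated
pointwise in pure Python loops.
"""

import numpy as np
import pytest
from scipy import signal

from dbtseg.network import (
    ArchitectureSpec,
    Kernel,
    LayerSpec,
    build_network,
    default_architecture,
    dilated_conv2d,
    load_model,
    predict_heatmap,
    receptive_field,
    save_model,
    softmax_channels,
)
from dbtseg.volume import ImageVolume


def nested_sum_oracle(f: np.ndarray, r: np.ndarray, d: int) -> np.ndarray:
    """Literal evaluation of the dilated-convolution sum with zero padding."""
    k = r.shape[0] // 2
    H, W = f.shape
    out = np.zeros((H, W))
    for pi in range(H):
        for pj in range(W):
            acc = 0.0
            for ti in range(-k, k + 1):
                for tj in range(-k, k + 1):
                    si, sj = pi - d * ti, pj - d * tj
                    if 0 <= si < H and 0 <= sj < W:
                        acc += f[si, sj] * r[ti + k, tj + k]
            out[pi, pj] = acc
    return out


class TestDilatedConv:
    def test_delta_kernel_is_identity(self):
        rng = np.random.default_rng(0)
        f = rng.random((12, 12))
        r = np.zeros((3, 3))
        r[1, 1] = 1.0
        for d in (1, 2, 4):
            assert np.allclose(dilated_conv2d(f, Kernel(r, d)), f)

    @pytest.mark.parametrize("d", [1, 2, 4, 8, 16])
    def test_matches_nested_sum_oracle(self, d):
        rng = np.random.default_rng(d)
        for _ in range(5):
            f = rng.standard_normal((16, 16))
            r = rng.standard_normal((3, 3))
            got = dilated_conv2d(f, Kernel(r, d))
            assert np.abs(got - nested_sum_oracle(f, r, d)).max() < 1e-5

    def test_d1_equals_ordinary_convolution(self):
        rng = np.random.default_rng(3)
        f = rng.random((16, 16))
        r = rng.random((5, 5))
        got = dilated_conv2d(f, Kernel(r, 1))
        ref = signal.convolve2d(f, r, mode="same", boundary="fill")
        assert np.allclose(got, ref, atol=1e-10)

    def test_impulse_with_dilated_averaging_kernel(self):
        f = np.zeros((11, 11))
        f[5, 5] = 1.0
        out = dilated_conv2d(f, Kernel(np.full((3, 3), 1 / 9), d=2))
        nz = np.argwhere(out > 0)
        assert len(nz) == 9
        for i in (3, 5, 7):
            for j in (3, 5, 7):
                assert out[i, j] == pytest.approx(1 / 9)

    def test_framework_layer_equals_flipped_kernel_convolution(self):
        # the learned layers use cross-correlation; flipping the kernel
        # recovers the literal convolution
        rng = np.random.default_rng(9)
        f = rng.random((16, 16)).astype(np.float32)
        r = rng.random((3, 3)).astype(np.float32)
        spec = ArchitectureSpec([LayerSpec(3, 1, 2, 2, False, False)])
        m = build_network(spec, seed=0)
        conv = m.blocks[0]
        conv.W[0, 0] = r
        conv.b[:] = 0.0
        out = m.forward(f[None, None])[0, 0]
        ref = dilated_conv2d(f.astype(np.float64), Kernel(r[::-1, ::-1].astype(np.float64), 2))
        assert np.abs(out - ref).max() < 1e-4

    def test_invalid_dilation_rejected(self):
        with pytest.raises(ValueError):
            Kernel(np.ones((3, 3)), d=0)


class TestArchitecture:
    def test_default_matches_published_stack(self):
        spec = default_architecture()
        assert len(spec.layers) == 8
        assert [l.dilation for l in spec.layers] == [1, 1, 2, 4, 8, 16, 1, 1]
        assert [l.kernel_size for l in spec.layers] == [3] * 7 + [1]
        assert spec.layers[-1].out_channels == 2
        assert not spec.layers[-1].batchnorm and not spec.layers[-1].relu
        assert all(l.batchnorm and l.relu for l in spec.layers[:-1])

    def test_channel_mismatch_rejected(self):
        spec = ArchitectureSpec(
            [LayerSpec(3, 1, 32), LayerSpec(3, 16, 2, 1, False, False)]
        )
        with pytest.raises(ValueError, match="mismatch"):
            spec.validate()

    @pytest.mark.parametrize("shape", [(64, 64), (100, 90)])
    def test_resolution_preserved(self, shape):
        m = build_network(seed=0)
        x = np.random.default_rng(0).random((1, 1, *shape)).astype(np.float32)
        assert m.forward(x).shape == (1, 2, *shape)

    def test_per_layer_shapes_never_shrink(self):
        m = build_network(seed=0)
        x = np.random.default_rng(1).random((1, 1, 48, 48)).astype(np.float32)
        h = np.ascontiguousarray(x.transpose(1, 0, 2, 3))
        from dbtseg.network import _BatchNorm

        for block in m.blocks:
            if isinstance(block, _BatchNorm):
                h = block.forward(h, train=False, cache=False)
            else:
                h = block.forward(h, cache=False)
            assert h.shape[-2:] == (48, 48)

    def test_same_seed_identical_weights(self):
        a = build_network(seed=5)
        b = build_network(seed=5)
        for (obj_a, name), (obj_b, _) in zip(a.parameters(), b.parameters()):
            assert np.array_equal(getattr(obj_a, name), getattr(obj_b, name))


class TestReceptiveField:
    def test_single_layer(self):
        spec = ArchitectureSpec([LayerSpec(3, 1, 2, 1, False, False)])
        assert receptive_field(spec) == (3, 3)

    def test_two_layers_d1_d2(self):
        spec = ArchitectureSpec(
            [LayerSpec(3, 1, 4, 1), LayerSpec(3, 4, 2, 2, False, False)]
        )
        assert receptive_field(spec) == (7, 7)

    def test_default_is_67_and_matches_gradient_footprint(self):
        spec = default_architecture()
        assert receptive_field(spec) == (67, 67)
        m = build_network(spec, seed=3)
        x = np.random.default_rng(0).random((1, 1, 128, 128)).astype(np.float32)
        y = m.forward(x, train=False, cache=True)
        d = np.zeros_like(y)
        d[0, :, 64, 64] = 1.0
        dx = m.backward(d)
        nz = np.argwhere(np.abs(dx[0, 0]) > 0)
        assert nz[:, 0].max() - nz[:, 0].min() + 1 == 67
        assert nz[:, 1].max() - nz[:, 1].min() + 1 == 67

    def test_small_stack_gradient_footprint(self):
        spec = ArchitectureSpec(
            [LayerSpec(3, 1, 4, 1), LayerSpec(3, 4, 2, 2, False, False)]
        )
        assert receptive_field(spec) == (7, 7)
        m = build_network(spec, seed=1)
        x = np.random.default_rng(2).random((1, 1, 32, 32)).astype(np.float32)
        y = m.forward(x, train=False, cache=True)
        d = np.zeros_like(y)
        d[0, :, 16, 16] = 1.0
        dx = m.backward(d)
        nz = np.argwhere(np.abs(dx[0, 0]) > 0)
        assert nz[:, 0].max() - nz[:, 0].min() + 1 == 7


class TestPrediction:
    def test_softmax_probabilities_sum_to_one(self):
        logits = np.random.default_rng(0).standard_normal((2, 2, 8, 8)).astype(np.float32)
        p = softmax_channels(logits)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_heatmap_shape_and_range(self):
        m = build_network(seed=0)
        vol = ImageVolume(np.random.default_rng(1).random((3, 100, 90)))
        hm = predict_heatmap(m, vol)
        assert hm.shape == (3, 100, 90)
        assert hm.probabilities.min() >= 0 and hm.probabilities.max() <= 1

    def test_zeroed_final_layer_gives_uniform_half(self):
        m = build_network(seed=0)
        final = m.blocks[-1]
        final.W[:] = 0.0
        final.b[:] = 0.0
        vol = ImageVolume(np.random.default_rng(2).random((1, 32, 32)))
        hm = predict_heatmap(m, vol)
        assert np.allclose(hm.probabilities, 0.5)

    def test_translation_equivariance_of_impulse(self):
        # shifting a centred impulse far from borders shifts the output
        m = build_network(seed=4)
        base = np.full((1, 1, 128, 128), 0.1, dtype=np.float32)
        a = base.copy()
        a[0, 0, 60, 60] = 1.0
        b = base.copy()
        b[0, 0, 70, 65] = 1.0
        ya = m.forward(a)[0, 1]
        yb = m.forward(b)[0, 1]
        # compare windows whose receptive fields stay clear of the border
        # (the zero padding breaks equivariance within 33 px of an edge)
        wa = ya[60 - 20 : 60 + 20, 60 - 20 : 60 + 20]
        wb = yb[70 - 20 : 70 + 20, 65 - 20 : 65 + 20]
        assert np.abs(wa - wb).max() < 1e-4

    def test_checkpoint_roundtrip(self, tmp_path):
        m = build_network(seed=7)
        vol = ImageVolume(np.random.default_rng(3).random((1, 40, 40)))
        before = predict_heatmap(m, vol).probabilities
        path = save_model(m, tmp_path / "model.npz")
        m2 = load_model(path)
        after = predict_heatmap(m2, vol).probabilities
        assert np.array_equal(before, after)
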