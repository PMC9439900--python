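import numpy as np
import pytest

from texfuse import (
    FusionInput,
    FusionNetSpec,
    add_fuse,
    build_network,
    fusion_position_shapes,
    summarize,
)
from texfuse.fusion_net import STAGE_DEPTHS, STAGE_WIDTHS

from oracles import vgg_shape_propagation

SMALL = FusionNetSpec(width_multiplier=0.0625, input_size=(32, 32))


class TestAddFuse:
    def test_additive_identity(self, rng):
        y = rng.random((3, 5, 5))
        out = add_fuse(np.zeros_like(y), y, np.ones(3))
        np.testing.assert_array_equal(out, y)

    def test_linearity_x_equals_y(self, rng):
        x = rng.random((2, 4, 4))
        np.testing.assert_allclose(add_fuse(x, x, np.ones(2)), 2 * x, atol=1e-12)

    def test_1x1_kernel_is_elementwise_scale(self, rng):
        x = rng.random((1, 3, 3))
        y = rng.random((1, 3, 3))
        w = 0.7
        np.testing.assert_allclose(
            add_fuse(x, y, np.array([[[w]]])), w * (x + y), atol=1e-12
        )

    def test_identity_sum_exact_on_integers(self, rng):
        x = rng.integers(0, 100, (4, 6, 6)).astype(float)
        y = rng.integers(0, 100, (4, 6, 6)).astype(float)
        out = add_fuse(x, y, np.ones(4))
        assert (out == x + y).all()
        assert (out == add_fuse(y, x, np.ones(4))).all()

    @pytest.mark.parametrize("channels", [1, 2, 64])
    @pytest.mark.parametrize("ksize", [1, 3])
    def test_shape_preserved(self, channels, ksize, rng):
        x = rng.random((channels, 7, 7))
        y = rng.random((channels, 7, 7))
        k = rng.random((channels, ksize, ksize))
        assert add_fuse(x, y, k).shape == x.shape

    def test_3x3_delta_kernel_equals_sum(self, rng):
        x = rng.random((2, 5, 5))
        y = rng.random((2, 5, 5))
        delta = np.zeros((2, 3, 3))
        delta[:, 1, 1] = 1.0
        np.testing.assert_allclose(add_fuse(x, y, delta), x + y, atol=1e-12)

    def test_shape_mismatch_names_both_shapes(self, rng):
        with pytest.raises(ValueError, match=r"\(2, 4, 4\).*\(2, 5, 5\)"):
            add_fuse(rng.random((2, 4, 4)), rng.random((2, 5, 5)), np.ones(2))


class TestShapes:
    def test_block3_and_block5_at_224(self):
        spec = FusionNetSpec(input_size=(224, 224))
        shapes = fusion_position_shapes(spec)
        assert shapes["block3"] == (256, 56, 56)
        assert shapes["block5"][1:] == (14, 14)
        assert shapes["input"] == (2, 224, 224)

    def test_matches_symbolic_propagation_oracle(self):
        spec = FusionNetSpec(input_size=(224, 224))
        want = vgg_shape_propagation((224, 224), STAGE_WIDTHS, STAGE_DEPTHS)
        got = fusion_position_shapes(spec)
        for k in want:
            assert got[k] == want[k]

    def test_indivisible_input_rejected(self):
        spec = FusionNetSpec(input_size=(224, 224))
        with pytest.raises(ValueError):
            fusion_position_shapes(spec, input_size=(100, 100))


class TestBuildNetwork:
    def test_forward_produces_two_vector(self, rng):
        net = build_network(SMALL, seed=0)
        logits = net.predict_logits(
            rng.random((3, 1, 32, 32)).astype(np.float32),
            rng.random((3, 2, 32, 32)).astype(np.float32),
        )
        assert logits.shape == (3, 2) and np.isfinite(logits).all()

    def test_scaled_down_parameter_count(self):
        full = build_network(FusionNetSpec(input_size=(224, 224)), seed=0)
        small = build_network(
            FusionNetSpec(width_multiplier=0.125, input_size=(64, 64)), seed=0
        )
        assert small.n_parameters < full.n_parameters / 10

    def test_fused_has_fewer_parameters_than_vgg16(self):
        # standard VGG-16: 13 convs + three-FC head (4096, 4096, 1000 classes)
        conv_params = 0
        cin = 3
        for width, depth in zip(STAGE_WIDTHS, STAGE_DEPTHS):
            for _ in range(depth):
                conv_params += cin * width * 9 + width
                cin = width
        flat = 512 * 7 * 7
        vgg16 = conv_params + (flat * 4096 + 4096) + (4096 * 4096 + 4096) + (4096 * 1000 + 1000)
        fused = build_network(FusionNetSpec(input_size=(224, 224)), seed=0)
        assert fused.n_parameters < vgg16

    def test_two_fc_head_smaller_than_three_fc_head(self):
        net = build_network(FusionNetSpec(input_size=(224, 224)), seed=0)
        head = sum(net.params[k].size for k in net.params if k.startswith(("fc", "out")))
        flat = 512 * 7 * 7
        three_fc = (flat * 4096 + 4096) + (4096 * 4096 + 4096) + (4096 * 1000 + 1000)
        assert head < three_fc

    def test_zero_texture_identity_kernels_match_depth_only(self, rng):
        net = build_network(SMALL, seed=3)
        depth = rng.random((2, 1, 32, 32)).astype(np.float32)
        zeros = np.zeros((2, 2, 32, 32), dtype=np.float32)
        np.testing.assert_allclose(
            net.predict_logits(depth, zeros), net.predict_logits(depth, None), atol=1e-5
        )

    def test_gradient_flows_into_both_branches(self, rng):
        net = build_network(SMALL, seed=1)
        depth = rng.random((4, 1, 32, 32)).astype(np.float32)
        tex = rng.random((4, 2, 32, 32)).astype(np.float32)
        labels = np.array([0, 1, 0, 1])
        _, grads = net.loss_and_grads(depth, tex, labels, rng=np.random.default_rng(0))
        bb = [k for k in grads if k.startswith("bb") and np.abs(grads[k]).max() > 0]
        tx = [k for k in grads if k.startswith("tx") and np.abs(grads[k]).max() > 0]
        assert bb and tx

    def test_parameter_count_nondecreasing_in_fusion_depth(self):
        counts = []
        for pos in ("input", "block1", "block2", "block3", "block4", "block5"):
            spec = FusionNetSpec(
                fusion_position=pos, width_multiplier=0.0625, input_size=(32, 32)
            )
            counts.append(build_network(spec, seed=0).n_parameters)
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_input_fusion_forward(self, rng):
        spec = FusionNetSpec(
            fusion_position="input", width_multiplier=0.0625, input_size=(32, 32)
        )
        net = build_network(spec, seed=0)
        logits = net.predict_logits(
            rng.random((2, 1, 32, 32)).astype(np.float32),
            rng.random((2, 2, 32, 32)).astype(np.float32),
        )
        assert logits.shape == (2, 2) and np.isfinite(logits).all()

    def test_separate_branches_mode(self, rng):
        spec = FusionNetSpec(
            width_multiplier=0.0625, input_size=(32, 32), texture_mode="separate_branches"
        )
        net = build_network(spec, seed=0)
        logits = net.predict_logits(
            rng.random((2, 1, 32, 32)).astype(np.float32),
            rng.random((2, 2, 32, 32)).astype(np.float32),
        )
        assert logits.shape == (2, 2)

    def test_share_weights_requires_matching_channels(self):
        with pytest.raises(ValueError):
            FusionNetSpec(share_weights=True, texture_channels=2, depth_channels=1)
        spec = FusionNetSpec(
            share_weights=True, texture_channels=1, depth_channels=1,
            width_multiplier=0.0625, input_size=(32, 32),
        )
        net = build_network(spec, seed=0)
        rng = np.random.default_rng(0)
        logits = net.predict_logits(
            rng.random((2, 1, 32, 32)).astype(np.float32),
            rng.random((2, 1, 32, 32)).astype(np.float32),
        )
        assert logits.shape == (2, 2)


class TestFusionInput:
    def test_mismatched_extents_rejected(self, rng):
        with pytest.raises(ValueError):
            FusionInput(rng.random((8, 8)), rng.random((2, 8, 9)))

    def test_default_texture_has_two_channels(self, rng):
        fi = FusionInput(rng.random((8, 8)), rng.random((2, 8, 8)))
        assert fi.texture_image.shape[0] == 2 and fi.depth_image.shape[0] == 1


def test_numeric_gradients_spot_check(rng):
    """Backprop agrees with central finite differences on a few coordinates."""
    spec = FusionNetSpec(width_multiplier=0.03125, input_size=(32, 32), dropout_rate=0.0)
    net = build_network(spec, seed=2)
    depth = rng.random((2, 1, 32, 32)).astype(np.float32)
    tex = rng.random((2, 2, 32, 32)).astype(np.float32)
    labels = np.array([0, 1])
    _, grads = net.loss_and_grads(depth, tex, labels)
    check = [("bb1_c0_W", (0, 0, 1, 1)), ("tx0_3_c1_W", (0, 0, 0, 0)),
             ("fuse_k", (0,)), ("fc2_W", (1, 2)), ("out_b", (1,))]
    eps = 1e-3
    for name, idx in check:
        orig = net.params[name][idx]
        net.params[name][idx] = orig + eps
        lp, _ = net.loss_and_grads(depth, tex, labels)
        net.params[name][idx] = orig - eps
        lm, _ = net.loss_and_grads(depth, tex, labels)
        net.params[name][idx] = orig
        fd = (lp - lm) / (2 * eps)
        assert grads[name][idx] == pytest.approx(fd, abs=2e-3)


def test_summarize_mentions_fusion_position():
    text = summarize(SMALL)
    assert "block3" in text and "total" in text
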