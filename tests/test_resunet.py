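"""Architecture contract: shapes, residual identity, parameter counts."""

import numpy as np
import pytest

from ascites_resunet import (
    ModelConfig,
    ResidualUNetSegmenter,
    build_model,
    count_parameters,
    layer_shapes,
    realized_layer_shapes,
)
from ascites_resunet.nn.layers import Conv2D
from ascites_resunet.nn.loss import loss_and_grad_from_logits

# the published shape table for the default 4-block / 2-conv / base-32
# network at 256 x 256 x 3
REFERENCE_SHAPES = {
    "input": (256, 256, 3),
    "encoder/residual_block_1/conv_1": (256, 256, 32),
    "encoder/residual_block_1/conv_2": (256, 256, 32),
    "encoder/residual_block_2/conv_1": (128, 128, 64),
    "encoder/residual_block_2/conv_2": (128, 128, 64),
    "encoder/residual_block_3/conv_1": (64, 64, 128),
    "encoder/residual_block_3/conv_2": (64, 64, 128),
    "encoder/residual_block_4/conv_1": (32, 32, 256),
    "encoder/residual_block_4/conv_2": (32, 32, 256),
    "bridge/residual_block_5/conv_1": (16, 16, 512),
    "bridge/residual_block_5/conv_2": (16, 16, 512),
    "decoder/residual_block_6/conv_1": (32, 32, 256),
    "decoder/residual_block_6/conv_2": (32, 32, 256),
    "decoder/residual_block_7/conv_1": (64, 64, 128),
    "decoder/residual_block_7/conv_2": (64, 64, 128),
    "decoder/residual_block_8/conv_1": (128, 128, 64),
    "decoder/residual_block_8/conv_2": (128, 128, 64),
    "decoder/residual_block_9/conv_1": (256, 256, 32),
    "decoder/residual_block_9/conv_2": (256, 256, 32),
    "output/conv_1x1": (256, 256, 1),
    "output/sigmoid": (256, 256, 1),
}


class TestLayerShapes:
    def test_default_config_matches_reference_table(self):
        shapes = {s.name: s.output for s in layer_shapes(ModelConfig())}
        assert shapes == REFERENCE_SHAPES

    def test_depth_two_bridge(self):
        cfg = ModelConfig(n_blocks=2)
        shapes = {s.name: s.output for s in layer_shapes(cfg)}
        assert shapes["bridge/residual_block_3/conv_1"] == (64, 64, 128)

    def test_unet_symmetry(self):
        """Mirror encoder/decoder levels share a spatial size (the
        precondition for channel concatenation)."""
        for n_blocks in (2, 3, 4, 5):
            cfg = ModelConfig(n_blocks=n_blocks, input_size=256 if n_blocks < 5 else 256)
            shapes = {s.name: s.output for s in layer_shapes(cfg)}
            for i in range(1, n_blocks + 1):
                enc = shapes[f"encoder/residual_block_{i}/conv_1"]
                dec = shapes[f"decoder/residual_block_{2 * n_blocks + 2 - i}/conv_1"]
                assert enc == dec

    @pytest.mark.parametrize("n_blocks,convs", [(2, 2), (3, 3), (4, 4), (2, 4), (5, 2)])
    def test_realized_shapes_equal_declared(self, n_blocks, convs):
        cfg = ModelConfig(
            n_blocks=n_blocks, convs_per_block=convs, base_filters=4,
            input_size=32, seed=0,
        )
        declared = {s.name: s.output for s in layer_shapes(cfg) if "conv" in s.name}
        realized = realized_layer_shapes(build_model(cfg))
        for name, shape in declared.items():
            assert realized[name] == shape

    def test_invalid_configs_list_supported_values(self):
        with pytest.raises(ValueError, match="allowed"):
            ModelConfig(n_blocks=6)
        with pytest.raises(ValueError, match="allowed"):
            ModelConfig(convs_per_block=1)
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(n_blocks=4, input_size=100)


class TestBuildModel:
    def test_seeded_builds_are_identical(self):
        cfg = ModelConfig(n_blocks=2, base_filters=4, input_size=16, seed=9)
        a, b = build_model(cfg), build_model(cfg)
        for (na, wa, _), (nb, wb, _) in zip(a.named_params(), b.named_params()):
            assert na == nb
            np.testing.assert_array_equal(wa, wb)

    def test_stride_placement(self):
        """Encoder blocks 2+ stride only in their first conv; decoder convs
        are all stride 1."""
        net = build_model(ModelConfig(n_blocks=3, base_filters=4, input_size=32))
        for i, blk in enumerate(net.encoder):
            strides = [conv.stride for _, _, conv in blk.units]
            assert strides == ([1] * len(strides) if i == 0 else [2] + [1] * (len(strides) - 1))
        assert [c.stride for _, _, c in net.bridge.units][0] == 2
        for dec in net.decoder:
            assert all(c.stride == 1 for _, _, c in dec.res.units)

    def test_residual_identity_with_zeroed_convs(self):
        """With all main-path conv weights at zero and BN neutral, a block
        reduces to its shortcut path."""
        net = build_model(ModelConfig(n_blocks=2, base_filters=4, input_size=16, seed=0))
        blk = net.encoder[0]
        for _, _, conv in blk.units:
            conv.W[:] = 0.0
            conv.b[:] = 0.0
        x = np.random.default_rng(0).normal(size=(3, 2, 16, 16)).astype(np.float32)
        out = blk.forward(x, training=False)
        expected = blk.shortcut.forward(x, training=False)
        np.testing.assert_allclose(out, expected, atol=1e-6)

    def test_sigmoid_output_range_and_shape(self):
        net = build_model(ModelConfig(n_blocks=2, base_filters=4, input_size=16, seed=1))
        x = np.random.default_rng(1).uniform(0, 1, (2, 16, 16, 3)).astype(np.float32)
        p = net.predict_proba(x)
        assert p.shape == (2, 16, 16)
        assert p.min() > 0.0 and p.max() < 1.0

    def test_inference_is_deterministic(self):
        net = build_model(ModelConfig(n_blocks=2, base_filters=4, input_size=16, seed=1))
        x = np.random.default_rng(2).uniform(0, 1, (2, 16, 16, 3)).astype(np.float32)
        np.testing.assert_array_equal(net.predict_proba(x), net.predict_proba(x))

    def test_wrong_input_size_rejected(self):
        net = build_model(ModelConfig(n_blocks=2, base_filters=4, input_size=16))
        with pytest.raises(ValueError):
            net.forward_logits(np.zeros((1, 32, 32, 3), dtype=np.float32))


class TestCountParameters:
    def test_single_conv_closed_form(self):
        """A 3x3 conv, 3 -> 32 channels with bias: 3*3*3*32 + 32 = 896."""
        conv = Conv2D("c", 3, 32, 3, 1, np.random.default_rng(0))
        n = sum(arr.size for _, arr, _ in conv.named_params())
        assert n == 896

    def test_monotone_in_base_filters(self):
        small = count_parameters(build_model(ModelConfig(n_blocks=2, base_filters=4, input_size=16)))
        large = count_parameters(build_model(ModelConfig(n_blocks=2, base_filters=8, input_size=16)))
        assert large[0] > small[0]

    def test_invariant_to_seed(self):
        a = count_parameters(build_model(ModelConfig(n_blocks=2, base_filters=4, input_size=16, seed=1)))
        b = count_parameters(build_model(ModelConfig(n_blocks=2, base_filters=4, input_size=16, seed=2)))
        assert a == b


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients agree with central differences on sampled
        weights (conv biases feeding BN have true gradient ~0 and are
        checked with an absolute floor)."""
        cfg = ModelConfig(n_blocks=2, convs_per_block=2, base_filters=4, input_size=16, seed=1)
        net = build_model(cfg)
        rng = np.random.default_rng(0)
        X = rng.random((2, 16, 16, 3)).astype(np.float32)
        y = (rng.random((2, 16, 16)) > 0.7).astype(np.float32)

        def loss_of():
            z = net.forward_logits(X, training=True)
            return loss_and_grad_from_logits(z, y)[0]

        z = net.forward_logits(X, training=True)
        *_, dz = loss_and_grad_from_logits(z, y)
        net.backward(dz)
        grads = {n: g().copy() for n, _, g in net.named_params()}
        params = {n: a for n, a, _ in net.named_params()}
        for name in ["encoder/residual_block_1/conv_1.W", "encoder/residual_block_2/shortcut.W",
                     "bridge/residual_block_3/bn_1.gamma", "output/conv_1x1.W",
                     "output/conv_1x1.b", "decoder/residual_block_4/shortcut.W",
                     "decoder/residual_block_5/bn_2.beta"]:
            flat = params[name].reshape(-1)
            g = grads[name].reshape(-1)
            for k in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                old = flat[k]
                flat[k] = old + 1e-3
                lp = loss_of()
                flat[k] = old - 1e-3
                lm = loss_of()
                flat[k] = old
                num = (lp - lm) / 2e-3
                assert abs(num - g[k]) < 0.05 * max(abs(num), abs(g[k])) + 3e-4, name


class TestEstimator:
    def test_sklearn_protocol(self):
        est = ResidualUNetSegmenter(n_blocks=2, base_filters=4, input_size=16)
        params = est.get_params()
        assert params["n_blocks"] == 2
        est.set_params(max_epochs=1)
        assert est.max_epochs == 1
        with pytest.raises(RuntimeError):
            est.predict_proba(np.zeros((1, 16, 16, 3), dtype=np.float32))

    def test_fit_predict_score(self, tiny_training_arrays):
        X, y, labels = tiny_training_arrays
        est = ResidualUNetSegmenter(
            n_blocks=2, base_filters=4, input_size=16, max_epochs=3, random_state=0
        )
        est.fit(X, y)
        assert est.n_epochs_ == 3
        assert len(est.loss_curve_) == 3
        p = est.predict_proba(X)
        assert p.shape == y.shape
        masks = est.predict(X)
        assert set(np.unique(masks)) <= {0, 1}
        assert 0.0 <= est.score(X, y) <= 1.0

    def test_input_validation(self):
        est = ResidualUNetSegmenter(n_blocks=2, base_filters=4)
        with pytest.raises(ValueError):
            est.fit(np.zeros((2, 16, 16, 1)), np.zeros((2, 16, 16)))
        with pytest.raises(ValueError):
            est.fit(np.full((2, 16, 16, 3), 2.0), np.zeros((2, 16, 16)))
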