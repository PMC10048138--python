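"""Residual/bottleneck block contracts, backbone taps, DSC cost accounting."""

import numpy as np
import pytest

from myinet.backbones import (BottleneckResidualBlock, DepthwiseSeparableConv,
                              InvertedResidual, ModelSpec, ResidualBlock,
                              build_backbone, build_mobilenetv2, build_resnet,
                              dsc_cost)
from myinet.nn import Tensor


def zero_branch(module):
    """Zero every convolution weight and batch-norm scale/shift in a module's
    transform branch so it computes the zero function."""
    for _, p in module.named_parameters():
        p.data[...] = 0.0
    for name, b in module.named_buffers():
        if name.endswith("running_mean"):
            b[...] = 0.0
        if name.endswith("running_var"):
            b[...] = 1.0


class TestResidualBlock:
    def test_zeroed_transform_branch_is_identity_on_nonneg_input(self, rng):
        block = ResidualBlock(4, 4, rng, stride=1)
        for attr in ("conv1", "bn1", "conv2", "bn2"):
            zero_branch(getattr(block, attr))
        block.eval()
        x = np.abs(rng.standard_normal((1, 4, 8, 8)))
        out = block(Tensor(x))
        np.testing.assert_allclose(out.data, x, atol=1e-12)

    def test_stride_two_halves_spatial_size(self, rng):
        block = ResidualBlock(4, 8, rng, stride=2)
        block.eval()
        out = block(Tensor(rng.standard_normal((1, 4, 8, 8))))
        assert out.data.shape == (1, 8, 4, 4)

    def test_dropping_shortcut_reduces_to_plain_cascade(self, rng):
        # the residual map is H(x) + x; the conventional cascade is H(x)
        block = ResidualBlock(4, 4, rng, stride=1)
        block.eval()
        x = rng.standard_normal((1, 4, 8, 8))
        from myinet.nn import functional as F

        h = block.bn2(block.conv2(F.relu(block.bn1(block.conv1(Tensor(x))))))
        plain = F.relu(h).data
        residual = block(Tensor(x)).data
        np.testing.assert_allclose(
            residual, np.maximum(h.data + x, 0.0), atol=1e-12)
        assert not np.allclose(plain, residual)


class TestBottleneckBlocks:
    def test_resnet_bottleneck_zeroed_branch_is_identity(self, rng):
        block = BottleneckResidualBlock(8, 2, rng, stride=1)  # out = 2*4 = 8
        for attr in ("conv1", "bn1", "conv2", "bn2", "conv3", "bn3"):
            zero_branch(getattr(block, attr))
        block.eval()
        x = np.abs(rng.standard_normal((1, 8, 6, 6)))
        np.testing.assert_allclose(block(Tensor(x)).data, x, atol=1e-12)

    def test_inverted_residual_zero_branch_identity_at_stride_one(self, rng):
        block = InvertedResidual(6, 6, rng, stride=1)
        zero_branch(block.body)
        block.eval()
        x = rng.standard_normal((1, 6, 8, 8))
        np.testing.assert_allclose(block(Tensor(x)).data, x, atol=1e-12)

    def test_inverted_residual_stride_two_halves_and_drops_skip(self, rng):
        block = InvertedResidual(6, 6, rng, stride=2)
        assert not block.use_skip
        block.eval()
        out = block(Tensor(rng.standard_normal((1, 6, 8, 8))))
        assert out.data.shape == (1, 6, 4, 4)

    def test_linear_projection_emits_negative_values(self, rng):
        block = InvertedResidual(6, 8, rng, stride=1)  # no skip: 6 != 8
        block.eval()
        out = block(Tensor(rng.standard_normal((2, 6, 8, 8))))
        assert (out.data < 0).any()

    def test_invalid_stride_rejected(self, rng):
        with pytest.raises(ValueError):
            InvertedResidual(4, 4, rng, stride=3)


class TestDscCost:
    def test_worked_arithmetic_kernel_corrected(self):
        assert dsc_cost(32, 64, 14, 3) == 56_448 + 401_408

    def test_unit_case_of_printed_form(self):
        assert dsc_cost(1, 1, 1, 1) == 2

    def test_width_multiplier_scales_terms_linearly_and_quadratically(self):
        full = dsc_cost(32, 64, 14, 1)
        half = dsc_cost(32, 64, 14, 1, epsilon=0.5)
        # first term (depthwise) halves, second (pointwise) quarters
        d_full, p_full = 32 * 196, 32 * 64 * 196
        assert full == d_full + p_full
        assert half == d_full / 2 + p_full / 4

    def test_instrumented_multiply_count_matches_formula(self, rng):
        for d_i, d_o, d_f in ((4, 8, 8), (3, 5, 6), (8, 8, 4)):
            layer = DepthwiseSeparableConv(d_i, d_o, rng)
            assert layer.multiply_count(d_f) == dsc_cost(d_i, d_o, d_f, 3)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            dsc_cost(0, 1, 1, 1)
        with pytest.raises(ValueError):
            dsc_cost(1, 1, 1, 1, epsilon=1.5)


class TestDepthwiseSeparableConv:
    def test_pointwise_identity_passes_depthwise_through(self, rng):
        layer = DepthwiseSeparableConv(1, 1, rng)
        layer.eval()
        # make the pointwise stage the identity scalar
        pw_conv = layer.pointwise.layers[0]
        pw_conv.weight.data[...] = 1.0
        x = np.abs(rng.standard_normal((1, 1, 8, 8)))
        depthwise_only = layer.depthwise(Tensor(x)).data
        # fresh normalisation statistics perturb values by ~eps/2 relatively
        np.testing.assert_allclose(layer(Tensor(x)).data,
                                   np.maximum(depthwise_only, 0.0), rtol=1e-4)

    def test_spatial_size_preserved(self, rng):
        layer = DepthwiseSeparableConv(3, 7, rng)
        layer.eval()
        out = layer(Tensor(rng.standard_normal((1, 3, 10, 10))))
        assert out.data.shape == (1, 7, 10, 10)


class TestBackboneAssembly:
    @pytest.mark.parametrize("backbone,size,low,high", [
        ("mi-resnet18", 64, 16, 4),
        ("mi-resnet18", 128, 32, 8),
        ("mi-resnet18", 256, 64, 16),
        ("mi-mobilenetv2", 256, 64, 16),
    ])
    def test_output_stride_contract(self, backbone, size, low, high):
        width = 0.25 if size <= 128 else 1.0
        spec = ModelSpec(backbone=backbone, width_multiplier=width)
        bb = build_backbone(spec, seed=0)
        bb.eval()
        lo, hi = bb(np.zeros((1, 1, size, size)))
        assert lo.data.shape[-2:] == (low, low)
        assert hi.data.shape[-2:] == (high, high)

    def test_parameter_count_ordering(self):
        counts = {}
        for name in ("mi-mobilenetv2", "mi-resnet18", "mi-resnet50"):
            bb = build_backbone(ModelSpec(backbone=name), seed=0)
            counts[name] = bb.n_parameters()
        assert (counts["mi-mobilenetv2"] < counts["mi-resnet18"]
                < counts["mi-resnet50"])

    def test_mobilenet_width_multiplier_thins_every_stage(self):
        full = build_mobilenetv2(ModelSpec(backbone="mi-mobilenetv2"), 0)
        half = build_mobilenetv2(
            ModelSpec(backbone="mi-mobilenetv2", width_multiplier=0.5), 0)
        assert half.low_level_channels == max(1, round(full.low_level_channels / 2))
        assert half.high_level_channels == max(1, round(full.high_level_channels / 2))

    def test_resolution_multiplier_shrinks_consumed_input(self):
        spec = ModelSpec(backbone="mi-mobilenetv2", resolution_multiplier=0.5,
                         width_multiplier=0.25)
        bb = build_mobilenetv2(spec, 0)
        assert bb.consumed_size(256, 256) == (128, 128)
        bb.eval()
        lo, hi = bb(np.zeros((1, 1, 256, 256)))
        assert lo.data.shape[-2:] == (32, 32)  # 128 / 4
        assert hi.data.shape[-2:] == (8, 8)    # 128 / 16

    def test_wrong_builder_for_backbone_rejected(self):
        with pytest.raises(ValueError):
            build_resnet(ModelSpec(backbone="mi-mobilenetv2"))
        with pytest.raises(ValueError):
            build_mobilenetv2(ModelSpec(backbone="mi-resnet18"))

    def test_forward_determinism(self, rng):
        spec = ModelSpec(backbone="mi-resnet18", width_multiplier=0.25)
        bb = build_backbone(spec, seed=3)
        bb.eval()
        x = rng.standard_normal((1, 1, 64, 64))
        lo1, hi1 = bb(x)
        lo2, hi2 = bb(x)
        np.testing.assert_array_equal(lo1.data, lo2.data)
        np.testing.assert_array_equal(hi1.data, hi2.data)

    def test_invalid_multiplier_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(backbone="mi-mobilenetv2", width_multiplier=0.0)
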