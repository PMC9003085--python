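"""Architecture contracts: encoders, pyramid block, alignment, attention
fusion, decoder, and the full forward pass."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from macn.macn_model import (MACN, ModelConfig, attention_fuse,
                             central_crop_align, load_checkpoint, preprocess,
                             save_checkpoint)
from macn.nn import Tensor


def _inputs(config, rng, batch=1):
    s = config.input_size
    return (rng.normal(size=(batch, 3, s, s)).astype(np.float32),
            rng.normal(size=(batch, 3, s, s)).astype(np.float32))


class TestEncode:
    def test_feature_map_downsample_factors(self, tiny_config, rng):
        model = MACN(tiny_config)
        x, _ = _inputs(tiny_config, rng)
        low_level, bottleneck = model.encode(x, "high")
        s = tiny_config.input_size
        assert low_level.shape[2:] == (s // 4, s // 4)
        assert bottleneck.shape[2:] == (s // tiny_config.output_stride,) * 2

    def test_output_stride_eight_keeps_finer_bottleneck(self, rng):
        cfg = ModelConfig(backbone_width_multiplier=0.25, input_size=64,
                          output_stride=8)
        model = MACN(cfg)
        x, _ = _inputs(cfg, rng)
        _, bottleneck = model.encode(x, "low")
        assert bottleneck.shape[2:] == (8, 8)

    def test_branches_have_independent_parameters(self, tiny_config, rng):
        model = MACN(tiny_config)
        x, _ = _inputs(tiny_config, rng)
        _, hi = model.encode(x, "high")
        _, lo = model.encode(x, "low")
        assert not np.allclose(hi.data, lo.data)

    def test_zero_input_bias_free_gives_zero_bottleneck(self, tiny_config):
        model = MACN(replace(tiny_config, bias_free=True))
        model.eval()
        zeros = np.zeros((1, 3, 64, 64), dtype=np.float32)
        _, bottleneck = model.encode(zeros, "high")
        np.testing.assert_allclose(bottleneck.data, 0.0, atol=1e-7)

    def test_strict_mode_rejects_wrong_size(self, tiny_config, rng):
        model = MACN(tiny_config)
        with pytest.raises(ValueError, match="expected"):
            model.encode(rng.normal(size=(1, 3, 32, 32)).astype(np.float32),
                         "high")


class TestPyramidBlock:
    def test_preserves_spatial_dims(self, tiny_config, rng):
        model = MACN(tiny_config)
        x, _ = _inputs(tiny_config, rng)
        _, bottleneck = model.encode(x, "high")
        out = model.dense_aspp(bottleneck, "high")
        assert out.shape[2:] == bottleneck.shape[2:]

    def test_mode_none_is_identity(self, rng):
        cfg = ModelConfig(backbone_width_multiplier=0.25, input_size=64,
                          aspp_mode="none")
        model = MACN(cfg)
        x = Tensor(rng.normal(size=(1, 32, 4, 4)).astype(np.float32))
        out = model.dense_aspp(x, "high")
        np.testing.assert_array_equal(out.data, x.data)

    def test_oversized_dilation_rates_clamped_with_warning(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="macn.macn_model"):
            MACN(ModelConfig(backbone_width_multiplier=0.25, input_size=64))
        assert "clamped" in caplog.text

    def test_receptive_field_exceeds_single_3x3_conv(self, rng):
        """Gradient support of one output pixel must reach beyond ±1."""
        cfg = ModelConfig(backbone_width_multiplier=0.25, input_size=256)
        model = MACN(cfg)  # bottleneck 16x16, rates (3,6,12,15,15)
        x = Tensor(rng.normal(size=(1, 32, 16, 16)).astype(np.float32),
                   requires_grad=True)
        out = model.dense_aspp(x, "high")
        g = np.zeros_like(out.data)
        g[0, :, 8, 8] = 1.0  # probe every channel: single units can be ReLU-dead
        out.backward(g)
        support = np.abs(x.grad).sum(axis=(0, 1)) > 1e-12
        rows = np.where(support.any(axis=1))[0]
        assert rows.max() - rows.min() + 1 > 3


class TestCentralCropAlign:
    def test_constant_map_preserved(self):
        const = np.full((1, 2, 16, 16), 3.25, dtype=np.float32)
        out = central_crop_align(const, 2)
        np.testing.assert_allclose(out.data, 3.25, atol=1e-6)
        assert out.shape == (1, 2, 16, 16)

    def test_crop_indices_match_quarter_arithmetic(self):
        # 32x32, ratio 2: the crop is rows/cols [8, 24)
        m = np.zeros((1, 1, 32, 32), dtype=np.float32)
        m[0, 0, 8:24, 8:24] = 1.0
        out = central_crop_align(m, 2)
        np.testing.assert_allclose(out.data, 1.0, atol=1e-6)

    def test_impulse_moves_to_corner(self):
        m = np.zeros((1, 1, 32, 32), dtype=np.float32)
        m[0, 0, 8, 8] = 1.0
        out = central_crop_align(m, 2).data[0, 0]
        assert out.sum() > 0
        # all energy concentrated near the (0,0) corner
        assert out[:4, :4].sum() == pytest.approx(out.sum(), rel=1e-5)

    def test_odd_size_rejected(self):
        with pytest.raises(ValueError, match="not divisible"):
            central_crop_align(np.zeros((1, 1, 15, 15), dtype=np.float32), 2)


class TestAttentionFuse:
    def test_zero_gate_input_gives_exactly_1_5_high(self, rng):
        h = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
        out = attention_fuse(h, np.zeros_like(h))
        np.testing.assert_allclose(out.fused.data, 1.5 * h, rtol=1e-6)
        np.testing.assert_allclose(out.gate.data, 0.5)

    def test_saturated_gate_doubles_high(self, rng):
        h = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
        out = attention_fuse(h, np.full_like(h, 20.0))
        np.testing.assert_allclose(out.fused.data, 2.0 * h, atol=1e-6)

    def test_zero_high_gives_zero_fused(self, rng):
        low = rng.normal(size=(1, 4, 8, 8)).astype(np.float32)
        out = attention_fuse(np.zeros_like(low), low)
        np.testing.assert_allclose(out.fused.data, 0.0)

    def test_fusion_algebra_fused_minus_high_is_gate_times_high(self, rng):
        h = rng.normal(size=(2, 3, 4, 4)).astype(np.float32)
        low = rng.normal(size=(2, 3, 4, 4)).astype(np.float32)
        out = attention_fuse(h, low)
        np.testing.assert_allclose(out.fused.data - h, out.gate.data * h,
                                   atol=1e-6)

    @settings(max_examples=30, deadline=None, database=None)
    @given(st.integers(0, 2**32 - 1))
    def test_gating_bounds_for_nonnegative_high(self, seed):
        r = np.random.default_rng(seed)
        h = np.abs(r.normal(size=(1, 3, 6, 6))).astype(np.float32)
        low = (r.normal(size=(1, 3, 6, 6)) * 10).astype(np.float32)
        fused = attention_fuse(h, low).fused.data
        assert (fused >= h - 1e-6).all()
        assert (fused <= 2 * h + 1e-6).all()

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            attention_fuse(np.zeros((1, 2, 4, 4), np.float32),
                           np.zeros((1, 2, 8, 8), np.float32))


class TestDecoderAndForward:
    def test_logits_are_full_resolution(self, tiny_config, rng):
        model = MACN(tiny_config)
        hi, lo = _inputs(tiny_config, rng)
        logits = model.forward_logits(hi, lo)
        s = tiny_config.input_size
        assert logits.shape == (1, 2, s, s)

    def test_decoder_off_has_fewer_parameters(self, tiny_config):
        with_dec = MACN(tiny_config)
        without = MACN(replace(tiny_config, decoder_enabled=False))
        assert len(without.parameters()) < len(with_dec.parameters())

    def test_zeroed_skip_projection_ignores_low_level_content(self,
                                                              tiny_config, rng):
        model = MACN(tiny_config)
        model.eval()
        model.head.proj.conv.weight.data[:] = 0.0
        hi, lo = _inputs(tiny_config, rng)
        skip_a, bottleneck = model.encode(hi, "high")
        fused = model.dense_aspp(bottleneck, "high")
        out_a = model.head(fused, skip_a)
        skip_b = Tensor(rng.normal(size=skip_a.shape).astype(np.float32))
        out_b = model.head(fused, skip_b)
        np.testing.assert_allclose(out_a.data, out_b.data, atol=1e-5)

    def test_probabilities_sum_to_one_and_eval_deterministic(self,
                                                             tiny_config, rng):
        model = MACN(tiny_config)
        model.eval()
        hi, lo = _inputs(tiny_config, rng)
        p1 = model.forward(hi, lo)
        p2 = model.forward(hi, lo)
        np.testing.assert_allclose(p1.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_array_equal(p1, p2)

    def test_concatenation_fusion_matches_shapes(self, tiny_config, rng):
        model = MACN(replace(tiny_config, fusion_mode="concatenation"))
        hi, lo = _inputs(tiny_config, rng)
        logits = model.forward_logits(hi, lo)
        assert logits.shape[2:] == (64, 64)

    def test_zero_high_branch_bias_free_gives_uniform_probabilities(self,
                                                                    tiny_config,
                                                                    rng):
        model = MACN(replace(tiny_config, bias_free=True))
        model.eval()
        _, lo = _inputs(tiny_config, rng)
        zeros = np.zeros_like(lo)
        probs = model.forward(zeros, lo)
        np.testing.assert_allclose(probs, 0.5, atol=1e-6)

    def test_preprocess_range_and_layout(self):
        patch = np.full((8, 8, 3), 255, dtype=np.uint8)
        x = preprocess(patch)
        assert x.shape == (1, 3, 8, 8)
        np.testing.assert_allclose(x, 1.0)
        np.testing.assert_allclose(preprocess(np.zeros((8, 8, 3), np.uint8)),
                                   -1.0)


def test_checkpoint_roundtrip_preserves_outputs(tiny_config, rng, tmp_path):
    model = MACN(tiny_config)
    model.eval()
    hi, lo = _inputs(tiny_config, rng)
    before = model.forward(hi, lo)
    save_checkpoint(model, tmp_path / "ckpt.npz")
    restored = load_checkpoint(tmp_path / "ckpt.npz")
    restored.eval()
    after = restored.forward(hi, lo)
    np.testing.assert_array_equal(before, after)
    assert restored.config == model.config


def test_checkpoint_rejects_mismatched_state(tiny_config, tmp_path, rng):
    model = MACN(tiny_config)
    save_checkpoint(model, tmp_path / "ckpt.npz")
    other = MACN(replace(tiny_config, backbone_width_multiplier=0.5))
    with pytest.raises((KeyError, ValueError)):
        other.load_state_dict(dict(np.load(tmp_path / "ckpt.npz")))


def test_config_validation_rejects_bad_values():
    with pytest.raises(ValueError):
        ModelConfig(output_stride=12)
    with pytest.raises(ValueError):
        ModelConfig(fusion_mode="sum")
    with pytest.raises(ValueError):
        ModelConfig(magnification_ratio=3)
    with pytest.raises(ValueError):
        ModelConfig(backbone="resnet101")
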