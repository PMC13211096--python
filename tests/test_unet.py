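"""Decoder components: attention gating, VGC bottleneck, UpBlocks, heads,
and the parameter/MAC accounting."""

import numpy as np
import pytest
from scipy.ndimage import correlate

from weedseg.autodiff import Tensor, no_grad
from weedseg.unet import (ConvBlock, DecoderConfig, Excitation, SpatialAttention,
                          UpBlock, VGCBlock, build_model, count_macs,
                          count_params, masked_global_pool)

RNG = np.random.default_rng


class TestSpatialAttention:
    def test_zero_gate_halves_features(self, rng):
        sa = SpatialAttention(3, rng)
        sa.gate.weight.data[:] = 0.0
        x = Tensor(rng.normal(0, 1, (1, 3, 4, 4)).astype(np.float32))
        np.testing.assert_allclose(sa(x).data, 0.5 * x.data, rtol=1e-6)

    def test_saturated_gate_passes_features_through(self, rng):
        sa = SpatialAttention(3, rng)
        sa.gate.weight.data[:] = 0.0
        sa.gate.bias.data[:] = 50.0  # sigmoid -> 1
        x = Tensor(rng.normal(0, 1, (1, 3, 4, 4)).astype(np.float32))
        np.testing.assert_allclose(sa(x).data, x.data, rtol=1e-5)

    def test_hand_computed_single_channel_gate(self):
        sa = SpatialAttention(1, RNG(0))
        sa.gate.weight.data[:] = 2.0
        sa.gate.bias.data[:] = -1.0
        x = np.array([[[[0.5, -1.0], [2.0, 0.0]]]], dtype=np.float32)
        w = 1.0 / (1.0 + np.exp(-(2.0 * x - 1.0)))
        np.testing.assert_allclose(sa(Tensor(x)).data, x * w, rtol=1e-6)

    def test_never_amplifies(self, rng):
        sa = SpatialAttention(4, rng)
        x = Tensor(rng.normal(0, 2, (2, 4, 8, 8)).astype(np.float32))
        assert (np.abs(sa(x).data) <= np.abs(x.data) + 1e-7).all()


class TestMaskedGlobalPool:
    def test_constant_feature_gives_the_constant(self, rng):
        f = np.zeros((1, 3, 4, 4), np.float32)
        for c, val in enumerate((1.5, -2.0, 0.25)):
            f[0, c] = val
        v = Tensor(rng.uniform(0.2, 1.0, (1, 1, 4, 4)).astype(np.float32))
        w = masked_global_pool(Tensor(f), v)
        np.testing.assert_allclose(w.data[0], [1.5, -2.0, 0.25], rtol=1e-4)

    def test_uniform_v_reduces_to_global_average(self, rng):
        f = Tensor(rng.normal(0, 1, (1, 5, 6, 6)).astype(np.float32))
        v = Tensor(np.ones((1, 1, 6, 6), np.float32))
        w = masked_global_pool(f, v)
        np.testing.assert_allclose(w.data[0], f.data.mean(axis=(2, 3))[0], rtol=1e-4)

    def test_hand_weighted_sum(self):
        f = Tensor(np.array([[[[1.0, 2.0], [3.0, 4.0]]]], dtype=np.float32))
        v = Tensor(np.array([[[[1.0, 0.0], [0.0, 1.0]]]], dtype=np.float32))
        w = masked_global_pool(f, v, epsilon=1e-6)
        np.testing.assert_allclose(w.data, [[2.5]], rtol=1e-5)


class TestExcitation:
    def test_zero_weights_give_half_gate(self, rng):
        ex = Excitation(4, 4, rng)
        ex.fc1.weight.data[:] = 0.0
        ex.fc2.weight.data[:] = 0.0
        g = ex(Tensor(rng.normal(0, 1, (1, 4)).astype(np.float32)))
        np.testing.assert_allclose(g.data, 0.5, rtol=1e-6)

    def test_hand_computed_two_layer_result(self):
        ex = Excitation(4, 4, RNG(0))
        w1 = np.array([[0.5], [-1.0], [0.25], [2.0]], np.float32)   # (4 -> 1)
        w2 = np.array([[1.0, -0.5, 2.0, 0.0]], np.float32)          # (1 -> 4)
        ex.fc1.weight.data = w1
        ex.fc1.bias.data[:] = 0.1
        ex.fc2.weight.data = w2
        ex.fc2.bias.data[:] = -0.2
        w_in = np.array([[1.0, -1.0, 2.0, 0.5]], np.float32)
        hidden = max((w_in @ w1).item() + 0.1, 0.0)
        expected = 1.0 / (1.0 + np.exp(-(hidden * w2[0] - 0.2)))
        np.testing.assert_allclose(ex(Tensor(w_in)).data[0], expected, rtol=1e-5)

    def test_gate_strictly_inside_unit_interval(self, rng):
        ex = Excitation(8, 4, rng)
        g = ex(Tensor(rng.normal(0, 2, (3, 8)).astype(np.float32))).data
        assert ((g > 0) & (g < 1)).all()

    def test_indivisible_reduction_rejected(self, rng):
        with pytest.raises(ValueError):
            Excitation(6, 4, rng)


class TestVGCBlock:
    def test_composition_matches_step_by_step_oracle(self, rng):
        vgc = VGCBlock(6, 8, 4, 1e-6, rng)
        x = Tensor(rng.normal(0, 1, (2, 6, 4, 4)).astype(np.float32))
        out, v = vgc(x)
        # recompute with the block's own layers composed explicitly
        with no_grad():
            v2 = vgc.v_conv(x).sigmoid()
            f = vgc.block(x)
            w = masked_global_pool(f, v2, 1e-6)
            g = vgc.excitation(w)
            expected = f.data * g.data[:, :, None, None]
        np.testing.assert_array_equal(v.data, v2.data)
        np.testing.assert_allclose(out.data, expected, rtol=1e-6)

    def test_channelwise_gating_isolation(self, rng):
        # output channel c is F channel c scaled by a factor in (0, 1)
        vgc = VGCBlock(4, 8, 4, 1e-6, rng)
        x = Tensor(rng.normal(0, 1, (1, 4, 4, 4)).astype(np.float32))
        out, _ = vgc(x)
        with no_grad():
            f = vgc.block(x).data
        for c in range(8):
            nz = np.abs(f[0, c]) > 1e-6
            if nz.any():
                ratios = out.data[0, c][nz] / f[0, c][nz]
                assert np.allclose(ratios, ratios.flat[0], rtol=1e-4)
                assert 0.0 < ratios.flat[0] < 1.0


class TestUpBlock:
    def test_output_extent_and_channels(self, rng):
        ub = UpBlock(8, 4, 6, rng)
        below = Tensor(rng.normal(0, 1, (1, 8, 4, 4)).astype(np.float32))
        skip = Tensor(rng.normal(0, 1, (1, 4, 8, 8)).astype(np.float32))
        assert ub(below, skip).shape == (1, 6, 8, 8)

    def test_extent_mismatch_rejected(self, rng):
        ub = UpBlock(8, 4, 6, rng)
        below = Tensor(np.zeros((1, 8, 4, 4), np.float32))
        skip = Tensor(np.zeros((1, 4, 9, 9), np.float32))
        with pytest.raises(ValueError, match="twice"):
            ub(below, skip)

    def test_constant_inputs_give_spatially_constant_output(self, rng):
        # bilinear preserves constants; convolutions of constants are constant
        # away from the zero-padded border
        ub = UpBlock(3, 2, 4, rng)
        below = Tensor(np.full((1, 3, 4, 4), 0.7, np.float32))
        skip = Tensor(np.full((1, 2, 8, 8), -0.3, np.float32))
        out = ub(below, skip).data[0, :, 2:-2, 2:-2]
        for c in range(4):
            assert np.allclose(out[c], out[c, 0, 0], atol=1e-6)

    def test_against_from_scratch_interpolation_convolution_oracle(self, rng):
        ub = UpBlock(2, 1, 3, rng)
        below = rng.normal(0, 1, (1, 2, 2, 2)).astype(np.float32)
        skip = rng.normal(0, 1, (1, 1, 4, 4)).astype(np.float32)
        out = ub(Tensor(below), Tensor(skip)).data

        def upsample2(plane):  # half-pixel-center bilinear, explicit formula
            n = plane.shape[0]
            src = np.clip((np.arange(2 * n) + 0.5) / 2 - 0.5, 0, n - 1)
            i0 = np.floor(src).astype(int)
            i1 = np.minimum(i0 + 1, n - 1)
            f = src - i0
            rows = plane[i0] * (1 - f)[:, None] + plane[i1] * f[:, None]
            return rows[:, i0] * (1 - f)[None, :] + rows[:, i1] * f[None, :]

        up = np.stack([upsample2(below[0, c]) for c in range(2)])
        gw = ub.attention.gate.weight.data[0, 0, 0, 0]
        gb = ub.attention.gate.bias.data[0]
        gate = 1.0 / (1.0 + np.exp(-(gw * skip[0, 0] + gb)))
        cat = np.concatenate([up, (skip[0] * gate)], axis=0)

        def conv3(stack, weight, bias):
            return np.stack([
                sum(correlate(stack[i], weight[o, i], mode="constant")
                    for i in range(stack.shape[0])) + bias[o]
                for o in range(weight.shape[0])])

        h = np.maximum(conv3(cat, ub.block.conv1.weight.data,
                             ub.block.conv1.bias.data), 0)
        expected = np.maximum(conv3(h, ub.block.conv2.weight.data,
                                    ub.block.conv2.bias.data), 0)
        np.testing.assert_allclose(out[0], expected, rtol=1e-4, atol=1e-5)


@pytest.fixture(scope="module")
def model():
    return build_model("fixture_tiny", DecoderConfig(64, (32, 24, 16)), seed=5)


class TestModelForward:

    def test_output_contract(self, model, rng):
        x = Tensor(rng.normal(0, 1, (2, 3, 64, 96)).astype(np.float32))
        with no_grad():
            out = model.forward(x)
        assert out.p_veg.shape == (2, 1, 64, 96)
        assert out.p_crop.shape == (2, 1, 64, 96)
        assert len(out.aux) == 3
        for a in out.aux:
            assert a.shape == (2, 2, 64, 96)
        assert out.v.shape == (2, 1, 2, 3)
        assert (out.v.data >= 0).all() and (out.v.data <= 1).all()

    def test_outputs_match_random_valid_extents(self, model, rng):
        for _ in range(5):
            h = 32 * int(rng.integers(1, 4))
            w = 32 * int(rng.integers(1, 4))
            with no_grad():
                out = model.forward(Tensor(np.zeros((1, 3, h, w), np.float32)))
            assert out.p_veg.shape[2:] == (h, w)
            assert all(a.shape[2:] == (h, w) for a in out.aux)

    def test_evaluation_determinism(self, model, rng):
        x = Tensor(rng.normal(0, 1, (1, 3, 64, 64)).astype(np.float32))
        with no_grad():
            a = model.forward(x)
            b = model.forward(x)
        np.testing.assert_array_equal(a.p_veg.data, b.p_veg.data)
        np.testing.assert_array_equal(a.p_crop.data, b.p_crop.data)

    def test_indivisible_extent_rejected(self, model):
        with pytest.raises(ValueError, match="divisible"):
            model.forward(Tensor(np.zeros((1, 3, 60, 64), np.float32)))

    def test_gradients_reach_every_decoder_parameter(self, smoke_pairs):
        from weedseg.train import TrainConfig, _batch_loss
        model = build_model("fixture_tiny", DecoderConfig(64, (32, 24, 16)), seed=5)
        cfg = TrainConfig(backbone="fixture_tiny", epochs=1)
        total, _ = _batch_loss(model, smoke_pairs[:2], cfg)
        model.zero_grad()
        total.backward()
        for name, p in model.named_parameters():
            if name.startswith("encoder."):
                continue
            assert p.grad is not None and np.abs(p.grad).max() > 0, name


class TestCounting:
    def test_fixture_params_equal_hand_summed_layer_arithmetic(self):
        model = build_model("fixture_tiny", DecoderConfig(64, (32, 24, 16)), seed=0)
        encoder = (3 * 8 * 9 + 8) + (8 * 8 * 9 + 8) + (8 * 16 * 9 + 16) \
            + (16 * 32 * 9 + 32) + (32 * 64 * 9 + 64)
        vgc = (64 + 1) + (64 * 64 * 9 + 64) + (64 * 64 * 9 + 64) \
            + (64 * 16 + 16) + (16 * 64 + 64)
        up1 = (32 + 1) + (96 * 32 * 9 + 32) + (32 * 32 * 9 + 32)
        up2 = (16 + 1) + (48 * 24 * 9 + 24) + (24 * 24 * 9 + 24)
        up3 = (8 + 1) + (32 * 16 * 9 + 16) + (16 * 16 * 9 + 16)
        heads = 2 * (16 + 1)
        assert count_params(model) == encoder + vgc + up1 + up2 + up3 + heads

    def test_include_aux_adds_three_tiny_heads(self):
        model = build_model("fixture_tiny", DecoderConfig(64, (32, 24, 16)), seed=0)
        u1, u2, u3 = 32, 24, 16
        expected = (u1 * 2 + 2) + (u2 * 2 + 2) + (u3 * 2 + 2)
        assert count_params(model, include_aux=True) - count_params(model) == expected

    def test_fixture_macs_equal_closed_form_sum(self):
        model = build_model("fixture_tiny", DecoderConfig(64, (32, 24, 16)), seed=0)
        encoder = 1024 * 8 * 27 + 256 * 8 * 72 + 64 * 16 * 72 \
            + 16 * 32 * 144 + 4 * 64 * 288
        vgc = 4 * 64 + 4 * 64 * 64 * 9 * 2 + 64 * 16 + 16 * 64
        up1 = 16 * 32 + 16 * 32 * 96 * 9 + 16 * 32 * 32 * 9
        up2 = 64 * 16 + 64 * 24 * 48 * 9 + 64 * 24 * 24 * 9
        up3 = 256 * 8 + 256 * 16 * 32 * 9 + 256 * 16 * 16 * 9
        heads = 2 * 256 * 16
        assert count_macs(model, (64, 64)) == encoder + vgc + up1 + up2 + up3 + heads


def test_forward_golden_regression(smoke_pairs):
    """Seed-fixed fixture model on a fixed synthetic patch reproduces frozen
    summary statistics of its probability maps."""
    from weedseg.data_io import standardize
    model = build_model("fixture_tiny", DecoderConfig(64, (32, 24, 16)), seed=5)
    x = standardize(smoke_pairs[0][0]).transpose(2, 0, 1)[None]
    with no_grad():
        out = model.forward(Tensor(x))
    golden = GOLDEN_FORWARD
    np.testing.assert_allclose(
        [out.p_veg.data.mean(), out.p_crop.data.mean(), out.v.data.mean()],
        golden, atol=1e-5)


GOLDEN_FORWARD = [0.4994936488998974, 0.5030454729428762, 0.4961609244346618]
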