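"""Loss terms against hand computations and brute-force stencil oracles."""

import numpy as np
import pytest
from scipy.ndimage import correlate

from weedseg.autodiff import Tensor
from weedseg.losses import (LAPLACIAN_KERNEL, LossWeights, aux_loss, bce_loss,
                            boundary_dice_loss, crop_recall_loss, dice_loss,
                            head_losses, total_loss)
from weedseg.optim import AdamW


def boundary_oracle(p, g):
    """Independent edge-map Dice via scipy correlation."""
    def edges(x):
        r = correlate(np.asarray(x, np.float64),
                      LAPLACIAN_KERNEL.astype(np.float64), mode="constant")
        return np.clip(np.maximum(r, 0.0), 0.0, 1.0)
    ep, eg = edges(p), edges(g)
    return 1.0 - (2.0 * (ep * eg).sum() + 1.0) / (ep.sum() + eg.sum() + 1.0)


class TestDice:
    def test_perfect_binary_prediction(self, rng):
        g = (rng.uniform(size=64) > 0.5).astype(np.float32)
        assert dice_loss(g, g).item() < 1e-2  # smoothing tolerance

    def test_disjoint_binary_maps(self):
        p = np.array([1.0, 1.0, 0.0, 0.0], np.float32)
        g = np.array([0.0, 0.0, 1.0, 1.0], np.float32)
        assert dice_loss(p, g).item() > 0.7

    def test_hand_evaluation_without_smoothing(self):
        loss = dice_loss(np.array([0.5, 0.5]), np.array([1.0, 0.0]), smooth=0.0)
        np.testing.assert_allclose(loss.item(), 0.5, rtol=1e-6)

    def test_empty_empty_convention(self):
        assert dice_loss(np.zeros(8), np.zeros(8)).item() == 0.0

    def test_permutation_invariance(self, rng):
        p = rng.uniform(size=32)
        g = (rng.uniform(size=32) > 0.5).astype(float)
        perm = rng.permutation(32)
        np.testing.assert_allclose(dice_loss(p, g).item(),
                                   dice_loss(p[perm], g[perm]).item(), rtol=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice_loss(np.zeros(4), np.zeros(5))


class TestBoundaryDice:
    def test_identical_maps(self, rng):
        g = (rng.uniform(size=(9, 9)) > 0.5).astype(np.float32)
        assert boundary_dice_loss(g, g).item() == 0.0

    def test_constant_maps_have_empty_edges(self):
        p = np.full((6, 6), 0.7, np.float32)
        g = np.ones((6, 6), np.float32)
        assert boundary_dice_loss(p, g).item() == 0.0

    def test_shifted_square_matches_stencil_oracle(self):
        p = np.zeros((7, 7), np.float32)
        g = np.zeros((7, 7), np.float32)
        p[2:5, 2:5] = 1.0
        g[2:5, 3:6] = 1.0
        got = boundary_dice_loss(p, g).item()
        assert got > 0.1
        np.testing.assert_allclose(got, boundary_oracle(p, g), rtol=1e-5)

    def test_random_maps_match_oracle(self, rng):
        p = rng.uniform(size=(9, 9)).astype(np.float32)
        g = (rng.uniform(size=(9, 9)) > 0.5).astype(np.float32)
        np.testing.assert_allclose(boundary_dice_loss(p, g).item(),
                                   boundary_oracle(p, g), rtol=1e-4)

    def test_translation_equivariance_away_from_borders(self):
        base = np.zeros((12, 12), np.float32)
        base[3:6, 3:6] = 1.0
        shifted = np.roll(base, (2, 2), axis=(0, 1))
        g = np.zeros((12, 12), np.float32)
        g[3:6, 4:7] = 1.0
        g_shifted = np.roll(g, (2, 2), axis=(0, 1))
        np.testing.assert_allclose(boundary_dice_loss(base, g).item(),
                                   boundary_dice_loss(shifted, g_shifted).item(),
                                   rtol=1e-5)


class TestBCE:
    def test_confident_correct_prediction(self):
        g = np.array([1.0, 0.0, 1.0])
        p = np.array([1.0, 0.0, 1.0])
        assert bce_loss(p, g).item() < 1e-5

    def test_uniform_half_gives_ln2(self):
        p = np.full(16, 0.5)
        g = (np.arange(16) % 2).astype(float)
        np.testing.assert_allclose(bce_loss(p, g).item(), np.log(2.0), rtol=1e-6)

    def test_two_pixel_hand_computation(self):
        loss = bce_loss(np.array([0.9, 0.2]), np.array([1.0, 0.0]))
        expected = -0.5 * (np.log(0.9) + np.log(0.8))
        np.testing.assert_allclose(loss.item(), expected, rtol=1e-6)
        np.testing.assert_allclose(loss.item(), 0.16425, atol=1e-4)


class TestCropRecall:
    def test_full_vegetation_mask_is_plain_dice(self, rng):
        p = rng.uniform(size=16)
        g = (rng.uniform(size=16) > 0.5).astype(float)
        np.testing.assert_allclose(
            crop_recall_loss(p, g, np.ones(16)).item(),
            dice_loss(p, g).item(), rtol=1e-6)

    def test_empty_vegetation_mask_gives_zero(self, rng):
        p = rng.uniform(size=16)
        assert crop_recall_loss(p, np.zeros(16), np.zeros(16)).item() == 0.0

    def test_mixed_case_against_masking_oracle(self):
        p = np.array([[0.8, 0.2], [0.6, 0.9]])
        gc = np.array([[1.0, 0.0], [0.0, 1.0]])
        gv = np.array([[1.0, 1.0], [0.0, 1.0]])
        expected = dice_loss((p * gv).ravel(), (gc * gv).ravel()).item()
        np.testing.assert_allclose(crop_recall_loss(p, gc, gv).item(),
                                   expected, rtol=1e-6)


class TestComposition:
    def test_perfect_predictions_give_near_zero_heads(self, rng):
        gv = (rng.uniform(size=(12, 12)) > 0.4).astype(np.float32)
        gc = gv * (rng.uniform(size=(12, 12)) > 0.5)
        gw = gv - gc
        lv, lc, lw = head_losses(gv, gc, gw, gv, gc, gw)
        assert lv.item() < 0.05 and lc.item() < 0.05 and lw.item() < 0.05

    def test_random_instance_matches_term_by_term_oracle(self, rng):
        w = LossWeights()
        pv, pch, pw = (rng.uniform(0.01, 0.99, (8, 8)) for _ in range(3))
        gv = (rng.uniform(size=(8, 8)) > 0.5).astype(float)
        gc = gv * (rng.uniform(size=(8, 8)) > 0.5)
        gw = gv - gc
        lv, lc, lw_ = head_losses(pv, pch, pw, gv, gc, gw, w)
        np.testing.assert_allclose(
            lv.item(),
            dice_loss(pv, gv).item() + w.lambda_bv * boundary_dice_loss(pv, gv).item(),
            rtol=1e-5)
        np.testing.assert_allclose(
            lc.item(),
            bce_loss(pch, gc).item() + dice_loss(pch, gc).item()
            + w.lambda_bc * boundary_dice_loss(pch, gc).item()
            + 0.5 * crop_recall_loss(pch, gc, gv).item(),
            rtol=1e-5)
        np.testing.assert_allclose(
            lw_.item(),
            0.7 * dice_loss(pw, gw).item()
            + w.lambda_bw * boundary_dice_loss(pw, gw).item(),
            rtol=1e-5)

    def test_total_with_unit_components(self):
        one = Tensor(np.array(1.0))
        total = total_loss((one, one, one), [one, one, one])
        np.testing.assert_allclose(total.item(), 4.05, rtol=1e-6)

    def test_total_rejects_wrong_aux_count(self):
        one = Tensor(np.array(1.0))
        with pytest.raises(ValueError):
            total_loss((one, one, one), [one])

    def test_zero_components_give_zero(self):
        zero = Tensor(np.array(0.0))
        assert total_loss((zero, zero, zero), [zero, zero, zero]).item() == 0.0

    def test_aux_loss_is_mean_of_channel_dices(self, rng):
        probs = rng.uniform(0.01, 0.99, (1, 2, 6, 6)).astype(np.float32)
        gv = (rng.uniform(size=(1, 1, 6, 6)) > 0.5).astype(np.float32)
        gc = (rng.uniform(size=(1, 1, 6, 6)) > 0.5).astype(np.float32)
        expected = 0.5 * (dice_loss(probs[:, :1], gv).item()
                          + dice_loss(probs[:, 1:], gc).item())
        np.testing.assert_allclose(aux_loss(probs, gv, gc).item(), expected, rtol=1e-5)

    def test_losses_finite_nonnegative_on_random_inputs(self, rng):
        for _ in range(10):
            p = rng.uniform(0, 1, (7, 7))
            g = (rng.uniform(size=(7, 7)) > 0.5).astype(float)
            for loss in (dice_loss(p, g), boundary_dice_loss(p, g), bce_loss(p, g)):
                v = loss.item()
                assert np.isfinite(v) and v >= 0.0
            assert dice_loss(p, g).item() <= 1.0
            assert boundary_dice_loss(p, g).item() <= 1.0


def test_dice_gradient_descent_recovers_target(rng):
    """Minimizing Dice loss over a free probability map converges to the
    binary target within 1e-2 in at most 500 steps."""
    g = (rng.uniform(size=(8, 8)) > 0.6).astype(np.float32)
    z = Tensor(np.zeros((8, 8), np.float32), requires_grad=True)
    opt = AdamW([z], lr=0.1, weight_decay=0.0)
    for _ in range(500):
        loss = dice_loss(z.sigmoid(), g)
        opt.zero_grad()
        loss.backward()
        opt.step()
    p = 1.0 / (1.0 + np.exp(-z.data))
    assert np.abs(p - g).max() < 1e-2
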