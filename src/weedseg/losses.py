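"""Composite segmentation objective.

Per head the loss combines overlap (Dice), boundary agreement (Dice between
Laplacian edge maps), pixelwise confidence (BCE) and, for the crop head, a
recall term restricted to vegetated pixels::

    L_veg  = Dice(P_veg, G_veg)   + λ_bV · Bound(P_veg, G_veg)
    L_crop = BCE(P̂_crop, G_crop) + Dice(P̂_crop, G_crop)
             + λ_bC · Bound(P̂_crop, G_crop) + 0.5 · CropRecall
    L_weed = 0.7 · Dice(P_weed, G_weed) + λ_bW · Bound(P_weed, G_weed)

    L_total = λ_V L_veg + λ_C L_crop + λ_W L_weed + Σ_k λ_aux L_aux_k

with the deep-supervision term ``L_aux_k`` the mean Dice loss of the k-th
auxiliary head's vegetation and crop channels.  Default weights come from
the training grid search: λ_bV = 0.3, λ_bC = 0.05, λ_bW = 0.3,
λ_aux = 0.05, λ_V = 1.3, λ_C = 1.6, λ_W = 1.

All losses accept Tensors or arrays and return a scalar Tensor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, channel_slice, conv2d

__all__ = ["LossWeights", "LAPLACIAN_KERNEL", "dice_loss", "boundary_dice_loss",
           "bce_loss", "crop_recall_loss", "head_losses", "aux_loss", "total_loss"]

#: 3x3 discrete Laplacian stencil used for edge extraction (entries sum to 0).
LAPLACIAN_KERNEL = np.array([[1.0, 1.0, 1.0],
                             [1.0, -8.0, 1.0],
                             [1.0, 1.0, 1.0]], dtype=np.float32)

_BCE_CLAMP = 1e-7


@dataclass
class LossWeights:
    lambda_bv: float = 0.3
    lambda_bc: float = 0.05
    lambda_bw: float = 0.3
    lambda_aux: float = 0.05
    lambda_v: float = 1.3
    lambda_c: float = 1.6
    lambda_w: float = 1.0
    weed_dice_coeff: float = 0.7
    recall_coeff: float = 0.5
    gamma: float = 0.75


def dice_loss(p, g, smooth: float = 1.0) -> Tensor:
    """``1 − 2ΣPG / (ΣP + ΣG + s)``.

    The smoothing term ``s`` (default 1) makes the empty-vs-empty case a
    well-defined zero loss; pass ``smooth=0`` for the raw overlap form on
    nonempty inputs.
    """
    p, g = as_tensor(p), as_tensor(g)
    if p.data.size != g.data.size:
        raise ValueError(f"size mismatch: {p.data.shape} vs {g.data.shape}")
    p = p.reshape(-1)
    g = g.reshape(-1)
    inter = (p * g).sum()
    denom = p.sum() + g.sum() + smooth
    return 1.0 - (2.0 * inter + smooth) / denom


def _edge_map(x: Tensor) -> Tensor:
    """Positive external contour: ReLU of the Laplacian response (zero padding)."""
    if x.ndim == 2:
        x = x.reshape(1, 1, *x.shape)
    elif x.ndim == 3:
        x = x.reshape(x.shape[0], 1, x.shape[1], x.shape[2])
    elif x.ndim == 4 and x.shape[1] != 1:
        raise ValueError("boundary loss expects single-channel maps")
    k = Tensor(LAPLACIAN_KERNEL.reshape(1, 1, 3, 3))
    # clamp to the unit range: raw contour responses reach 8, and soft Dice
    # is only a set similarity (loss in [0, 1]) for inputs in [0, 1]
    return conv2d(x, k, padding=1).relu().clip(0.0, 1.0)


def boundary_dice_loss(p, g) -> Tensor:
    """Dice loss between rectified Laplacian edge maps of ``p`` and ``g``.

    Constant maps have empty edges on both sides, giving zero loss by the
    smoothed-Dice convention.
    """
    p, g = as_tensor(p), as_tensor(g)
    if p.data.shape != g.data.shape:
        raise ValueError("boundary loss requires equal extents")
    return dice_loss(_edge_map(p), _edge_map(g), smooth=1.0)


def bce_loss(p, g) -> Tensor:
    """Mean binary cross-entropy; probabilities clamped away from {0, 1}."""
    p, g = as_tensor(p), as_tensor(g)
    if p.data.size != g.data.size:
        raise ValueError(f"size mismatch: {p.data.shape} vs {g.data.shape}")
    p = p.reshape(-1)
    g = g.reshape(-1)
    pc = p.clip(_BCE_CLAMP, 1.0 - _BCE_CLAMP)
    n = float(p.data.size)
    ll = g * pc.log() + (1.0 - g) * (1.0 - pc).log()
    return -ll.sum() * (1.0 / n)


def crop_recall_loss(p_crop_hat, g_crop, g_veg, smooth: float = 1.0) -> Tensor:
    """Dice loss restricted to vegetation-labeled pixels.

    Both prediction and target are masked by ``G_veg`` before the overlap,
    encouraging recovery of every crop pixel inside the vegetation support.
    """
    p = as_tensor(p_crop_hat).reshape(-1)
    gc = as_tensor(g_crop).reshape(-1)
    gv = as_tensor(g_veg).reshape(-1)
    return dice_loss(p * gv, gc * gv, smooth=smooth)


def head_losses(p_veg, p_crop_hat, p_weed, g_veg, g_crop, g_weed,
                weights: LossWeights | None = None) -> tuple[Tensor, Tensor, Tensor]:
    """Per-head composite losses ``(L_veg, L_crop, L_weed)``."""
    w = weights or LossWeights()
    l_veg = dice_loss(p_veg, g_veg) + w.lambda_bv * boundary_dice_loss(p_veg, g_veg)
    l_crop = (bce_loss(p_crop_hat, g_crop)
              + dice_loss(p_crop_hat, g_crop)
              + w.lambda_bc * boundary_dice_loss(p_crop_hat, g_crop)
              + w.recall_coeff * crop_recall_loss(p_crop_hat, g_crop, g_veg))
    l_weed = (w.weed_dice_coeff * dice_loss(p_weed, g_weed)
              + w.lambda_bw * boundary_dice_loss(p_weed, g_weed))
    return l_veg, l_crop, l_weed


def aux_loss(aux_probs, g_veg, g_crop) -> Tensor:
    """Deep-supervision term: mean Dice loss of an auxiliary head's
    vegetation and crop probability channels (shape (N, 2, H, W))."""
    p = as_tensor(aux_probs)
    if p.ndim != 4 or p.shape[1] != 2:
        raise ValueError("auxiliary head output must be (N, 2, H, W)")
    p_veg = channel_slice(p, 0, 1)
    p_crop = channel_slice(p, 1, 2)
    return 0.5 * (dice_loss(p_veg, g_veg) + dice_loss(p_crop, g_crop))


def total_loss(heads: tuple[Tensor, Tensor, Tensor],
               aux_terms: list[Tensor],
               weights: LossWeights | None = None) -> Tensor:
    """Weighted sum of head losses and the three deep-supervision terms."""
    w = weights or LossWeights()
    if len(aux_terms) != 3:
        raise ValueError(f"expected 3 auxiliary losses, got {len(aux_terms)}")
    l_veg, l_crop, l_weed = heads
    total = w.lambda_v * as_tensor(l_veg) + w.lambda_c * as_tensor(l_crop) \
        + w.lambda_w * as_tensor(l_weed)
    for la in aux_terms:
        total = total + w.lambda_aux * as_tensor(la)
    return total
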