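"""Dual-head hierarchical U-Net decoder.

The decoder consumes a four-level feature pyramid (strides 4/8/16/32) and
produces two full-resolution probability maps — vegetation and crop — from
which the weed map is later derived as residual vegetation
(:mod:`weedseg.hierarchy`).  Its pieces:

* **Spatial attention** on each skip connection: a 1x1 convolution predicts a
  single-channel sigmoid weight map that multiplicatively gates the skip
  features (per-pixel, broadcast over channels).
* **Vegetation Global Context (VGC) bottleneck**: a sigmoid 1x1 convolution
  on the last encoder stage estimates a vegetation probability map ``V``;
  bottleneck features are pooled with ``V`` as soft spatial weights
  (masked global pooling), squeezed/excited through a channel bottleneck of
  reduction ratio ``r``, and the resulting per-channel gate rescales the
  features.
* **Three UpBlocks**: bilinear x2 upsampling, attention-gated skip,
  channel concatenation, then two 3x3 conv + ReLU layers (no normalization).
* **Dual 1x1 heads** at stride 4, bilinearly interpolated to the input
  extent; three auxiliary 2-channel heads (vegetation, crop) on the decoder
  stages provide deep supervision and are discarded at inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .autodiff import Tensor, bilinear_resize, concat, linear, mac_counter, no_grad
from .encoders import Encoder, get_backbone, list_backbones

__all__ = [
    "DecoderConfig", "UNetOutputs", "SpatialAttention", "Excitation",
    "VGCBlock", "ConvBlock", "UpBlock", "HierarchicalUNet",
    "masked_global_pool", "count_params", "count_macs",
    "default_decoder_config", "build_model",
]

# Reference decoder widths per backbone, calibrated so that the
# ConvNeXt V2 Tiny model lands at the published 32.52 M-parameter budget.
_REFERENCE_WIDTHS = {
    "convnextv2_tiny": (320, (144, 80, 48)),
    "fastvit_s12": (256, (128, 64, 48)),
    "fastvit_sa24": (256, (128, 64, 48)),
    "repvit_m2": (256, (128, 64, 48)),
    "mambavision_t": (256, (128, 64, 48)),
    "fixture_tiny": (64, (32, 24, 16)),
}


@dataclass
class DecoderConfig:
    bottleneck_channels: int = 320
    up_channels: tuple[int, int, int] = (144, 80, 48)
    vgc_reduction: int = 4
    epsilon: float = 1e-6
    n_aux_heads: int = 3

    def __post_init__(self):
        if self.bottleneck_channels % self.vgc_reduction:
            raise ValueError(
                f"vgc_reduction {self.vgc_reduction} must divide "
                f"bottleneck_channels {self.bottleneck_channels}")
        if self.n_aux_heads != 3:
            raise ValueError("the decoder has exactly 3 auxiliary heads")


def default_decoder_config(backbone: str) -> DecoderConfig:
    bott, ups = _REFERENCE_WIDTHS.get(backbone, (256, (128, 64, 48)))
    return DecoderConfig(bottleneck_channels=bott, up_channels=ups)


@dataclass
class UNetOutputs:
    """Full-resolution probabilities plus auxiliary maps.

    ``p_veg``/``p_crop`` are sigmoid probabilities at the input extent;
    ``aux`` holds three (N, 2, H, W) probability tensors (vegetation, crop)
    from the deep-supervision heads; ``v`` is the bottleneck vegetation
    probability map at stride 32.
    """
    p_veg: Tensor
    p_crop: Tensor
    aux: list = field(default_factory=list)
    v: Tensor | None = None


class SpatialAttention(nn.Module):
    """Self-gated per-pixel attention: ``x * sigmoid(conv1x1(x))``."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.gate = nn.Conv2d(channels, 1, 1, rng=rng, init_std=1e-2)

    def forward(self, x):
        w = self.gate(x).sigmoid()
        return x * w


def masked_global_pool(f: Tensor, v: Tensor, epsilon: float = 1e-6) -> Tensor:
    """Soft masked global pooling.

    ``w_c = sum_ij F[c,i,j] V[i,j] / (sum_ij V[i,j] + eps)`` — a spatial mean
    of each feature channel weighted by the vegetation probability ``V``.

    Parameters are NCHW tensors: ``f`` (N, C, H, W), ``v`` (N, 1, H, W) with
    values in [0, 1].  Returns an (N, C) tensor.
    """
    num = (f * v).sum(axis=(2, 3))
    den = v.sum(axis=(2, 3)) + epsilon
    return num / den


class Excitation(nn.Module):
    """Squeeze-and-excitation channel gate: ``sigmoid(W2 relu(W1 w))``."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        if channels % reduction:
            raise ValueError(f"reduction {reduction} does not divide {channels} channels")
        self.fc1 = nn.Linear(channels, channels // reduction, rng=rng)
        self.fc2 = nn.Linear(channels // reduction, channels, rng=rng)

    def forward(self, w):
        return self.fc2(self.fc1(w).relu()).sigmoid()


class ConvBlock(nn.Module):
    """Two consecutive 3x3 convolutions, each followed by ReLU."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, padding=1, rng=rng)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, padding=1, rng=rng)

    def forward(self, x):
        return self.conv2(self.conv1(x).relu()).relu()


class VGCBlock(nn.Module):
    """Vegetation Global Context bottleneck.

    The vegetation map ``V`` comes from its own sigmoid 1x1 convolution on
    the last encoder stage (distinct from the final vegetation head and
    without dedicated supervision); features are recalibrated channel-wise
    by the excitation gate computed from the ``V``-weighted pooled
    descriptor.
    """

    def __init__(self, in_ch: int, out_ch: int, reduction: int,
                 epsilon: float, rng: np.random.Generator):
        self.v_conv = nn.Conv2d(in_ch, 1, 1, rng=rng, init_std=1e-2)
        self.block = ConvBlock(in_ch, out_ch, rng=rng)
        self.excitation = Excitation(out_ch, reduction, rng=rng)
        self.epsilon = epsilon

    def forward(self, x_enc):
        v = self.v_conv(x_enc).sigmoid()
        f = self.block(x_enc)
        w = masked_global_pool(f, v, self.epsilon)
        g = self.excitation(w)
        n, c = g.shape
        f_prime = f * g.reshape(n, c, 1, 1)
        return f_prime, v


class UpBlock(nn.Module):
    """Bilinear x2 upsample, gated skip, concatenation, ConvBlock refinement."""

    def __init__(self, below_ch: int, skip_ch: int, out_ch: int,
                 rng: np.random.Generator):
        self.attention = SpatialAttention(skip_ch, rng=rng)
        self.block = ConvBlock(below_ch + skip_ch, out_ch, rng=rng)

    def forward(self, below, skip):
        bh, bw = below.shape[2:]
        sh, sw = skip.shape[2:]
        if (sh, sw) != (2 * bh, 2 * bw):
            raise ValueError(
                f"skip extent {sh}x{sw} must be twice the below extent {bh}x{bw}")
        up = bilinear_resize(below, (sh, sw))
        gated = self.attention(skip)
        return self.block(concat([up, gated], axis=1))


class HierarchicalUNet(nn.Module):
    """Encoder + VGC bottleneck + three UpBlocks + dual heads + aux heads."""

    def __init__(self, encoder: Encoder, config: DecoderConfig | None = None,
                 rng: np.random.Generator | None = None,
                 backbone_name: str | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.encoder = encoder
        self.config = config or default_decoder_config(backbone_name or "")
        self.backbone_name = backbone_name
        c1, c2, c3, c4 = encoder.channels
        u1, u2, u3 = self.config.up_channels
        self.vgc = VGCBlock(c4, self.config.bottleneck_channels,
                            self.config.vgc_reduction, self.config.epsilon, rng)
        self.up1 = UpBlock(self.config.bottleneck_channels, c3, u1, rng)
        self.up2 = UpBlock(u1, c2, u2, rng)
        self.up3 = UpBlock(u2, c1, u3, rng)
        self.head_veg = nn.Conv2d(u3, 1, 1, rng=rng, init_std=1e-2)
        self.head_crop = nn.Conv2d(u3, 1, 1, rng=rng, init_std=1e-2)
        self.aux_heads = nn.ModuleList(
            nn.Conv2d(u, 2, 1, rng=rng, init_std=1e-2) for u in (u1, u2, u3))

    def forward(self, x, with_aux: bool = True) -> UNetOutputs:
        n, _, h, w = x.shape
        f1, f2, f3, f4 = self.encoder(x)
        f_bott, v = self.vgc(f4)
        d3 = self.up1(f_bott, f3)
        d2 = self.up2(d3, f2)
        d1 = self.up3(d2, f1)
        p_veg = bilinear_resize(self.head_veg(d1), (h, w)).sigmoid()
        p_crop = bilinear_resize(self.head_crop(d1), (h, w)).sigmoid()
        aux = []
        if with_aux:
            for head, feat in zip(self.aux_heads, (d3, d2, d1)):
                aux.append(bilinear_resize(head(feat), (h, w)).sigmoid())
        return UNetOutputs(p_veg=p_veg, p_crop=p_crop, aux=aux, v=v)


def build_model(backbone: str = "fixture_tiny",
                config: DecoderConfig | None = None,
                seed: int = 0) -> HierarchicalUNet:
    """Instantiate the segmentation model for a registered backbone."""
    rng = np.random.default_rng(seed)
    encoder = get_backbone(backbone, rng)
    cfg = config or default_decoder_config(backbone)
    return HierarchicalUNet(encoder, cfg, rng=rng, backbone_name=backbone)


def count_params(model: HierarchicalUNet, include_aux: bool = False) -> int:
    """Trainable scalar parameters; auxiliary heads excluded by default
    (they are discarded at inference)."""
    total = model.n_parameters()
    if not include_aux:
        total -= sum(p.data.size for p in model.aux_heads.parameters())
    return int(total)


def count_macs(model: HierarchicalUNet, extent: tuple[int, int],
               include_aux: bool = False) -> int:
    """Multiply-accumulates for one forward pass at ``extent`` (H, W).

    Counted during an actual forward pass: every convolution and linear
    layer contributes once per multiply-accumulate; interpolation and
    elementwise work are not counted, matching standard per-layer counters.
    """
    h, w = extent
    x = Tensor(np.zeros((1, 3, h, w), dtype=np.float32))
    with no_grad(), mac_counter() as counter:
        model.forward(x, with_aux=include_aux)
    return counter.total
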