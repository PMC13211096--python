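"""Feature-pyramid encoders.

Every backbone exposes the same contract: given a standardized NCHW image
whose height and width are divisible by 32, ``forward`` returns four feature
maps at strides 4/8/16/32 with the channel signature declared in the
registry.

Two backbones are instantiable here:

* ``fixture_tiny`` — a ~25k-parameter strided CNN so the full segmentation
  stack runs on CPU in seconds; used throughout the test suite.
* ``convnextv2_tiny`` — the four-stage ConvNeXt V2 Tiny layout (depths
  3/3/9/3, dims 96/192/384/768, depthwise 7x7 + inverted bottleneck with
  global response normalization), randomly initialized.  Its layer shapes
  are exact, so parameter and multiply-accumulate accounting of the full
  segmentation model is faithful even without pretrained weights.

The remaining registry entries (FastViT, RepViT, MambaVision) declare the
channel signatures used for decoder sizing but require pretrained weights
from a model zoo and therefore cannot be instantiated in this package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autodiff import Tensor

__all__ = ["BackboneInfo", "list_backbones", "get_backbone", "pyramid_extents",
           "FixtureEncoder", "ConvNeXtV2"]

STRIDES = (4, 8, 16, 32)


@dataclass(frozen=True)
class BackboneInfo:
    name: str
    channels: tuple[int, int, int, int]
    pretrained_available: bool
    instantiable: bool


_REGISTRY = {
    "convnextv2_tiny": BackboneInfo("convnextv2_tiny", (96, 192, 384, 768), False, True),
    "fastvit_s12": BackboneInfo("fastvit_s12", (64, 128, 256, 512), False, False),
    "fastvit_sa24": BackboneInfo("fastvit_sa24", (64, 128, 256, 512), False, False),
    "repvit_m2": BackboneInfo("repvit_m2", (80, 160, 320, 640), False, False),
    "mambavision_t": BackboneInfo("mambavision_t", (80, 160, 320, 640), False, False),
    "fixture_tiny": BackboneInfo("fixture_tiny", (8, 16, 32, 64), False, True),
}


def list_backbones() -> dict[str, BackboneInfo]:
    """Registry of available backbones and their stage channel signatures."""
    return dict(_REGISTRY)


def pyramid_extents(height: int, width: int) -> list[tuple[int, int]]:
    """Spatial extents of the four pyramid levels for a valid input extent."""
    _check_extent(height, width)
    return [(height // s, width // s) for s in STRIDES]


def _check_extent(height: int, width: int) -> None:
    if height % 32 or width % 32:
        raise ValueError(
            f"input extent {height}x{width} is not divisible by 32; "
            "pad the image (e.g. reflect-pad) to the next multiple of 32")


def get_backbone(name: str, rng: np.random.Generator | None = None) -> "Encoder":
    try:
        info = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown backbone {name!r}; registered: {sorted(_REGISTRY)}") from None
    if not info.instantiable:
        raise ValueError(
            f"backbone {name!r} requires pretrained weights from a model zoo that "
            "this package does not bundle; instantiable backbones: "
            f"{sorted(k for k, v in _REGISTRY.items() if v.instantiable)}")
    rng = rng if rng is not None else np.random.default_rng(0)
    if name == "fixture_tiny":
        return FixtureEncoder(rng)
    return ConvNeXtV2(rng)


class Encoder(nn.Module):
    """Base: validates the extent then delegates to ``_features``."""

    channels: tuple[int, int, int, int]

    def forward(self, x: Tensor) -> list[Tensor]:
        _, _, h, w = x.shape
        _check_extent(h, w)
        feats = self._features(x)
        assert len(feats) == 4
        return feats


class FixtureEncoder(Encoder):
    """Tiny four-stage strided CNN (channels 8/16/32/64) for CPU tests."""

    channels = (8, 16, 32, 64)

    def __init__(self, rng: np.random.Generator):
        self.stage1 = nn.Sequential(
            nn.Conv2d(3, 8, 3, stride=2, padding=1, rng=rng), nn.ReLU(),
            nn.Conv2d(8, 8, 3, stride=2, padding=1, rng=rng), nn.ReLU(),
        )
        self.stage2 = nn.Sequential(
            nn.Conv2d(8, 16, 3, stride=2, padding=1, rng=rng), nn.ReLU())
        self.stage3 = nn.Sequential(
            nn.Conv2d(16, 32, 3, stride=2, padding=1, rng=rng), nn.ReLU())
        self.stage4 = nn.Sequential(
            nn.Conv2d(32, 64, 3, stride=2, padding=1, rng=rng), nn.ReLU())

    def _features(self, x):
        f1 = self.stage1(x)
        f2 = self.stage2(f1)
        f3 = self.stage3(f2)
        f4 = self.stage4(f3)
        return [f1, f2, f3, f4]


class _ConvNeXtBlock(nn.Module):
    """Depthwise 7x7 -> LN -> 1x1 expand x4 -> GELU -> GRN -> 1x1 project, residual."""

    def __init__(self, dim: int, rng: np.random.Generator):
        self.dwconv = nn.DepthwiseConv2d(dim, 7, padding=3, rng=rng)
        self.norm = nn.LayerNorm(dim, axis=1)
        self.pwconv1 = nn.Conv2d(dim, 4 * dim, 1, rng=rng)
        self.grn = nn.GRN(4 * dim)
        self.pwconv2 = nn.Conv2d(4 * dim, dim, 1, rng=rng)

    def forward(self, x):
        y = self.dwconv(x)
        y = self.norm(y)
        y = self.pwconv1(y).gelu()
        y = self.grn(y)
        y = self.pwconv2(y)
        return x + y


class ConvNeXtV2(Encoder):
    """ConvNeXt V2 Tiny layout: stem stride 4 then stages of depths 3/3/9/3."""

    channels = (96, 192, 384, 768)
    depths = (3, 3, 9, 3)

    def __init__(self, rng: np.random.Generator):
        dims = self.channels
        self.stem = nn.Sequential(
            nn.Conv2d(3, dims[0], 4, stride=4, rng=rng),
            nn.LayerNorm(dims[0], axis=1))
        self.stages = nn.ModuleList(
            nn.Sequential(*[_ConvNeXtBlock(d, rng) for _ in range(n)])
            for d, n in zip(dims, self.depths))
        self.downsamples = nn.ModuleList(
            nn.Sequential(nn.LayerNorm(dims[i], axis=1),
                          nn.Conv2d(dims[i], dims[i + 1], 2, stride=2, rng=rng))
            for i in range(3))

    def _features(self, x):
        feats = []
        y = self.stem(x)
        for i, stage in enumerate(self.stages):
            y = stage(y)
            feats.append(y)
            if i < 3:
                y = self.downsamples[i](y)
        return feats
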