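"""Synthetic aerial field patches with exact 3-class ground truth.

The generator emulates the salient structure of low-altitude drone imagery
of a transplanted row crop: a brown soil background with smooth illumination
texture, large compact crop plants ("rosettes" — unions of 5–9 overlapping
ellipses) placed on a jittered planting grid, and weeds as thin random-walk
filaments and small blotches scattered over the bare soil.  Crop and weed
greens are separated by a configurable hue offset (default 15°) so the
classes are distinguishable but not trivially so.

Because vegetation pixels are painted exactly where the mask says they are,
the mask is correct by construction and the HSV green filter recovers the
vegetation support almost exactly — which is what ties the generator to the
dataset-repair tool.

What it does **not** emulate: perspective, shadows, occlusion, growth
stages, soil moisture variation, or photorealistic leaf texture.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.color import hsv2rgb

from .data_io import ClassMask, ImagePatch, save_pair, write_manifest

__all__ = ["FieldParams", "generate_field", "generate_dataset",
           "expected_class_fractions"]


@dataclass
class FieldParams:
    """Generator configuration.

    extent
        (height, width) in pixels, each divisible by 32.
    n_crops
        Number of crop plants on the jittered grid.
    crop_radius / crop_radius_jitter
        Mean rosette radius in px and its relative jitter.
    weed_density
        Expected weed fragments per 10^4 px of canvas.
    soil_palette
        Candidate base soil colors (RGB triplets, 0-255).
    illumination_gain
        Global brightness multiplier.
    crop_hue / weed_hue_delta
        Crop green hue in degrees and the weed hue offset from it.
    """
    extent: tuple[int, int] = (352, 480)
    n_crops: int = 8
    crop_radius: float = 36.0
    crop_radius_jitter: float = 0.25
    weed_density: float = 1.5
    soil_palette: tuple = ((120, 85, 50), (134, 98, 60), (106, 74, 46))
    illumination_gain: float = 1.0
    crop_hue: float = 100.0
    weed_hue_delta: float = 15.0
    weed_length: tuple[int, int] = (12, 35)
    weed_width: tuple[int, int] = (1, 3)
    weed_blotch_frac: float = 0.4
    weed_blotch_radius: tuple[float, float] = (3.0, 6.0)
    seed: int = 0

    def __post_init__(self):
        h, w = self.extent
        if h % 32 or w % 32:
            raise ValueError(f"extent {self.extent} must be divisible by 32")
        if self.n_crops < 0 or self.weed_density < 0:
            raise ValueError("n_crops and weed_density must be nonnegative")


def _rosette(rng: np.random.Generator, center, radius: float, shape) -> np.ndarray:
    """Union of 5-9 overlapping rotated ellipses around a center."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros(shape, dtype=bool)
    n_lobes = int(rng.integers(5, 10))
    for _ in range(n_lobes):
        ang = rng.uniform(0, np.pi)
        a = radius * rng.uniform(0.7, 1.0)
        b = a * rng.uniform(0.4, 0.6)
        off = rng.uniform(-0.25, 0.25, size=2) * radius
        cy, cx = center[0] + off[0], center[1] + off[1]
        ca, sa = np.cos(ang), np.sin(ang)
        u = (xx - cx) * ca + (yy - cy) * sa
        v = -(xx - cx) * sa + (yy - cy) * ca
        mask |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask


def _weed_blotch(rng: np.random.Generator, shape, radius_range) -> np.ndarray:
    """Small compact weed: union of 2-3 tiny ellipses."""
    h, w = shape
    cy, cx = rng.uniform(0, h), rng.uniform(0, w)
    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros(shape, dtype=bool)
    for _ in range(int(rng.integers(2, 4))):
        r = rng.uniform(*radius_range)
        ang = rng.uniform(0, np.pi)
        a, b = r, r * rng.uniform(0.5, 0.9)
        oy, ox = rng.uniform(-0.6, 0.6, 2) * r
        ca, sa = np.cos(ang), np.sin(ang)
        u = (xx - cx - ox) * ca + (yy - cy - oy) * sa
        v = -(xx - cx - ox) * sa + (yy - cy - oy) * ca
        mask |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask


def _weed_fragment(rng: np.random.Generator, shape,
                   length_range, width_range) -> np.ndarray:
    """Thin filament: a smoothly turning random walk stamped with a small disk."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    y, x = rng.uniform(0, h), rng.uniform(0, w)
    ang = rng.uniform(0, 2 * np.pi)
    length = int(rng.integers(length_range[0], length_range[1] + 1))
    width = int(rng.integers(width_range[0], width_range[1] + 1))
    r = (width - 1) // 2
    for _ in range(length):
        ang += rng.normal(0.0, 0.35)
        y += np.sin(ang)
        x += np.cos(ang)
        iy, ix = int(round(y)), int(round(x))
        if not (0 <= iy < h and 0 <= ix < w):
            break
        y0, y1 = max(iy - r, 0), min(iy + r + 1, h)
        x0, x1 = max(ix - r, 0), min(ix + r + 1, w)
        mask[y0:y1, x0:x1] = True
    return mask


def _soil(rng: np.random.Generator, params: FieldParams) -> np.ndarray:
    h, w = params.extent
    base = np.array(params.soil_palette[rng.integers(len(params.soil_palette))],
                    dtype=np.float32) / 255.0
    illum = gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=18.0)
    illum = 1.0 + 0.25 * illum / (np.abs(illum).max() + 1e-9)
    speckle = rng.normal(0.0, 0.02, (h, w, 3))
    img = base[None, None, :] * illum[..., None] + speckle
    return np.clip(img * params.illumination_gain, 0.0, 1.0)


def _paint_vegetation(rng, img, support, hue_deg):
    """Color `support` pixels a jittered green in HSV space."""
    n = int(support.sum())
    if n == 0:
        return
    hue = (hue_deg + rng.normal(0.0, 3.0, n)) / 360.0
    sat = np.clip(rng.normal(0.62, 0.08, n), 0.40, 0.90)
    val = np.clip(rng.normal(0.50, 0.10, n), 0.28, 0.85)
    hsv = np.stack([np.clip(hue, 0.0, 0.999), sat, val], axis=-1)
    img[support] = hsv2rgb(hsv[None, :, :])[0]


def generate_field(params: FieldParams) -> tuple[ImagePatch, ClassMask]:
    """Render one field patch and its exact mask, deterministically per seed."""
    h, w = params.extent
    rng = np.random.default_rng(params.seed)
    if params.n_crops * np.pi * params.crop_radius ** 2 > 0.8 * h * w:
        raise ValueError("requested crop area exceeds 80% of the canvas")

    labels = np.zeros((h, w), dtype=np.uint8)

    # crops on a jittered planting grid
    if params.n_crops > 0:
        n_cols = max(1, int(round(np.sqrt(params.n_crops * w / h))))
        n_rows = max(1, int(np.ceil(params.n_crops / n_cols)))
        cells = [(i, j) for i in range(n_rows) for j in range(n_cols)]
        margin = params.crop_radius * 0.8
        for (i, j) in cells[:params.n_crops]:
            cy = (i + 0.5) / n_rows * h + rng.uniform(-0.12, 0.12) * h / n_rows
            cx = (j + 0.5) / n_cols * w + rng.uniform(-0.12, 0.12) * w / n_cols
            cy = float(np.clip(cy, margin, h - margin))
            cx = float(np.clip(cx, margin, w - margin))
            radius = params.crop_radius * (
                1.0 + rng.uniform(-params.crop_radius_jitter, params.crop_radius_jitter))
            labels[_rosette(rng, (cy, cx), radius, (h, w))] = 1

    # weeds on bare soil only
    n_weeds = rng.poisson(params.weed_density * h * w / 1e4)
    for _ in range(n_weeds):
        if rng.uniform() < params.weed_blotch_frac:
            frag = _weed_blotch(rng, (h, w), params.weed_blotch_radius)
        else:
            frag = _weed_fragment(rng, (h, w), params.weed_length, params.weed_width)
        labels[frag & (labels == 0)] = 2

    img = _soil(rng, params)
    _paint_vegetation(rng, img, labels == 1, params.crop_hue)
    _paint_vegetation(rng, img, labels == 2, params.crop_hue + params.weed_hue_delta)

    pixels = (img * 255.0).round().clip(0, 255).astype(np.uint8)
    return ImagePatch(pixels, source_id=f"synthetic-{params.seed}"), ClassMask(labels)


def generate_dataset(n: int, params: FieldParams, seed: int = 0,
                     out_dir: str | Path | None = None):
    """Generate ``n`` patch/mask pairs with per-item derived seeds.

    Returns ``(pairs, manifest_rows)``; when ``out_dir`` is given, PNGs and a
    ``manifest.csv`` are also written there.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    item_seeds = rng.integers(0, 2**31 - 1, size=n)
    pairs, rows = [], []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(item_seeds):
        patch, mask = generate_field(replace(params, seed=int(s)))
        pairs.append((patch, mask))
        row = {"image": f"patch_{i:04d}.png", "mask": f"mask_{i:04d}.png",
               "campaign": "synthetic", "split": ""}
        rows.append(row)
        if out is not None:
            save_pair(patch, mask, out / row["image"], out / row["mask"])
    if out is not None:
        write_manifest(rows, out / "manifest.csv")
    return pairs, rows


def expected_class_fractions(params: FieldParams, n_mc: int = 64,
                             seed: int = 12345) -> dict:
    """Monte-Carlo estimate of expected crop/weed pixel fractions.

    Samples the shape primitives directly (rosette areas, filament areas)
    rather than running the full generator, giving an independent reference
    for the pixel-fraction statistics of generated datasets.
    """
    h, w = params.extent
    rng = np.random.default_rng(seed)
    crop_areas = []
    for _ in range(n_mc):
        radius = params.crop_radius * (
            1.0 + rng.uniform(-params.crop_radius_jitter, params.crop_radius_jitter))
        c = (h / 2, w / 2)
        crop_areas.append(_rosette(rng, c, radius, (h, w)).sum())
    weed_areas = [
        _weed_fragment(rng, (h, w), params.weed_length, params.weed_width).sum()
        for _ in range(n_mc)]
    crop_frac = params.n_crops * float(np.mean(crop_areas)) / (h * w)
    weed_frac = (params.weed_density * h * w / 1e4) * float(np.mean(weed_areas)) / (h * w)
    return {"crop": crop_frac, "weed": weed_frac}
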