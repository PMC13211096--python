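"""Patch/mask I/O, standardization, splits, binary targets, and dataset repair.

Masks are single-channel PNGs with literal class indices 0 (background),
1 (crop) and 2 (weed); a tolerant reader also maps the {0, 128, 255}
grayscale dialect, with a warning.  The repair tool addresses misnamed
patch↔mask pairs: an HSV green filter extracts each patch's vegetation
support, which is then matched by nearest-neighbor distance against the
vegetation support of every candidate ground-truth mask — ground truth is
never modified, only re-associated.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.color import rgb2hsv

__all__ = [
    "IMAGENET_MEAN", "IMAGENET_STD", "HSVBounds",
    "ImagePatch", "ClassMask", "BinaryTargets", "SplitSpec",
    "load_pair", "save_pair", "standardize", "split_dataset",
    "green_mask_hsv", "match_masks", "to_binary_targets",
    "write_manifest", "read_manifest", "write_repair_csv",
]

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)

VALID_LABELS = frozenset({0, 1, 2})


@dataclass
class ImagePatch:
    """8-bit RGB raster (H, W, 3)."""
    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"patch must be (H, W, 3) RGB, got {self.pixels.shape}")
        if self.height < 32 or self.width < 32:
            raise ValueError(f"patch extent {self.pixels.shape[:2]} below 32 px minimum")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class ClassMask:
    """Integer raster over {0, 1, 2}: background / crop / weed."""
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        bad = set(np.unique(self.labels)) - VALID_LABELS
        if bad:
            raise ValueError(f"mask contains labels outside {{0,1,2}}: {sorted(bad)}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    def vegetation_support(self) -> np.ndarray:
        return (self.labels > 0).astype(np.uint8)


@dataclass
class BinaryTargets:
    """Binary rasters for the three supervised maps; crop + weed = vegetation."""
    g_veg: np.ndarray
    g_crop: np.ndarray
    g_weed: np.ndarray


@dataclass
class SplitSpec:
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.fractions}")
        if not all(0.0 < f < 1.0 for f in self.fractions):
            raise ValueError("each split fraction must lie in (0, 1)")


@dataclass(frozen=True)
class HSVBounds:
    """Green-filter bounds; hue in degrees [0, 360)."""
    hue_lo: float = 60.0
    hue_hi: float = 170.0
    sat_min: float = 0.15
    val_min: float = 0.15


def load_pair(image_path, mask_path) -> tuple[ImagePatch, ClassMask]:
    """Load a patch/mask pair, validating extent and label range."""
    image_path, mask_path = Path(image_path), Path(mask_path)
    img = np.asarray(Image.open(image_path).convert("RGB"))
    raw = np.asarray(Image.open(mask_path))
    if raw.ndim != 2:
        raise ValueError(f"mask {mask_path} is not single-channel")
    vals = set(np.unique(raw))
    if vals <= {0, 128, 255} and not vals <= VALID_LABELS:
        warnings.warn(f"mask {mask_path} uses the 0/128/255 dialect; remapping to 0/1/2")
        raw = np.select([raw == 128, raw == 255], [1, 2], default=0).astype(np.uint8)
    bad = set(np.unique(raw)) - VALID_LABELS
    if bad:
        raise ValueError(f"mask {mask_path} has out-of-range labels {sorted(bad)}")
    if img.shape[:2] != raw.shape:
        raise ValueError(
            f"extent mismatch between {image_path} ({img.shape[:2]}) and "
            f"{mask_path} ({raw.shape})")
    return ImagePatch(img, source_id=image_path.stem), ClassMask(raw)


def save_pair(patch: ImagePatch, mask: ClassMask, image_path, mask_path) -> None:
    Image.fromarray(patch.pixels.astype(np.uint8), mode="RGB").save(image_path)
    Image.fromarray(mask.labels.astype(np.uint8), mode="L").save(mask_path)


def standardize(patch: ImagePatch | np.ndarray) -> np.ndarray:
    """Scale to [0, 1] then standardize with the ImageNet channel statistics."""
    pix = patch.pixels if isinstance(patch, ImagePatch) else np.asarray(patch)
    return (pix.astype(np.float32) / 255.0 - IMAGENET_MEAN) / IMAGENET_STD


def split_dataset(items, spec: SplitSpec) -> tuple[list, list, list]:
    """Random whole-item split into train/val/test.

    Train and validation sizes are the rounded fractions; the test set takes
    the remainder (e.g. 1584 items at 0.8/0.1/0.1 -> 1267/158/159).
    Deterministic for a given seed.
    """
    items = list(items)
    if len(items) < 10:
        raise ValueError("need at least 10 items to split")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(items))
    n = len(items)
    n_train = int(round(n * spec.fractions[0]))
    n_val = int(round(n * spec.fractions[1]))
    n_train = min(n_train, n - 2)
    n_val = min(n_val, n - n_train - 1)
    train = [items[i] for i in order[:n_train]]
    val = [items[i] for i in order[n_train:n_train + n_val]]
    test = [items[i] for i in order[n_train + n_val:]]
    return train, val, test


def green_mask_hsv(patch: ImagePatch | np.ndarray,
                   bounds: HSVBounds = HSVBounds()) -> np.ndarray:
    """Binary vegetation mask from an HSV green filter.

    A pixel is vegetation iff hue ∈ [hue_lo, hue_hi] (degrees), saturation
    ≥ sat_min and value ≥ val_min.
    """
    pix = patch.pixels if isinstance(patch, ImagePatch) else np.asarray(patch)
    hsv = rgb2hsv(pix.astype(np.float32) / 255.0)
    hue = hsv[..., 0] * 360.0
    return ((hue >= bounds.hue_lo) & (hue <= bounds.hue_hi)
            & (hsv[..., 1] >= bounds.sat_min)
            & (hsv[..., 2] >= bounds.val_min)).astype(np.uint8)


def _mask_distance(a: np.ndarray, b: np.ndarray, metric: str) -> float:
    if metric == "hamming":
        return float(np.count_nonzero(a != b))
    if metric == "one_minus_iou":
        union = np.count_nonzero(a | b)
        if union == 0:
            return 0.0
        return 1.0 - np.count_nonzero(a & b) / union
    raise ValueError(f"unknown metric {metric!r}")


def match_masks(patches: dict, gt_masks: dict,
                bounds: HSVBounds = HSVBounds(),
                metric: str = "hamming") -> tuple[dict, list]:
    """Re-associate each patch with its nearest ground-truth mask.

    For every patch, an HSV-extracted vegetation mask is compared against
    the vegetation support (label ∈ {1, 2}) of *every* candidate mask; the
    mask at minimum distance wins (1-nearest-neighbor).  Distance ties break
    lexicographically by mask id and are reported in the second return
    value.  Ground-truth content is never altered.
    """
    if len(patches) != len(gt_masks):
        raise ValueError("patch and mask collections must have equal size")
    supports = {mid: m.vegetation_support() for mid, m in gt_masks.items()}
    mapping: dict = {}
    ambiguous: list = []
    for pid in sorted(patches):
        green = green_mask_hsv(patches[pid], bounds)
        dists = {mid: _mask_distance(green, sup, metric)
                 for mid, sup in sorted(supports.items())}
        dmin = min(dists.values())
        winners = sorted(mid for mid, d in dists.items() if d == dmin)
        if len(winners) > 1:
            ambiguous.append((pid, winners))
        mapping[pid] = winners[0]
    return mapping, ambiguous


def to_binary_targets(mask: ClassMask | np.ndarray) -> BinaryTargets:
    """Decompose a 3-class mask into vegetation/crop/weed binary targets."""
    labels = mask.labels if isinstance(mask, ClassMask) else np.asarray(mask)
    return BinaryTargets(
        g_veg=(labels > 0).astype(np.float32),
        g_crop=(labels == 1).astype(np.float32),
        g_weed=(labels == 2).astype(np.float32),
    )


# -- manifests ---------------------------------------------------------------

_MANIFEST_FIELDS = ("image", "mask", "campaign", "split")


def write_manifest(rows, path) -> None:
    """Write a dataset manifest CSV with columns image, mask, campaign, split."""
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_MANIFEST_FIELDS)
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row.get(k, "") for k in _MANIFEST_FIELDS})


def read_manifest(path, exclude_campaigns=()) -> list[dict]:
    """Read a manifest, optionally filtering out listed campaigns."""
    exclude = {str(c) for c in exclude_campaigns}
    with open(path, newline="") as fh:
        rows = [dict(r) for r in csv.DictReader(fh)]
    return [r for r in rows if str(r.get("campaign", "")) not in exclude]


def write_repair_csv(mapping: dict, path) -> None:
    """Record the repair outcome: old mask name -> matched mask name."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patch_id", "matched_mask_id"])
        for pid, mid in sorted(mapping.items()):
            writer.writerow([pid, mid])
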