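"""Hierarchical label consistency: vegetation ⊇ crop, weed = residual vegetation.

A pixel can only be crop if it is vegetation, so the crop probability is
softly suppressed outside predicted vegetation::

    P̂_crop = P_crop · P_veg^γ          (γ = 0.75 by default)

and the weed probability is derived logically rather than predicted::

    P_weed = max(P_veg − P̂_crop, 0)

The soft residual keeps boundary uncertainty from both maps, which behaves
better than a hard XOR of binarized masks.  The final 3-class mask is
assembled by thresholding, crop taking precedence over weed.

All functions accept either NumPy arrays or autodiff Tensors, so the same
code path runs at training time (differentiably) and at inference.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["GAMMA_DEFAULT", "THRESHOLD_DEFAULT", "constrain_crop",
           "derive_weed", "assemble_mask"]

GAMMA_DEFAULT = 0.75
THRESHOLD_DEFAULT = 0.3

_P_FLOOR = 1e-6  # keeps the γ-power differentiable at P_veg = 0


def constrain_crop(p_crop, p_veg, gamma: float = GAMMA_DEFAULT):
    """Scale crop probability by the vegetation prediction: ``P_crop · P_veg^γ``.

    Nondecreasing in both arguments; equals ``P_crop`` where vegetation is
    certain and vanishes where vegetation probability is zero.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if isinstance(p_crop, Tensor) or isinstance(p_veg, Tensor):
        p_crop = p_crop if isinstance(p_crop, Tensor) else Tensor(p_crop)
        p_veg = p_veg if isinstance(p_veg, Tensor) else Tensor(p_veg)
        return p_crop * (p_veg.clip(_P_FLOOR, 1.0) ** gamma)
    return np.asarray(p_crop) * np.asarray(p_veg) ** gamma


def derive_weed(p_veg, p_crop_hat):
    """Residual vegetation: ``P_veg − P̂_crop`` where nonnegative, else 0."""
    if isinstance(p_veg, Tensor) or isinstance(p_crop_hat, Tensor):
        p_veg = p_veg if isinstance(p_veg, Tensor) else Tensor(p_veg)
        p_crop_hat = p_crop_hat if isinstance(p_crop_hat, Tensor) else Tensor(p_crop_hat)
        return (p_veg - p_crop_hat).relu()
    return np.maximum(np.asarray(p_veg) - np.asarray(p_crop_hat), 0.0)


def assemble_mask(p_crop_hat: np.ndarray, p_weed: np.ndarray,
                  thresholds: tuple[float, float] = (THRESHOLD_DEFAULT, THRESHOLD_DEFAULT)
                  ) -> np.ndarray:
    """Threshold the probability maps into a {0, 1, 2} class mask.

    A pixel is crop (1) if ``P̂_crop >= t_crop``; otherwise weed (2) if
    ``P_weed >= t_weed``; otherwise background (0).  Crop takes precedence
    because it is directly predicted while weed is a lower-confidence
    residual.  ``t_weed`` may be set below ``t_crop`` since subtraction
    lowers the magnitude of weed probabilities.
    """
    t_crop, t_weed = thresholds
    for t in (t_crop, t_weed):
        if not 0.0 < t < 1.0:
            raise ValueError(f"thresholds must lie in (0, 1), got {thresholds}")
    p_crop_hat = np.asarray(p_crop_hat)
    p_weed = np.asarray(p_weed)
    if p_crop_hat.shape != p_weed.shape:
        raise ValueError("probability rasters must share an extent")
    mask = np.zeros(p_crop_hat.shape, dtype=np.uint8)
    mask[p_weed >= t_weed] = 2
    mask[p_crop_hat >= t_crop] = 1
    return mask
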