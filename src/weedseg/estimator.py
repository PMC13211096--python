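"""Scikit-learn style estimator wrapping the full segmentation pipeline.

``HierarchicalUNetSegmenter`` behaves like a classifier over pixels: ``fit``
trains the dual-head U-Net on (image, mask) pairs, ``predict`` returns
{0,1,2} class masks, and ``score`` reports the mean of crop and weed Dice.
Hyperparameters follow the sklearn convention (constructor args mirrored by
``get_params``/``set_params``), so the estimator composes with sklearn
model-selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import train as training
from .data_io import ClassMask, ImagePatch
from .losses import LossWeights
from .unet import DecoderConfig

__all__ = ["HierarchicalUNetSegmenter"]


def _as_patches(X) -> list[ImagePatch]:
    if isinstance(X, np.ndarray) and X.ndim == 4:
        X = list(X)
    return [x if isinstance(x, ImagePatch) else ImagePatch(np.asarray(x)) for x in X]


def _as_masks(y) -> list[ClassMask]:
    if isinstance(y, np.ndarray) and y.ndim == 3:
        y = list(y)
    return [m if isinstance(m, ClassMask) else ClassMask(np.asarray(m)) for m in y]


class HierarchicalUNetSegmenter(BaseEstimator):
    """Single-stage hierarchical crop/weed segmenter.

    Parameters
    ----------
    backbone : str
        Encoder registry name (``"fixture_tiny"`` for CPU-scale work,
        ``"convnextv2_tiny"`` for the full reference model).
    epochs, lr, weight_decay, batch_size : training protocol knobs
        (AdamW + cosine annealing; defaults follow the published protocol).
    gamma : float
        Exponent of the vegetation scaling in the crop constraint.
    threshold_crop, threshold_weed : float
        Binarization thresholds for mask assembly.
    val_fraction : float
        Fraction of the training data held out for best-checkpoint selection;
        when the held-out set would be empty, training data doubles as
        validation (useful for overfitting smoke runs).
    seed : int
        Controls initialization and data order; CPU runs are deterministic.

    Attributes
    ----------
    model_ : HierarchicalUNet
        The trained network (best-validation weights).
    history_ : list of dict
        Per-step loss components.
    best_score_, best_epoch_ : float, int
        Validation mean crop/weed Dice of the kept checkpoint.
    """

    def __init__(self, backbone: str = "fixture_tiny", epochs: int = 50,
                 lr: float = 1e-4, weight_decay: float = 1e-4,
                 batch_size: int = 4, gamma: float = 0.75,
                 threshold_crop: float = 0.3, threshold_weed: float = 0.3,
                 val_fraction: float = 0.1, seed: int = 0,
                 warmup_steps: int = 0, grad_clip: float | None = 1.0,
                 loss_weights: LossWeights | None = None,
                 decoder: DecoderConfig | None = None):
        self.backbone = backbone
        self.epochs = epochs
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.gamma = gamma
        self.threshold_crop = threshold_crop
        self.threshold_weed = threshold_weed
        self.val_fraction = val_fraction
        self.seed = seed
        self.warmup_steps = warmup_steps
        self.grad_clip = grad_clip
        self.loss_weights = loss_weights
        self.decoder = decoder

    def _config(self) -> training.TrainConfig:
        return training.TrainConfig(
            backbone=self.backbone, lr=self.lr, weight_decay=self.weight_decay,
            epochs=self.epochs, batch_size=self.batch_size, seed=self.seed,
            warmup_steps=self.warmup_steps, grad_clip=self.grad_clip,
            gamma=self.gamma,
            thresholds=(self.threshold_crop, self.threshold_weed),
            loss_weights=self.loss_weights or LossWeights(),
            decoder=self.decoder)

    def fit(self, X, y):
        patches = _as_patches(X)
        masks = _as_masks(y)
        if len(patches) != len(masks):
            raise ValueError("X and y must have equal length")
        pairs = list(zip(patches, masks))
        rng = np.random.default_rng(self.seed)
        n_val = int(round(self.val_fraction * len(pairs)))
        if 0 < n_val < len(pairs):
            order = rng.permutation(len(pairs))
            val = [pairs[i] for i in order[:n_val]]
            tr = [pairs[i] for i in order[n_val:]]
        else:
            tr, val = pairs, pairs
        result = training.train(self._config(), tr, val)
        self.model_ = result.model
        self.history_ = result.history
        self.best_score_ = result.best_score
        self.best_epoch_ = result.best_epoch
        return self

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        masks = []
        for patch in _as_patches(X):
            probs = training.predict_probabilities(self.model_, patch, self.gamma)
            masks.append(training.hierarchy.assemble_mask(
                probs["p_crop_hat"], probs["p_weed"],
                (self.threshold_crop, self.threshold_weed)))
        return np.stack(masks)

    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel maps stacked as (n, 3, H, W): (1−P_veg, P̂_crop, P_weed).

        The channels express the hierarchical heads rather than a normalized
        categorical distribution.
        """
        self._check_fitted()
        out = []
        for patch in _as_patches(X):
            probs = training.predict_probabilities(self.model_, patch, self.gamma)
            out.append(np.stack([1.0 - probs["p_veg"], probs["p_crop_hat"],
                                 probs["p_weed"]]))
        return np.stack(out)

    def score(self, X, y) -> float:
        """Mean of crop and weed Dice over the given set (micro-averaged)."""
        self._check_fitted()
        pairs = list(zip(_as_patches(X), _as_masks(y)))
        rep = training.evaluate(self.model_, pairs,
                                (self.threshold_crop, self.threshold_weed),
                                gamma=self.gamma)
        return 0.5 * (rep.dice["crop"] + rep.dice["weed"])

    def evaluate(self, X, y):
        """Full metrics report (per-class IoU/Dice, mIoU, accuracy, kappa)."""
        self._check_fitted()
        pairs = list(zip(_as_patches(X), _as_masks(y)))
        return training.evaluate(self.model_, pairs,
                                 (self.threshold_crop, self.threshold_weed),
                                 gamma=self.gamma)

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit() first")
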