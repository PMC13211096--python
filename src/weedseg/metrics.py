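"""Confusion-matrix evaluation: per-class IoU/Dice, mIoU, accuracy, Cohen's kappa.

Scores aggregate micro-style: confusion matrices are summed over all test
patches before any ratio is taken, so large and small patches contribute by
pixel count.  mIoU averages all three classes (background, crop, weed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hierarchy import assemble_mask

__all__ = ["CLASS_NAMES", "MetricsReport", "confusion", "scores", "threshold_sweep"]

CLASS_NAMES = ("background", "crop", "weed")
N_CLASSES = 3


@dataclass
class MetricsReport:
    iou: dict
    dice: dict
    miou: float
    overall_accuracy: float
    kappa: float
    threshold: tuple[float, float] | None = None
    images_per_second: float | None = None

    def to_dict(self) -> dict:
        out = {
            "iou": self.iou, "dice": self.dice, "miou": self.miou,
            "overall_accuracy": self.overall_accuracy, "kappa": self.kappa,
            "aggregation": "micro (confusions summed over patches)",
        }
        if self.threshold is not None:
            out["threshold"] = {"crop": self.threshold[0], "weed": self.threshold[1]}
        if self.images_per_second is not None:
            out["images_per_second"] = self.images_per_second
        return out


def confusion(reference: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """3x3 confusion matrix; rows index the reference class, columns the prediction."""
    reference = np.asarray(reference)
    predicted = np.asarray(predicted)
    if reference.shape != predicted.shape:
        raise ValueError(
            f"extent mismatch: reference {reference.shape} vs predicted {predicted.shape}")
    idx = reference.astype(np.int64).ravel() * N_CLASSES + predicted.astype(np.int64).ravel()
    return np.bincount(idx, minlength=N_CLASSES * N_CLASSES).reshape(N_CLASSES, N_CLASSES)


def scores(cm: np.ndarray, threshold: tuple[float, float] | None = None) -> MetricsReport:
    """Metrics from a confusion matrix.

    IoU_c = TP/(TP+FP+FN), Dice_c = 2TP/(2TP+FP+FN); a class absent from both
    reference and prediction scores 1 by convention.  Overall accuracy is the
    diagonal fraction and kappa the chance-corrected agreement computed from
    the row/column marginals.
    """
    cm = np.asarray(cm, dtype=np.float64)
    total = cm.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    tp = np.diag(cm)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    iou = np.where(tp + fp + fn > 0, tp / np.maximum(tp + fp + fn, 1e-300), 1.0)
    dice = np.where(2 * tp + fp + fn > 0, 2 * tp / np.maximum(2 * tp + fp + fn, 1e-300), 1.0)
    oa = tp.sum() / total
    pe = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / total**2
    kappa = 1.0 if pe == 1.0 else (oa - pe) / (1.0 - pe)
    return MetricsReport(
        iou={n: float(v) for n, v in zip(CLASS_NAMES, iou)},
        dice={n: float(v) for n, v in zip(CLASS_NAMES, dice)},
        miou=float(iou.mean()),
        overall_accuracy=float(oa),
        kappa=float(kappa),
        threshold=threshold,
    )


def threshold_sweep(prob_pairs, references, grid=None):
    """Select binarization thresholds on a validation set.

    Parameters
    ----------
    prob_pairs : sequence of (P̂_crop, P_weed) arrays
        Hierarchically constrained probability maps per patch.
    references : sequence of {0,1,2} masks.
    grid : iterable of float, default 0.10..0.50 step 0.05
        Candidate thresholds; every (t_crop, t_weed) combination is scored.

    Returns
    -------
    (best_t_crop, best_t_weed), table
        The pair maximizing the mean of crop and weed Dice, and the full
        per-combination list of ``(t_crop, t_weed, MetricsReport)`` rows.
    """
    if grid is None:
        grid = np.round(np.arange(0.10, 0.501, 0.05), 2)
    grid = [float(t) for t in grid]
    if not grid:
        raise ValueError("threshold grid is empty")
    prob_pairs = list(prob_pairs)
    references = list(references)
    table = []
    best = None
    for t_crop in grid:
        for t_weed in grid:
            cm = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
            for (pc, pw), ref in zip(prob_pairs, references):
                pred = assemble_mask(pc, pw, (t_crop, t_weed))
                cm += confusion(ref, pred)
            rep = scores(cm, threshold=(t_crop, t_weed))
            key = 0.5 * (rep.dice["crop"] + rep.dice["weed"])
            table.append((t_crop, t_weed, rep))
            if best is None or key > best[0]:
                best = (key, (t_crop, t_weed))
    return best[1], table
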