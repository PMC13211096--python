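"""Training loop, checkpointing, evaluation and prediction.

Protocol: AdamW (lr 1e-4, weight decay 1e-4 by default), cosine-annealed
learning rate over the full run, 50 epochs, and best-validation
checkpointing where the validation score is the mean of crop and weed Dice
at the configured thresholds.  Images are standardized with ImageNet
statistics; every loss component is logged per step.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import hierarchy, losses, metrics
from .autodiff import Tensor, no_grad
from .data_io import ClassMask, ImagePatch, standardize, to_binary_targets
from .losses import LossWeights
from .optim import AdamW, cosine_lr
from .unet import DecoderConfig, HierarchicalUNet, build_model, default_decoder_config

__all__ = ["TrainConfig", "TrainResult", "train", "evaluate", "predict",
           "save_checkpoint", "load_checkpoint", "forward_hierarchy"]


@dataclass
class TrainConfig:
    backbone: str = "fixture_tiny"
    lr: float = 1e-4
    weight_decay: float = 1e-4
    epochs: int = 50
    batch_size: int = 4
    seed: int = 0
    grad_clip: float | None = 1.0
    warmup_steps: int = 0
    gamma: float = hierarchy.GAMMA_DEFAULT
    thresholds: tuple[float, float] = (0.3, 0.3)
    loss_weights: LossWeights = field(default_factory=LossWeights)
    decoder: DecoderConfig | None = None

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainResult:
    model: HierarchicalUNet
    config: TrainConfig
    best_state: dict
    best_score: float
    best_epoch: int
    history: list


def _to_batch(pairs) -> tuple[np.ndarray, dict]:
    """Stack (patch, mask) pairs into NCHW inputs and binary target arrays."""
    xs, gv, gc, gw = [], [], [], []
    for patch, mask in pairs:
        xs.append(standardize(patch).transpose(2, 0, 1))
        t = to_binary_targets(mask)
        gv.append(t.g_veg[None])
        gc.append(t.g_crop[None])
        gw.append(t.g_weed[None])
    return (np.stack(xs).astype(np.float32),
            {"veg": np.stack(gv), "crop": np.stack(gc), "weed": np.stack(gw)})


def forward_hierarchy(model: HierarchicalUNet, x: Tensor, gamma: float,
                      with_aux: bool = True):
    """Forward pass plus the hierarchical constraint and weed derivation."""
    out = model.forward(x, with_aux=with_aux)
    p_crop_hat = hierarchy.constrain_crop(out.p_crop, out.p_veg, gamma)
    p_weed = hierarchy.derive_weed(out.p_veg, p_crop_hat)
    return out, p_crop_hat, p_weed


def _batch_loss(model, batch_pairs, cfg: TrainConfig):
    x_np, targets = _to_batch(batch_pairs)
    x = Tensor(x_np)
    out, p_crop_hat, p_weed = forward_hierarchy(model, x, cfg.gamma, with_aux=True)
    gv, gc, gw = (Tensor(targets[k]) for k in ("veg", "crop", "weed"))
    l_veg, l_crop, l_weed = losses.head_losses(
        out.p_veg, p_crop_hat, p_weed, gv, gc, gw, cfg.loss_weights)
    aux_terms = [losses.aux_loss(a, gv, gc) for a in out.aux]
    total = losses.total_loss((l_veg, l_crop, l_weed), aux_terms, cfg.loss_weights)
    parts = {"veg": l_veg.item(), "crop": l_crop.item(), "weed": l_weed.item(),
             "aux": [a.item() for a in aux_terms], "total": total.item()}
    return total, parts


def _clip_grad_norm(params, max_norm: float) -> None:
    """Scale gradients so their global L2 norm is at most ``max_norm``.

    Prevents early optimizer steps from saturating the head sigmoids (a
    frozen all-ones/all-zeros prediction with vanished gradients).
    """
    total = 0.0
    grads = [p.grad for p in params if p.grad is not None]
    for g in grads:
        total += float((g * g).sum())
    norm = np.sqrt(total)
    if norm > max_norm:
        scale = max_norm / (norm + 1e-12)
        for g in grads:
            g *= scale


def _validation_score(model, val_pairs, cfg: TrainConfig) -> float:
    """Mean of crop and weed Dice on a validation set at the configured thresholds."""
    rep = evaluate(model, val_pairs, cfg.thresholds, gamma=cfg.gamma)
    return 0.5 * (rep.dice["crop"] + rep.dice["weed"])


def train(config: TrainConfig, train_pairs, val_pairs,
          out_dir: str | Path | None = None) -> TrainResult:
    """Train a model, keeping the best-validation-score weights.

    Raises ``RuntimeError`` on non-finite loss (divergence).
    """
    if not train_pairs or not val_pairs:
        raise ValueError("training and validation sets must be nonempty")
    model = build_model(config.backbone, config.decoder, seed=config.seed)
    opt = AdamW(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    rng = np.random.default_rng(config.seed)
    history: list[dict] = []
    best_state, best_score, best_epoch = model.state_dict(), -np.inf, -1
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_pairs))
        for start in range(0, len(order), config.batch_size):
            epoch_lr = cosine_lr(config.lr, epoch, config.epochs)
            if step < config.warmup_steps:
                # linear warmup keeps early Adam steps from saturating the heads
                epoch_lr *= (step + 1) / config.warmup_steps
            opt.lr = epoch_lr
            batch = [train_pairs[i] for i in order[start:start + config.batch_size]]
            total, parts = _batch_loss(model, batch, config)
            if not np.isfinite(parts["total"]):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}, step {step}: "
                    f"loss components {parts}")
            opt.zero_grad()
            total.backward()
            if config.grad_clip:
                _clip_grad_norm(model.parameters(), config.grad_clip)
            opt.step()
            history.append({"epoch": epoch, "step": step, "lr": opt.lr, **parts})
            step += 1
        score = _validation_score(model, val_pairs, config)
        history[-1]["val_score"] = score
        if score > best_score:
            best_score, best_epoch = score, epoch
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    result = TrainResult(model=model, config=config, best_state=best_state,
                         best_score=best_score, best_epoch=best_epoch,
                         history=history)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_checkpoint(result.model, config, out / "checkpoint.npz")
        _write_history(history, out / "history.csv")
        (out / "manifest.json").write_text(json.dumps({
            "config": _config_dict(config),
            "n_train": len(train_pairs), "n_val": len(val_pairs),
            "best_epoch": best_epoch, "best_val_score": best_score,
        }, indent=2))
    return result


def _write_history(history, path) -> None:
    import csv
    keys = ["epoch", "step", "lr", "veg", "crop", "weed", "total", "val_score"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(keys + ["aux1", "aux2", "aux3"])
        for row in history:
            writer.writerow([row.get(k, "") for k in keys] + list(row.get("aux", [])))


def predict_probabilities(model: HierarchicalUNet, patch: ImagePatch | np.ndarray,
                          gamma: float = hierarchy.GAMMA_DEFAULT) -> dict:
    """Per-head probability maps for one patch (no thresholding)."""
    x = standardize(patch).transpose(2, 0, 1)[None]
    h, w = x.shape[2], x.shape[3]
    ph, pw = (-h) % 32, (-w) % 32
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
    with no_grad():
        out, p_crop_hat, p_weed = forward_hierarchy(
            model, Tensor(x), gamma, with_aux=False)
    sl = (0, slice(0, 1), slice(0, h), slice(0, w))
    return {
        "p_veg": out.p_veg.data[sl][0],
        "p_crop": out.p_crop.data[sl][0],
        "p_crop_hat": p_crop_hat.data[sl][0],
        "p_weed": p_weed.data[sl][0],
    }


def evaluate(model: HierarchicalUNet, test_pairs,
             thresholds: tuple[float, float] = (0.3, 0.3),
             gamma: float = hierarchy.GAMMA_DEFAULT) -> metrics.MetricsReport:
    """Forward → hierarchy → threshold → micro-averaged scores.

    Also measures throughput (images/second) over the full loop, reported
    informationally on the metrics object.
    """
    test_pairs = list(test_pairs)
    if not test_pairs:
        raise ValueError("test set is empty")
    cm = np.zeros((3, 3), dtype=np.int64)
    t0 = time.perf_counter()
    for patch, mask in test_pairs:
        probs = predict_probabilities(model, patch, gamma)
        pred = hierarchy.assemble_mask(probs["p_crop_hat"], probs["p_weed"], thresholds)
        labels = mask.labels if isinstance(mask, ClassMask) else np.asarray(mask)
        cm += metrics.confusion(labels, pred)
    elapsed = time.perf_counter() - t0
    rep = metrics.scores(cm, threshold=thresholds)
    rep.images_per_second = len(test_pairs) / max(elapsed, 1e-9)
    return rep


def predict(model: HierarchicalUNet, image_paths, out_dir,
            thresholds: tuple[float, float] = (0.3, 0.3),
            gamma: float = hierarchy.GAMMA_DEFAULT,
            save_probabilities: bool = False) -> list[Path]:
    """Write {0,1,2} PNG masks (and optional probability maps) per image."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for path in image_paths:
        path = Path(path)
        try:
            img = np.asarray(Image.open(path).convert("RGB"))
        except Exception as exc:  # unreadable input: skip, keep going
            warnings.warn(f"skipping unreadable image {path}: {exc}")
            continue
        probs = predict_probabilities(model, img, gamma)
        pred = hierarchy.assemble_mask(probs["p_crop_hat"], probs["p_weed"], thresholds)
        mask_path = out / f"{path.stem}_mask.png"
        Image.fromarray(pred, mode="L").save(mask_path)
        if save_probabilities:
            np.savez(out / f"{path.stem}_probs.npz", **probs)
        written.append(mask_path)
    if not written:
        raise RuntimeError("no input image could be read")
    return written


# -- checkpointing -----------------------------------------------------------


def _config_dict(config: TrainConfig) -> dict:
    d = asdict(config)
    d["decoder"] = asdict(config.decoder) if config.decoder else None
    return d


def save_checkpoint(model: HierarchicalUNet, config: TrainConfig, path) -> None:
    """Single-file checkpoint: weights + config + backbone name (npz)."""
    meta = {
        "config": _config_dict(config),
        "backbone": model.backbone_name or config.backbone,
        "decoder": asdict(model.config),
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.state_dict())


def load_checkpoint(path) -> tuple[HierarchicalUNet, TrainConfig]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    cfg_d = dict(meta["config"])
    cfg_d["thresholds"] = tuple(cfg_d["thresholds"])
    cfg_d["loss_weights"] = LossWeights(**cfg_d["loss_weights"])
    cfg_d["decoder"] = DecoderConfig(**meta["decoder"])
    cfg_d["decoder"].up_channels = tuple(cfg_d["decoder"].up_channels)
    config = TrainConfig(**cfg_d)
    model = build_model(meta["backbone"], config.decoder, seed=config.seed)
    model.load_state_dict(state)
    return model, config
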