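"""Training and evaluation engine.

Loads samples from a CSV manifest (``image,mask,label,split``), runs the
joint classification + segmentation objective with RMSprop, and provides the
evaluation, cross-validation and gamma-sweep harnesses.  Everything is
driven by a single seed: weight init, shuffling and augmentation are
reproducible run to run.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.model_selection import StratifiedKFold

from .config import TrainConfig
from .metrics import ConfusionCounts, EvalReport, compute_metrics
from .model import STNet
from .nn.optim import RMSprop, SGD
from .objectives import joint_loss
from .synthetic import load_image, load_mask

__all__ = ["train", "evaluate", "cross_validate", "gamma_sweep",
           "TrainResult", "load_batch"]


def _resize(img: np.ndarray, size: int, order: int = 1) -> np.ndarray:
    """Resize a HxW or HxWxC array to size x size (spline interpolation)."""
    if img.shape[0] == size and img.shape[1] == size:
        return img
    factors = (size / img.shape[0], size / img.shape[1]) + (1,) * (img.ndim - 2)
    return ndimage.zoom(img, factors, order=order, grid_mode=True, mode="nearest")


def _augment(img: np.ndarray, mask: np.ndarray | None, rng: np.random.Generator,
             rotation_deg: float, crop_fraction: float):
    """Random rotation and random cropping, applied identically to the image
    and its mask."""
    angle = rng.uniform(-rotation_deg, rotation_deg)
    img = ndimage.rotate(img, angle, axes=(0, 1), reshape=False, order=1,
                         mode="nearest")
    if mask is not None:
        mask = ndimage.rotate(mask, angle, axes=(0, 1), reshape=False, order=0,
                              mode="nearest")
    size = img.shape[0]
    crop = max(int(round(size * crop_fraction)), 1)
    top = rng.integers(0, size - crop + 1)
    left = rng.integers(0, size - crop + 1)
    img = _resize(img[top:top + crop, left:left + crop], size)
    if mask is not None:
        mask = _resize(mask[top:top + crop, left:left + crop], size, order=0)
    return np.clip(img, 0.0, 1.0), mask


def load_batch(rows: pd.DataFrame, image_size: int,
               rng: np.random.Generator | None = None,
               rotation_deg: float = 30.0, crop_fraction: float = 0.875):
    """Load (and optionally augment) a manifest chunk.

    Returns images (N,3,H,W), labels (N,), masks (N,H,W) and a boolean
    mask-availability vector; rows without a mask get an all-zero placeholder
    that the loss never reads.
    """
    images, labels, masks, avail = [], [], [], []
    for _, row in rows.iterrows():
        img = _resize(load_image(row["image"]), image_size)
        mask_path = row.get("mask", "")
        has_mask = isinstance(mask_path, str) and mask_path != ""
        mask = _resize(load_mask(mask_path), image_size, order=0) if has_mask \
            else None
        if rng is not None:
            img, mask = _augment(img, mask, rng, rotation_deg, crop_fraction)
        images.append(img.transpose(2, 0, 1))
        labels.append(int(row["label"]))
        masks.append(mask if mask is not None
                     else np.zeros((image_size, image_size)))
        avail.append(has_mask)
    return (np.stack(images), np.asarray(labels, dtype=np.float64),
            np.stack(masks), np.asarray(avail, dtype=bool))


@dataclass
class TrainResult:
    model: STNet
    log: pd.DataFrame
    best_val_f1: float
    best_state: dict


def _build_model(config: TrainConfig) -> STNet:
    return STNet(depth=config.depth, pgc_enabled=config.pgc_enabled,
                 deformable_stages=config.deformable_stages,
                 reduction_ratio=config.reduction_ratio,
                 grad_scale=config.alpha, caff_enabled=config.caff_enabled,
                 with_decoder=config.with_decoder, seed=config.seed,
                 pretrained_texture_path=config.pretrained_texture_path)


def _make_optimizer(config: TrainConfig, params):
    if config.optimizer == "rmsprop":
        return RMSprop(params, lr=config.learning_rate,
                       momentum=config.momentum,
                       weight_decay=config.weight_decay)
    if config.optimizer == "sgd":
        return SGD(params, lr=config.learning_rate, momentum=config.momentum,
                   weight_decay=config.weight_decay)
    raise ValueError(f"unknown optimizer {config.optimizer!r}")


def train(config: TrainConfig, manifest: pd.DataFrame,
          work_dir: str | None = None) -> TrainResult:
    """Train on the manifest's ``train`` split, checkpointing best val F1.

    Rows with an empty ``split`` tag are treated as training data; the shape
    loss covers only mask-bearing samples and the run completes (pure
    classification) when the manifest has no masks at all.
    """
    train_rows = manifest[manifest["split"].isin(["train", ""])]
    val_rows = manifest[manifest["split"] == "val"]
    if train_rows.empty:
        raise ValueError("manifest has no training rows")
    if sorted(train_rows["label"].unique()) != [0, 1]:
        raise ValueError("training split needs at least one sample per class")

    model = _build_model(config)
    optimizer = _make_optimizer(config, model.parameters())
    rng = np.random.default_rng(config.seed)
    records = []
    best_f1, best_state = -1.0, model.state_dict()
    step = 0
    done = False
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_rows))
        for start in range(0, len(order), config.batch_size):
            rows = train_rows.iloc[order[start:start + config.batch_size]]
            aug_rng = rng if config.augment else None
            images, labels, masks, avail = load_batch(
                rows, config.image_size, aug_rng,
                config.rotation_deg, config.crop_fraction)
            model.train()
            out = model(images)
            mask_pred = (out.mask_pred.reshape(out.mask_pred.shape[0],
                                               *out.mask_pred.shape[2:])
                         if out.mask_pred is not None else None)
            total, l_cls, l_shp = joint_loss(
                out.p, labels, mask_pred, masks, avail,
                params=config.loss_params, weights=config.joint_weights,
                loss_type=config.loss_type)
            optimizer.zero_grad()
            total.backward()
            optimizer.step()
            records.append({"step": step, "epoch": epoch, "loss_cls": l_cls,
                            "loss_shp": l_shp, "lr": config.learning_rate})
            step += 1
            if config.max_steps is not None and step >= config.max_steps:
                done = True
                break
        if not val_rows.empty:
            report = evaluate(model, val_rows, config.image_size,
                              config.batch_size)
            records[-1]["val_f1"] = report.f1
            if report.f1 > best_f1:
                best_f1, best_state = report.f1, model.state_dict()
        else:
            best_f1, best_state = float("nan"), model.state_dict()
        if done:
            break
    if not val_rows.empty:
        model.load_state_dict(best_state)
    log = pd.DataFrame(records)
    if work_dir is not None:
        work_dir = Path(work_dir)
        work_dir.mkdir(parents=True, exist_ok=True)
        log.to_csv(work_dir / "training_log.csv", index=False)
        np.savez(work_dir / "checkpoint.npz", **best_state)
        config.to_yaml(str(work_dir / "config.yaml"))
    return TrainResult(model, log, best_f1, best_state)


def predict_scores(model: STNet, rows: pd.DataFrame, image_size: int,
                   batch_size: int = 8) -> np.ndarray:
    scores = []
    for start in range(0, len(rows), batch_size):
        chunk = rows.iloc[start:start + batch_size]
        images, _, _, _ = load_batch(chunk, image_size)
        scores.append(model.predict_proba(images))
    return np.concatenate(scores)


def evaluate(model: STNet, rows: pd.DataFrame, image_size: int,
             batch_size: int = 8, threshold: float = 0.5) -> EvalReport:
    """Score a split: a sample is predicted malignant when p > threshold
    (strictly, so p = 0.5 is called benign)."""
    if rows.empty:
        raise ValueError("cannot evaluate an empty split")
    scores = predict_scores(model, rows, image_size, batch_size)
    y_true = rows["label"].to_numpy()
    counts = ConfusionCounts.from_predictions(y_true, scores > threshold)
    return compute_metrics(counts)


def cross_validate(manifest: pd.DataFrame, k: int, config: TrainConfig,
                   seed: int = 0) -> pd.DataFrame:
    """Stratified k-fold cross-validation; trains on k-1 folds, tests on the
    held-out fold, and reports per-fold metrics (F1 being the headline one
    for imbalanced data)."""
    labels = manifest["label"].to_numpy()
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > min(np.bincount(labels)):
        raise ValueError(f"k={k} exceeds the smallest class count")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    for fold, (train_idx, test_idx) in enumerate(skf.split(labels, labels)):
        fold_manifest = manifest.copy()
        fold_manifest.loc[:, "split"] = ""
        fold_manifest.iloc[train_idx, fold_manifest.columns.get_loc("split")] = "train"
        fold_manifest.iloc[test_idx, fold_manifest.columns.get_loc("split")] = "test"
        fold_config = TrainConfig(**{**vars(config), "seed": seed + fold})
        result = train(fold_config, fold_manifest)
        report = evaluate(result.model,
                          fold_manifest[fold_manifest["split"] == "test"],
                          config.image_size, config.batch_size)
        rows.append({"fold": fold, **report.as_dict()})
    return pd.DataFrame(rows)


def gamma_sweep(manifest: pd.DataFrame, gamma_minus_values,
                config: TrainConfig, out_csv: str | None = None) -> pd.DataFrame:
    """Train one seeded model per gamma_minus (gamma_plus fixed by the
    config) and tabulate test metrics."""
    rows = []
    for gm in gamma_minus_values:
        if gm < 0:
            raise ValueError("gamma_minus values must be >= 0")
        cfg = TrainConfig(**{**vars(config),
                             "gamma_minus": float(gm),
                             "gamma_plus": min(config.gamma_plus, float(gm))})
        result = train(cfg, manifest)
        test_rows = manifest[manifest["split"] == "test"]
        report = evaluate(result.model, test_rows, cfg.image_size,
                          cfg.batch_size)
        rows.append({"gamma_minus": gm, **report.as_dict()})
    table = pd.DataFrame(rows)
    if out_csv:
        table.to_csv(out_csv, index=False)
    return table
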