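"""Desk-scale mechanism experiments.

The headline behaviors of the method — the asymmetric loss lifting recall on
imbalanced data, and joint shape supervision lifting F1 when the shape cue
carries the class signal — are checked here as *directional* comparisons on
synthetic data with the tiny CPU profile (2-stage encoders, 64x64 images,
batch 8).  Problem sizes are kept small on purpose: a few dozen training
images and under a hundred optimization steps per run, which is enough for
the tiny network to express the effect while keeping a full comparison to a
few minutes on one CPU.

Every experiment is a pure function of its seed(s); all randomness (data,
weights, shuffling, augmentation) derives from them.
"""

from __future__ import annotations

import tempfile

import numpy as np
import pandas as pd

from . import pipeline
from .config import TrainConfig
from .synthetic import ClassParams, generate_dataset, split_manifest

__all__ = [
    "overfit_experiment",
    "imbalance_experiment",
    "joint_learning_experiment",
    "cross_validation_experiment",
]

# texture ranges made identical so boundary irregularity is the only class cue
SHAPE_ONLY_PARAMS = ClassParams(texture_benign=(0.05, 0.09),
                                texture_malignant=(0.05, 0.09))


def _dataset(n_mal, n_ben, seed, out_dir, mask_fraction=0.15,
             class_params=None):
    manifest = generate_dataset(
        n_mal, n_ben, mask_fraction=mask_fraction, image_size=64, seed=seed,
        out_dir=out_dir,
        class_params=class_params or ClassParams())
    return split_manifest(manifest, (6, 2, 2), seed=seed)


def overfit_experiment(seed: int = 0, n_steps: int = 200,
                       work_dir: str | None = None) -> float:
    """Train the tiny model to memorize 32 synthetic samples; returns final
    training accuracy (expected to reach 1.0 within ``n_steps`` steps)."""
    with tempfile.TemporaryDirectory() as tmp:
        out = work_dir or tmp
        manifest = generate_dataset(11, 21, mask_fraction=0.5, image_size=64,
                                    seed=seed, out_dir=out)
        manifest["split"] = "train"
        cfg = TrainConfig.tiny(seed=seed, epochs=10 ** 6, max_steps=n_steps,
                               augment=False)
        result = pipeline.train(cfg, manifest)
        scores = pipeline.predict_scores(result.model, manifest, 64)
        return float(np.mean((scores > 0.5) == manifest["label"].to_numpy()))


def imbalance_experiment(seeds=(0, 1, 2), n_mal: int = 30, n_ben: int = 90,
                         epochs: int = 8) -> pd.DataFrame:
    """Asymmetric loss vs plain cross-entropy on 1:3 imbalanced data.

    One model per (seed, loss type) on the same seeded dataset; returns a
    frame with test recall (and the other metrics) per run.  The asymmetric
    loss damps the gradient of the abundant easy negatives, so its recall on
    the rare malignant class is expected to match or beat cross-entropy's
    for most seeds.
    """
    rows = []
    for seed in seeds:
        with tempfile.TemporaryDirectory() as tmp:
            manifest = _dataset(n_mal, n_ben, seed, tmp)
            test_rows = manifest[manifest["split"] == "test"]
            for loss_type in ("asymmetric", "cross_entropy"):
                cfg = TrainConfig.tiny(seed=seed, epochs=epochs,
                                       loss_type=loss_type)
                result = pipeline.train(cfg, manifest)
                report = pipeline.evaluate(result.model, test_rows, 64)
                rows.append({"seed": seed, "loss": loss_type,
                             **report.as_dict()})
    return pd.DataFrame(rows)


def joint_learning_experiment(seeds=(0, 1, 2), n_mal: int = 24,
                              n_ben: int = 48, epochs: int = 30) -> pd.DataFrame:
    """Joint learning (beta > 0) vs no joint learning (beta = 0) when the
    shape cue carries the class signal.

    The dataset neutralizes the texture cue (same speckle range for both
    classes) and every sample carries a mask; the mask supervision can then
    teach the shape encoder boundary features the classifier needs.  The two
    runs per seed are identical in every respect (architecture, alpha, data,
    init) except beta, so the comparison isolates the joint-learning term.
    Returns best validation F1 per (seed, beta) run.
    """
    rows = []
    for seed in seeds:
        with tempfile.TemporaryDirectory() as tmp:
            manifest = _dataset(n_mal, n_ben, seed, tmp, mask_fraction=1.0,
                                class_params=SHAPE_ONLY_PARAMS)
            for beta in (1.0, 0.0):
                cfg = TrainConfig.tiny(seed=seed, epochs=epochs, beta=beta)
                result = pipeline.train(cfg, manifest)
                rows.append({"seed": seed, "beta": beta,
                             "val_f1": result.best_val_f1})
    return pd.DataFrame(rows)


def cross_validation_experiment(seed: int = 0, n_mal: int = 20, n_ben: int = 40,
                                k: int = 5, epochs: int = 4) -> pd.DataFrame:
    """Five-fold CV of the tiny model on a small synthetic set; reports
    per-fold metrics (F1 spread is the quantity of interest)."""
    with tempfile.TemporaryDirectory() as tmp:
        manifest = generate_dataset(n_mal, n_ben, mask_fraction=0.15,
                                    image_size=64, seed=seed, out_dir=tmp)
        cfg = TrainConfig.tiny(seed=seed, epochs=epochs)
        return pipeline.cross_validate(manifest, k, cfg, seed=seed)
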