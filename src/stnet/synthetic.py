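"""Synthetic lesion images with controllable shape and texture cues.

Real dermoscopy and pathology collections are large, partly private and
unevenly annotated, so the package ships a generator that reproduces the
*statistical structure* such data presents to a shape-and-texture classifier:

* a **shape cue** — malignant lesions carry an irregular boundary, modelled as
  a truncated Fourier perturbation (orders 2-8) of a circle;
* a **texture cue** — the speckle noise inside the lesion has a
  class-dependent standard deviation;
* **class imbalance** — the default malignant:benign ratio is ~1:2.85;
* **partial mask annotation** — only a seeded fraction of samples carry a
  ground-truth mask (default 0.15).

Because the boundary is a radial function r(theta) > 0 around a fixed centre,
the lesion is star-shaped and therefore always a single connected component.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "LesionSpec",
    "ClassParams",
    "DEFAULT_CLASS_PARAMS",
    "generate_lesion",
    "boundary_radial_variance",
    "generate_dataset",
    "split_manifest",
    "load_image",
    "load_mask",
]

_FOURIER_ORDERS = np.arange(2, 9)  # low-order harmonics perturbing the circle


@dataclass(frozen=True)
class LesionSpec:
    """Parameters of a single synthetic lesion.

    irregularity is the amplitude of the radial boundary perturbation
    (0 = perfect circle); texture_contrast is the standard deviation of the
    within-lesion speckle noise on the 0-1 intensity scale.
    """

    seed: int
    label: int
    image_size: int = 64
    irregularity: float = 0.0
    texture_contrast: float = 0.05
    base_radius_frac: float = 0.3

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError(f"image_size must be >= 32, got {self.image_size}")
        if not (0.0 < self.base_radius_frac < 0.5):
            raise ValueError(
                f"base_radius_frac must lie in (0, 0.5), got {self.base_radius_frac}"
            )
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if self.irregularity < 0 or self.texture_contrast < 0:
            raise ValueError("irregularity and texture_contrast must be >= 0")


def _boundary_radius(spec: LesionSpec, theta: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """r(theta) = R * (1 + irregularity * sum of seeded low-order sinusoids).

    The harmonic amplitudes are normalized to unit RMS so that
    ``irregularity`` directly scales the relative boundary perturbation; the
    radius is floored at 0.1 R so the region never vanishes.
    """
    R = spec.base_radius_frac * spec.image_size
    a = rng.normal(size=_FOURIER_ORDERS.size)
    b = rng.normal(size=_FOURIER_ORDERS.size)
    norm = np.sqrt((a ** 2 + b ** 2).sum() / 2.0)
    if norm > 0:
        a, b = a / norm, b / norm
    pert = (a[:, None] * np.cos(_FOURIER_ORDERS[:, None] * theta[None])
            + b[:, None] * np.sin(_FOURIER_ORDERS[:, None] * theta[None])).sum(axis=0)
    r = R * (1.0 + spec.irregularity * pert)
    return np.maximum(r, 0.1 * R)


def generate_lesion(spec: LesionSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one lesion. Returns (image uint8 HxWx3, mask uint8 HxW in {0,1}).

    Deterministic: the same spec always yields bit-identical arrays.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    cy = cx = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    dist = np.hypot(dy, dx)
    r_theta = _boundary_radius(spec, theta.ravel(), rng).reshape(n, n)
    mask = (dist <= r_theta).astype(np.uint8)

    # Smooth background gradient (healthy tissue) in a seeded direction.
    ang = rng.uniform(0, 2 * np.pi)
    ramp = (dx * np.cos(ang) + dy * np.sin(ang)) / n
    background = 0.78 + 0.10 * ramp + 0.02 * rng.normal(size=(n, n))

    # Lesion interior: darker base tone + class-dependent speckle.
    base_tone = rng.uniform(0.40, 0.50)
    speckle = rng.normal(scale=max(spec.texture_contrast, 1e-12), size=(n, n))
    lesion = base_tone + speckle

    gray = np.where(mask.astype(bool), lesion, background)
    tint = np.array([1.05, 0.85, 0.75])  # skin-like channel balance
    img = np.clip(gray[..., None] * tint[None, None], 0.0, 1.0)
    return (img * 255).round().astype(np.uint8), mask


def boundary_radial_variance(mask: np.ndarray) -> float:
    """Variance of the distances of mask boundary pixels from the mask centroid.

    The simple hand-crafted shape statistic used to verify that the synthetic
    classes are separable by boundary irregularity alone.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    interior = (np.roll(mask, 1, 0) & np.roll(mask, -1, 0)
                & np.roll(mask, 1, 1) & np.roll(mask, -1, 1))
    boundary = mask & ~interior
    ys, xs = np.nonzero(boundary)
    cy, cx = np.nonzero(mask)[0].mean(), np.nonzero(mask)[1].mean()
    d = np.hypot(ys - cy, xs - cx)
    return float(d.var())


@dataclass(frozen=True)
class ClassParams:
    """Class-conditional sampling ranges for the generator.

    Defaults give disjoint irregularity ranges (shape cue) and separated
    speckle levels (texture cue); either cue can be neutralized by making the
    two ranges equal.
    """

    irregularity_benign: tuple[float, float] = (0.0, 0.15)
    irregularity_malignant: tuple[float, float] = (0.25, 0.5)
    texture_benign: tuple[float, float] = (0.02, 0.06)
    texture_malignant: tuple[float, float] = (0.10, 0.16)
    base_radius_frac: tuple[float, float] = (0.22, 0.35)


DEFAULT_CLASS_PARAMS = ClassParams()


def generate_dataset(n_malignant: int, n_benign: int, mask_fraction: float = 0.15,
                     image_size: int = 64, seed: int = 0,
                     out_dir: str | os.PathLike = "synthetic_data",
                     class_params: ClassParams = DEFAULT_CLASS_PARAMS,
                     ) -> pd.DataFrame:
    """Write a synthetic dataset to ``out_dir`` and return its manifest.

    The manifest has columns ``image, mask, label, split`` (split initially
    empty); exactly ``floor(mask_fraction * n)`` rows carry masks, chosen by
    seeded sampling without replacement.
    """
    if n_malignant < 1 or n_benign < 1:
        raise ValueError("need at least one sample per class")
    if not (0.0 <= mask_fraction <= 1.0):
        raise ValueError("mask_fraction must lie in [0, 1]")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(seed)
    labels = np.array([1] * n_malignant + [0] * n_benign)
    n = labels.size
    order = rng.permutation(n)
    labels = labels[order]
    n_masked = int(np.floor(mask_fraction * n))
    masked_rows = set(rng.choice(n, size=n_masked, replace=False).tolist())

    cp = class_params
    rows = []
    for i, label in enumerate(labels):
        irr_lo, irr_hi = (cp.irregularity_malignant if label
                          else cp.irregularity_benign)
        tex_lo, tex_hi = cp.texture_malignant if label else cp.texture_benign
        spec = LesionSpec(
            seed=int(rng.integers(0, 2 ** 31)),
            label=int(label),
            image_size=image_size,
            irregularity=float(rng.uniform(irr_lo, irr_hi)),
            texture_contrast=float(rng.uniform(tex_lo, tex_hi)),
            base_radius_frac=float(rng.uniform(*cp.base_radius_frac)),
        )
        img, mask = generate_lesion(spec)
        img_path = out_dir / "images" / f"sample_{i:05d}.png"
        Image.fromarray(img).save(img_path)
        mask_path = ""
        if i in masked_rows:
            mask_path = out_dir / "masks" / f"sample_{i:05d}.png"
            Image.fromarray((mask * 255).astype(np.uint8)).save(mask_path)
            mask_path = str(mask_path)
        rows.append({"image": str(img_path), "mask": mask_path,
                     "label": int(label), "split": ""})
    manifest = pd.DataFrame(rows, columns=["image", "mask", "label", "split"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def _allocate(n: int, ratios: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of n items to len(ratios) bins."""
    exact = ratios * n
    counts = np.floor(exact).astype(int)
    rem = n - counts.sum()
    if rem:
        order = np.argsort(-(exact - counts))
        counts[order[:rem]] += 1
    return counts


def split_manifest(manifest: pd.DataFrame,
                   ratios: tuple[float, float, float] = (6, 2, 2),
                   seed: int = 0, stratify: bool = True) -> pd.DataFrame:
    """Assign each row to train/val/test with the given ratios (normalized).

    With ``stratify`` the allocation is done per class so every split keeps
    the dataset's class balance to within one sample per class.
    """
    ratios = np.asarray(ratios, dtype=float)
    if (ratios < 0).any() or ratios.sum() <= 0:
        raise ValueError("ratios must be non-negative with positive sum")
    ratios = ratios / ratios.sum()
    n_splits_needed = int((ratios > 0).sum())
    if len(manifest) < n_splits_needed:
        raise ValueError(
            f"{len(manifest)} samples cannot fill {n_splits_needed} splits"
        )
    rng = np.random.default_rng(seed)
    names = np.array(["train", "val", "test"])
    out = manifest.copy()
    out["split"] = ""
    groups = ([df for _, df in out.groupby("label")] if stratify else [out])
    for df in groups:
        idx = df.index.to_numpy()
        rng.shuffle(idx)
        counts = _allocate(len(idx), ratios)
        start = 0
        for name, c in zip(names, counts):
            out.loc[idx[start:start + c], "split"] = name
            start += c
    return out


def load_image(path: str) -> np.ndarray:
    """Load an RGB image as float64 HxWx3 in [0, 1]."""
    return np.asarray(Image.open(path).convert("RGB"), dtype=np.float64) / 255.0


def load_mask(path: str) -> np.ndarray:
    """Load a grayscale mask PNG, binarized at >127."""
    return (np.asarray(Image.open(path).convert("L")) > 127).astype(np.float64)
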