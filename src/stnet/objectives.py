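"""Loss functions and the joint optimization contract.

Classification uses an asymmetric loss built for imbalanced benign/malignant
data.  Starting from binary cross-entropy

    L_CE = -y ln p - (1-y) ln(1-p),

two changes decouple the positive and negative branches:

* **asymmetric focusing** — the branches are weighted by (1-p)^gamma_plus and
  p^gamma_minus respectively; gamma_plus < gamma_minus damps the abundant,
  mostly easy negatives harder than the rare positives;
* **probability transfer** — the negative weight uses
  p_t = max(p - phi, 0) instead of p, so negatives already predicted below
  the cutoff phi contribute exactly zero loss and training concentrates on
  hard samples near the decision boundary.

Segmentation supervision is the pixel-wise mean square error between the
predicted and ground-truth masks.  The three parameter groups are optimized
jointly: the texture encoder sees only the classification loss, the shape
decoder only the shape loss, and the shape encoder a weighted mix
alpha*L_CLS + beta*L_SHP — alpha realized by the gradient-scaling layer on
the shape-feature path into the fusion head, beta as the weight of L_SHP in
the total loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.tensor import Tensor, as_tensor

__all__ = [
    "AsymLossParams",
    "JointLossWeights",
    "cross_entropy",
    "transfer_probability",
    "asymmetric_loss",
    "shape_loss",
    "joint_loss",
]

EPS = 1e-7  # probability clamp keeping every loss finite


@dataclass(frozen=True)
class AsymLossParams:
    """Focusing exponents and probability cutoff of the asymmetric loss."""

    gamma_plus: float = 1.0
    gamma_minus: float = 3.0
    phi: float = 0.05

    def __post_init__(self):
        if self.gamma_plus < 0 or self.gamma_minus < 0:
            raise ValueError("focusing exponents must be >= 0")
        if self.gamma_plus > self.gamma_minus:
            raise ValueError(
                "gamma_plus must not exceed gamma_minus (negatives are damped "
                "at least as hard as positives)"
            )
        if not (0.0 <= self.phi < 1.0):
            raise ValueError("phi must lie in [0, 1)")


@dataclass(frozen=True)
class JointLossWeights:
    """alpha scales L_CLS and beta scales L_SHP in the shape-encoder objective."""

    alpha: float = 0.1
    beta: float = 1.0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("loss weights must be >= 0")
        if self.alpha == 0 and self.beta == 0:
            raise ValueError("alpha and beta cannot both be zero")


def _prep(y, p):
    y = as_tensor(y)
    p = as_tensor(p).clamp(EPS, 1.0 - EPS)
    return y, p


def _as_result(t: Tensor, was_tensor: bool):
    if was_tensor:
        return t
    v = t.data
    return float(v) if v.ndim == 0 else v


def cross_entropy(y, p, reduce: bool = False):
    """Binary cross-entropy -y ln p - (1-y) ln(1-p), natural log.

    Element-wise on arrays; ``reduce`` takes the batch mean.  Accepts plain
    numbers/arrays (returns floats/arrays) or Tensors (stays on the graph).
    """
    was_tensor = isinstance(p, Tensor)
    y, p = _prep(y, p)
    loss = -(y * p.log()) - (1.0 - y) * (1.0 - p).log()
    if reduce:
        loss = loss.mean()
    return _as_result(loss, was_tensor)


def transfer_probability(p, phi: float):
    """Shifted probability p_t = max(p - phi, 0) of the negative branch."""
    was_tensor = isinstance(p, Tensor)
    pt = (as_tensor(p) - phi).maximum(0.0)
    return _as_result(pt, was_tensor)


def asymmetric_loss(y, p, params: AsymLossParams = AsymLossParams(),
                    reduce: bool = False):
    """Asymmetric classification loss

        -y (1-p)^gamma_plus ln p  -  (1-y) p_t^gamma_minus ln(1-p)

    with p_t = max(p - phi, 0).  Reduces exactly to cross-entropy at
    gamma_plus = gamma_minus = 0, phi = 0 (0^0 := 1).
    """
    was_tensor = isinstance(p, Tensor)
    y, pc = _prep(y, p)
    pt = (pc - params.phi).maximum(0.0)
    pos = y * ((1.0 - pc) ** params.gamma_plus) * pc.log()
    neg = (1.0 - y) * (pt ** params.gamma_minus) * (1.0 - pc).log()
    loss = -(pos + neg)
    if reduce:
        loss = loss.mean()
    return _as_result(loss, was_tensor)


def shape_loss(mask_pred, mask_true):
    """Pixel-wise mean square error between predicted and ground-truth masks."""
    was_tensor = isinstance(mask_pred, Tensor)
    mp, mt = as_tensor(mask_pred), as_tensor(mask_true)
    if mp.shape != mt.shape:
        raise ValueError(f"mask shapes differ: {mp.shape} vs {mt.shape}")
    return _as_result(((mp - mt) ** 2).mean(), was_tensor)


def joint_loss(p, y, mask_pred=None, mask_true=None, mask_available=None,
               params: AsymLossParams = AsymLossParams(),
               weights: JointLossWeights = JointLossWeights(),
               loss_type: str = "asymmetric"):
    """Total training loss L_CLS + beta * L_SHP for one batch.

    ``mask_available`` is a boolean vector; the shape term averages over the
    mask-bearing samples only and is zero (with zero gradient everywhere)
    when no sample in the batch has a mask.  The alpha weighting of the
    shape-encoder objective is applied by the fusion head's gradient-scaling
    layer, not here.

    Returns (total, L_CLS value, L_SHP value).
    """
    if loss_type == "asymmetric":
        l_cls = asymmetric_loss(y, p, params, reduce=True)
    elif loss_type == "cross_entropy":
        l_cls = cross_entropy(y, p, reduce=True)
    else:
        raise ValueError(f"unknown loss type {loss_type!r}")
    l_shp = None
    if mask_pred is not None and mask_available is not None:
        avail = np.asarray(mask_available, dtype=bool)
        if avail.any():
            idx = np.nonzero(avail)[0]
            mp = as_tensor(mask_pred)[idx]
            mt = as_tensor(mask_true).data[idx]
            l_shp = shape_loss(mp, Tensor(mt))
    if l_shp is None:
        total = l_cls
        shp_value = 0.0
    else:
        total = l_cls + weights.beta * l_shp
        shp_value = float(l_shp.data)
    return total, float(l_cls.data), shp_value
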