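"""Channel-attention feature fusion (CAFF) and the classifier head.

The texture and shape feature maps are concatenated along channels, which
widens the feature pool but also introduces redundancy; a channel-attention
gate learns which channels matter.  Each channel k is first summarized by

    g_k = 1/2 (mean_{i,j} z_{i,j,k} + max_{i,j} z_{i,j,k}),

balancing average and peak characterization, then two 1x1 transforms with
logistic activations produce a weight in (0, 1) per channel:

    w_att = sigmoid(W2^T sigmoid(W1^T g)),      Z' = w_att (x) Z.

Both nonlinearities are logistic (unusual — most attention blocks rectify the
hidden layer — but it is the design adopted here), which makes the gate a
strict element-wise contraction: |Z'| <= |Z|.

A gradient-scaling layer sits between the shape feature map and the
concatenation: identity forward, gradient times a constant backward.  It
damps the classification gradient flowing into the shape encoder so that
segmentation supervision dominates that stream's early training.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn.functional import gradient_scale
from .nn.tensor import Tensor, as_tensor

__all__ = [
    "global_dual_pool",
    "channel_attention",
    "apply_attention",
    "gradient_scale",
    "FusionHead",
]


def global_dual_pool(Z):
    """Per-channel average of global mean and max pooling.

    Accepts (C,H,W) or (N,C,H,W) arrays/Tensors; returns (C,) or (N,C).
    Each g_k lies between the channel mean and channel max (it is their
    average).
    """
    Z = as_tensor(Z)
    if Z.ndim == 3:
        return (global_dual_pool(Z.reshape((1,) + Z.shape))).reshape(Z.shape[0])
    if Z.ndim != 4 or Z.shape[2] * Z.shape[3] == 0:
        raise ValueError(f"expected a non-empty (N,C,H,W) map, got {Z.shape}")
    flat = Z.reshape(Z.shape[0], Z.shape[1], -1)
    return (flat.mean(axis=2) + flat.max(axis=2)) * 0.5


def channel_attention(g, w1, w2):
    """Attention weights w_att = sigmoid(w2^T sigmoid(w1^T g)).

    ``w1`` maps c -> c/r hidden units and ``w2`` maps c/r -> c (weight shapes
    (c, c/r) and (c/r, c)); every output lies strictly in (0, 1).
    """
    g, w1, w2 = as_tensor(g), as_tensor(w1), as_tensor(w2)
    c = g.shape[-1]
    if w1.shape[0] != c or w2.shape[1] != c or w1.shape[1] != w2.shape[0]:
        raise ValueError(
            f"weight shapes {w1.shape}, {w2.shape} do not compose over {c} channels"
        )
    return ((g @ w1).sigmoid() @ w2).sigmoid()


def apply_attention(Z, w_att):
    """Scale each channel of Z by its attention weight (Z' = w_att (x) Z)."""
    Z, w_att = as_tensor(Z), as_tensor(w_att)
    if Z.ndim == 3:
        if w_att.shape != (Z.shape[0],):
            raise ValueError(f"{w_att.shape} weights for {Z.shape[0]} channels")
        return Z * w_att.reshape(Z.shape[0], 1, 1)
    if Z.ndim == 4:
        if w_att.shape[-1] != Z.shape[1]:
            raise ValueError(f"{w_att.shape} weights for {Z.shape[1]} channels")
        w = w_att if w_att.ndim == 2 else w_att.reshape(1, Z.shape[1])
        return Z * w.reshape(w.shape[0], Z.shape[1], 1, 1)
    raise ValueError(f"expected (C,H,W) or (N,C,H,W), got {Z.shape}")


class FusionHead(nn.Module):
    """Gradient-scale the shape features, concatenate, gate with CAFF,
    pool and classify.

    Parameters
    ----------
    texture_channels, shape_channels:
        channel counts of the two incoming feature maps.
    reduction_ratio:
        bottleneck ratio r of the attention hidden layer (SE-style default 16,
        clipped so the hidden layer keeps at least one unit).
    grad_scale:
        factor applied to gradients entering the shape stream (the alpha of
        the shape-encoder objective).
    caff_enabled:
        ablation switch; when off the concatenated map goes straight to
        pooling.
    """

    def __init__(self, texture_channels, shape_channels, reduction_ratio=16,
                 grad_scale=0.1, caff_enabled=True, seed=0):
        super().__init__()
        if grad_scale <= 0:
            raise ValueError("grad_scale must be > 0")
        rng = np.random.default_rng(seed)
        c = texture_channels + shape_channels
        hidden = max(c // reduction_ratio, 1)
        self.att1 = nn.Linear(c, hidden, bias=False, rng=rng)
        self.att2 = nn.Linear(hidden, c, bias=False, rng=rng)
        self.classifier = nn.Linear(c, 1, rng=rng)
        self.texture_channels = texture_channels
        self.shape_channels = shape_channels
        self.grad_scale = grad_scale
        self.caff_enabled = caff_enabled

    def attention_weights(self, fused) -> Tensor:
        g = global_dual_pool(fused)
        return channel_attention(g, self.att1.weight, self.att2.weight)

    def forward(self, texture_feat, shape_feat):
        """Return the predicted malignancy score p in (0, 1) per sample."""
        texture_feat = as_tensor(texture_feat)
        shape_feat = as_tensor(shape_feat)
        if texture_feat.shape[0] != shape_feat.shape[0] or \
                texture_feat.shape[2:] != shape_feat.shape[2:]:
            raise ValueError(
                f"stream geometries differ: {texture_feat.shape} vs {shape_feat.shape}"
            )
        scaled = gradient_scale(shape_feat, self.grad_scale)
        fused = nn.cat([texture_feat, scaled], axis=1)
        if self.caff_enabled:
            w_att = self.attention_weights(fused)
            fused = apply_attention(fused, w_att)
        pooled = fused.reshape(fused.shape[0], fused.shape[1], -1).mean(axis=2)
        return self.classifier(pooled).sigmoid().reshape(fused.shape[0])
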