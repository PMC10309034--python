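"""Shape-biased stream: deformable-convolution encoder and mask decoder.

The encoder replaces the 3x3 convolutions of its deep bottleneck stages with
deformable convolutions, y(p) = sum_k w(p_k) x(p + p_k + dp_k): each kernel
tap is displaced by an offset predicted by a small convolution over the same
input, and fractional positions are read through bilinear interpolation.
Offset layers start at zero, so the encoder is exactly its non-deformable
counterpart at initialization.

The decoder upsamples the deepest feature map back to input resolution with
transposed convolutions and ResNet-18-style basic blocks, and squashes the
1-channel output to [0, 1].  There are deliberately no encoder-decoder
shortcut connections: all information reaching the decoder flows through the
deepest feature map, which is what makes that map a shape bottleneck.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .backbone import Encoder, get_profile
from .nn.functional import deformable_conv2d

__all__ = ["bilinear_sample", "deformable_conv", "ShapeEncoder", "ShapeDecoder"]


def bilinear_sample(channel: np.ndarray, point) -> float:
    """Bilinearly interpolate a 2-D array at a fractional (row, col) point.

    Pixel centers sit at integer coordinates; reads outside the array
    contribute zero (matching the zero-padding convention of the
    convolutions).
    """
    x = np.asarray(channel, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError(f"expected a 2-D channel, got shape {x.shape}")
    py, px = float(point[0]), float(point[1])
    H, W = x.shape
    y0, x0 = int(np.floor(py)), int(np.floor(px))
    wy, wx = py - y0, px - x0
    total = 0.0
    for dy, dx, w in ((0, 0, (1 - wy) * (1 - wx)), (0, 1, (1 - wy) * wx),
                      (1, 0, wy * (1 - wx)), (1, 1, wy * wx)):
        yy, xx = y0 + dy, x0 + dx
        if 0 <= yy < H and 0 <= xx < W:
            total += w * x[yy, xx]
    return total


def deformable_conv(x, weights, offsets, stride: int = 1, padding: int = 0,
                    bias=None):
    """Deformable convolution on an NCHW array or Tensor.

    ``offsets`` has shape (N, 2*kh*kw, H_out, W_out) with (row, col)
    displacement pairs interleaved per kernel tap; zero offsets reduce the
    operation to a standard convolution.
    """
    return deformable_conv2d(x, weights, offsets, bias=bias, stride=stride,
                             padding=padding)


class ShapeEncoder(nn.Module):
    """Backbone encoder with deformable 3x3 convolutions in selected stages.

    ``deformable_stages`` lists 0-based stage indices; the default is every
    stage past the first (the deep stages), bounding the extra cost of offset
    learning while covering the layers whose receptive fields matter most for
    boundary geometry.
    """

    def __init__(self, depth="tiny", deformable_stages: list[int] | None = None,
                 seed: int = 0):
        super().__init__()
        profile = get_profile(depth)
        if deformable_stages is None:
            deformable_stages = list(range(1, len(profile.stage_blocks)))
        rng = np.random.default_rng(seed)

        def factory_for_stage(stage_index):
            deform = stage_index in deformable_stages
            def make_conv2(cin, cout, stride, rng_):
                if deform:
                    return nn.DeformableConv2d(cin, cout, 3, stride=stride,
                                               padding=1, bias=False, rng=rng_)
                return nn.Conv2d(cin, cout, 3, stride=stride, padding=1,
                                 bias=False, rng=rng_)
            return make_conv2

        self.encoder = Encoder(profile, factory_for_stage, rng=rng)
        self.profile = profile

    @property
    def out_channels(self):
        return self.profile.out_channels

    def forward(self, image):
        return self.encoder(image)


class _BasicBlock(nn.Module):
    """ResNet-18-style residual block (two 3x3 convolutions)."""

    def __init__(self, channels, rng=None):
        super().__init__()
        self.conv1 = nn.Conv2d(channels, channels, 3, padding=1, bias=False,
                               rng=rng)
        self.bn1 = nn.BatchNorm2d(channels)
        self.conv2 = nn.Conv2d(channels, channels, 3, padding=1, bias=False,
                               rng=rng)
        self.bn2 = nn.BatchNorm2d(channels)

    def forward(self, x):
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out))
        return (out + x).relu()


class ShapeDecoder(nn.Module):
    """Deconvolution decoder predicting the lesion mask.

    One x2 transposed-convolution stage per entry of ``widths`` followed by a
    basic residual block, then a 1x1 head squashed by a logistic so the
    predicted mask lives in [0, 1] (it is compared to a {0,1} mask under L2).
    """

    def __init__(self, in_channels, widths=(32, 16, 8), seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        stages = []
        cin = in_channels
        for w in widths:
            stages.append(nn.Sequential(
                nn.ConvTranspose2d(cin, w, 2, stride=2, bias=False, rng=rng),
                nn.BatchNorm2d(w),
                nn.ReLU(),
                _BasicBlock(w, rng=rng),
            ))
            cin = w
        self.stages = stages
        self.head = nn.Conv2d(cin, 1, 1, rng=rng)
        self.in_channels = in_channels
        self.upsample_factor = 2 ** len(widths)

    def forward(self, feature):
        x = nn.as_tensor(feature)
        if x.data.ndim != 4 or x.data.shape[1] != self.in_channels:
            raise ValueError(
                f"decoder expects (N,{self.in_channels},h,w), got {x.data.shape}"
            )
        for stage in self.stages:
            x = stage(x)
        return self.head(x).sigmoid()


def decoder_widths_for(depth) -> tuple[int, ...]:
    """Default decoder stage widths matching an encoder profile's stride."""
    profile = get_profile(depth)
    if profile.name in ("resnet50", "resnet101"):
        return (1024, 512, 256, 128, 64)
    n_up = int(np.log2(profile.total_stride))
    return tuple(profile.out_channels // (2 ** (i + 1)) for i in range(n_up))
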