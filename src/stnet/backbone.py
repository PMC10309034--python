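"""Shared ResNet-style backbone machinery for the two streams.

Both encoders use the same stage geometry (so their final feature maps can be
concatenated); they differ in how the 3x3 convolution inside each bottleneck
is built — pyramid-grouped in the texture stream, deformable in the deep
stages of the shape stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

EXPANSION = 4  # bottleneck output channels = EXPANSION * mid channels


@dataclass(frozen=True)
class EncoderProfile:
    """Geometry of an encoder backbone.

    ``resnet50`` / ``resnet101`` mirror the standard 50/101-layer networks
    (stride-32 overall, 2048 final channels); ``tiny`` is a 2-stage, stride-8
    profile sized for CPU experiments on 64x64 images.
    """

    name: str
    stem_channels: int
    stem_kernel: int
    stem_stride: int
    stem_pool: bool
    stage_blocks: tuple[int, ...]
    stage_mid: tuple[int, ...]
    stage_strides: tuple[int, ...]

    @property
    def out_channels(self) -> int:
        return EXPANSION * self.stage_mid[-1]

    @property
    def total_stride(self) -> int:
        s = self.stem_stride * (2 if self.stem_pool else 1)
        return s * int(np.prod(self.stage_strides))


PROFILES = {
    "resnet50": EncoderProfile("resnet50", 64, 7, 2, True,
                               (3, 4, 6, 3), (64, 128, 256, 512), (1, 2, 2, 2)),
    "resnet101": EncoderProfile("resnet101", 64, 7, 2, True,
                                (3, 4, 23, 3), (64, 128, 256, 512), (1, 2, 2, 2)),
    "tiny": EncoderProfile("tiny", 16, 3, 2, True,
                           (1, 1), (8, 16), (1, 2)),
}


def get_profile(depth) -> EncoderProfile:
    """Resolve a depth (50, 101, 'tiny' or a profile) to an EncoderProfile."""
    if isinstance(depth, EncoderProfile):
        return depth
    key = {50: "resnet50", 101: "resnet101"}.get(depth, depth)
    if key not in PROFILES:
        raise ValueError(f"unknown backbone profile {depth!r}")
    return PROFILES[key]


class Bottleneck(nn.Module):
    """1x1 -> 3x3 -> 1x1 bottleneck with a residual connection.

    ``conv2_factory(cin, cout, stride, rng)`` builds the middle convolution,
    which is where the texture (grouped) and shape (deformable) streams
    differ; the two 1x1 convolutions take explicit group counts so the
    texture stream can apply its dense-to-sparse pyramid schedule.
    """

    def __init__(self, in_channels, mid_channels, stride, conv2_factory,
                 groups1=1, groups3=1, rng=None):
        super().__init__()
        out_channels = EXPANSION * mid_channels
        self.conv1 = nn.Conv2d(in_channels, mid_channels, 1, groups=groups1,
                               bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(mid_channels)
        self.conv2 = conv2_factory(mid_channels, mid_channels, stride, rng)
        self.bn2 = nn.BatchNorm2d(mid_channels)
        self.conv3 = nn.Conv2d(mid_channels, out_channels, 1, groups=groups3,
                               bias=False, rng=rng)
        self.bn3 = nn.BatchNorm2d(out_channels)
        if stride != 1 or in_channels != out_channels:
            self.shortcut = nn.Sequential(
                nn.Conv2d(in_channels, out_channels, 1, stride=stride,
                          bias=False, rng=rng),
                nn.BatchNorm2d(out_channels),
            )
        else:
            self.shortcut = nn.Identity()

    def forward(self, x):
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        return (out + self.shortcut(x)).relu()


class Encoder(nn.Module):
    """Stem + bottleneck stages; returns the deepest feature map."""

    def __init__(self, profile: EncoderProfile, conv2_factory_for_stage,
                 groups_for_stage=None, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        p = profile
        self.profile = p
        pad = p.stem_kernel // 2
        self.stem = nn.Sequential(
            nn.Conv2d(3, p.stem_channels, p.stem_kernel, stride=p.stem_stride,
                      padding=pad, bias=False, rng=rng),
            nn.BatchNorm2d(p.stem_channels),
            nn.ReLU(),
        )
        self.pool = nn.MaxPool2d(3, 2, 1) if p.stem_pool else nn.Identity()
        stages = []
        cin = p.stem_channels
        for s, (blocks, mid, stride) in enumerate(
                zip(p.stage_blocks, p.stage_mid, p.stage_strides)):
            factory = conv2_factory_for_stage(s)
            g1, g3 = (groups_for_stage(s, mid) if groups_for_stage else (1, 1))
            layers = []
            for b in range(blocks):
                layers.append(Bottleneck(cin, mid, stride if b == 0 else 1,
                                         factory, g1, g3, rng=rng))
                cin = EXPANSION * mid
            stages.append(nn.Sequential(*layers))
        self.stages = stages

    def forward(self, x):
        x = self.pool(self.stem(nn.as_tensor(x)))
        for stage in self.stages:
            x = stage(x)
        return x
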