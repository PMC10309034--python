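"""Texture-biased stream: pyramid-grouped convolution (PGC) encoder.

Standard convolution connects every kernel to every input channel; grouped
convolution restricts each kernel to one channel group, and depth-wise
convolution is the extreme with one group per channel.  A PGC block arranges
its layers so the group count grows layer by layer — channel connectivity
transitions from dense to sparse, shrinking the channel-wise receptive field
of successive kernels.  Here the pyramid runs over the three convolutions of
each bottleneck block: [1, g_mid, C_mid], with g_mid chosen by geometric
interpolation between the dense and depth-wise extremes.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .backbone import Encoder, get_profile
from .nn.functional import conv2d as _conv2d

__all__ = ["pgc_group_schedule", "grouped_conv", "TextureEncoder"]


def _nearest_divisor(c: int, target: float) -> int:
    """Divisor of ``c`` closest to ``target`` in log space (ties -> smaller)."""
    divisors = [d for d in range(1, c + 1) if c % d == 0]
    key = lambda d: (abs(np.log(d) - np.log(target)), d)
    return min(divisors, key=key)


def pgc_group_schedule(n_layers: int, channels: int) -> list[int]:
    """Dense-to-sparse group counts for a PGC block.

    Layer l (1-based) uses the divisor of ``channels`` nearest to
    ``channels**((l-1)/(L-1))``, so the schedule always starts at 1 (standard
    convolution), ends at ``channels`` (depth-wise) and is non-decreasing.
    """
    if n_layers < 1 or channels < 1:
        raise ValueError("n_layers and channels must be >= 1")
    if n_layers == 1:
        return [1]
    exps = np.arange(n_layers) / (n_layers - 1)
    schedule = [_nearest_divisor(channels, float(channels) ** e) for e in exps]
    # geometric targets are monotone; divisor rounding could in principle
    # produce a local dip, so enforce the dense-to-sparse invariant
    for i in range(1, n_layers):
        schedule[i] = max(schedule[i], schedule[i - 1])
    return schedule


def grouped_conv(x, weights, groups: int = 1, stride: int = 1,
                 padding: int = 0, bias=None):
    """Grouped 2-D convolution on an NCHW array or Tensor.

    ``weights`` has shape (C_out, C_in/groups, kh, kw); output channels of
    group i depend only on the input channels of group i.  Returns a Tensor
    (use ``.data`` for the ndarray).
    """
    return _conv2d(x, weights, bias=bias, stride=stride, padding=padding,
                   groups=groups)


class TextureEncoder(nn.Module):
    """ResNet-style encoder whose bottlenecks use the PGC pyramid.

    With ``pgc_enabled=False`` every group count is 1 and the encoder is the
    plain backbone (the ablation baseline).  ``schedule`` may be a custom
    3-element list applied to every bottleneck instead of the geometric one.
    """

    def __init__(self, depth="tiny", pgc_enabled: bool = True,
                 schedule: list[int] | None = None, seed: int = 0):
        super().__init__()
        profile = get_profile(depth)
        rng = np.random.default_rng(seed)

        def factory_for_stage(stage_index):
            def make_conv2(cin, cout, stride, rng_):
                if pgc_enabled:
                    g = (schedule[1] if schedule
                         else pgc_group_schedule(3, cin)[1])
                else:
                    g = 1
                return nn.Conv2d(cin, cout, 3, stride=stride, padding=1,
                                 groups=g, bias=False, rng=rng_)
            return make_conv2

        def groups_for_stage(stage_index, mid):
            if not pgc_enabled:
                return 1, 1
            sched = schedule if schedule else pgc_group_schedule(3, mid)
            return sched[0], sched[2]

        self.encoder = Encoder(profile, factory_for_stage, groups_for_stage,
                               rng=rng)
        self.profile = profile

    @property
    def out_channels(self):
        return self.profile.out_channels

    def forward(self, image):
        """Encode an image batch (N,3,H,W) into the final texture feature map."""
        return self.encoder(image)
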