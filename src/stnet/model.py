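"""Assembly of the two-stream network."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .backbone import get_profile
from .fusion import FusionHead
from .nn.tensor import Tensor
from .shape import ShapeDecoder, ShapeEncoder, decoder_widths_for
from .texture import TextureEncoder

__all__ = ["StreamOutputs", "STNet"]


@dataclass
class StreamOutputs:
    """Everything the network produces for one batch."""

    texture_feature: Tensor
    shape_feature: Tensor
    mask_pred: Tensor  # (N, 1, H, W) in [0, 1]
    p: Tensor          # (N,) malignancy scores in (0, 1)


class STNet(nn.Module):
    """Two-stream shape-and-texture network.

    The image is fed to a texture-biased PGC encoder and a shape-biased
    deformable encoder in parallel; the shape feature additionally drives a
    mask decoder (segmentation supervision), and both features are fused by
    channel attention before classification.  The decoder consumes the shape
    feature *before* the gradient-scaling layer, so classification gradients
    entering the shape encoder are damped by ``grad_scale`` while
    segmentation gradients are not.
    """

    def __init__(self, depth="tiny", pgc_enabled=True, deformable_stages=None,
                 decoder_widths=None, reduction_ratio=16, grad_scale=0.1,
                 caff_enabled=True, with_decoder=True, seed: int = 0,
                 pretrained_texture_path: str | None = None):
        super().__init__()
        profile = get_profile(depth)
        rng = np.random.default_rng(seed)
        seeds = rng.integers(0, 2 ** 31, size=4)
        self.texture_encoder = TextureEncoder(profile, pgc_enabled=pgc_enabled,
                                              seed=int(seeds[0]))
        self.shape_encoder = ShapeEncoder(profile,
                                          deformable_stages=deformable_stages,
                                          seed=int(seeds[1]))
        self.decoder = None
        if with_decoder:
            widths = decoder_widths or decoder_widths_for(profile)
            self.decoder = ShapeDecoder(profile.out_channels, widths,
                                        seed=int(seeds[2]))
        self.fusion = FusionHead(profile.out_channels, profile.out_channels,
                                 reduction_ratio=reduction_ratio,
                                 grad_scale=grad_scale,
                                 caff_enabled=caff_enabled, seed=int(seeds[3]))
        self.profile = profile
        if pretrained_texture_path:
            self.load_texture_weights(pretrained_texture_path)

    def load_texture_weights(self, path: str) -> None:
        """Hook for externally supplied texture-encoder weights (.npz of the
        texture encoder's state dict)."""
        state = dict(np.load(path))
        self.texture_encoder.load_state_dict(state)

    def forward(self, images) -> StreamOutputs:
        """Run a batch of images (N, 3, H, W) through both streams."""
        x = nn.as_tensor(images)
        tex = self.texture_encoder(x)
        shp = self.shape_encoder(x)
        mask_pred = self.decoder(shp) if self.decoder is not None else None
        p = self.fusion(tex, shp)
        return StreamOutputs(tex, shp, mask_pred, p)

    def predict_proba(self, images) -> np.ndarray:
        """Malignancy scores in eval mode, without building gradients."""
        mode = self.training
        self.eval()
        # classification does not need the decoder
        x = nn.Tensor(np.asarray(images, dtype=np.float64))
        tex = self.texture_encoder(x)
        shp = self.shape_encoder(x)
        p = self.fusion(tex, shp)
        self.train(mode)
        return p.data.copy()

    def predict_mask(self, images) -> np.ndarray:
        """Predicted masks (N, H, W) in [0, 1], eval mode."""
        if self.decoder is None:
            raise ValueError("model was built without a decoder")
        mode = self.training
        self.eval()
        shp = self.shape_encoder(nn.Tensor(np.asarray(images, dtype=np.float64)))
        mask = self.decoder(shp).data[:, 0]
        self.train(mode)
        return mask.copy()
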