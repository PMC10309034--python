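"""Training configuration.

Defaults follow the reference training recipe for the full-size network
(224x224 inputs, batch 64, RMSprop with lr 5e-4, weight decay 1e-5,
momentum 0.9, asymmetric loss with gamma_plus=1, gamma_minus=3);
``TrainConfig.tiny()`` is the CPU-sized profile used by the test-bench
experiments (2-stage encoders, 64x64 images, batch 8).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .objectives import AsymLossParams, JointLossWeights

__all__ = ["TrainConfig"]


@dataclass
class TrainConfig:
    # data
    image_size: int = 224
    batch_size: int = 64
    # optimization
    learning_rate: float = 5e-4
    weight_decay: float = 1e-5
    momentum: float = 0.9
    optimizer: str = "rmsprop"
    epochs: int = 30
    max_steps: int | None = None
    seed: int = 0
    # architecture
    depth: str | int = 50
    pgc_enabled: bool = True
    deformable_stages: list | None = None
    reduction_ratio: int = 16
    caff_enabled: bool = True
    with_decoder: bool = True
    pretrained_texture_path: str | None = None
    # objectives
    loss_type: str = "asymmetric"
    gamma_plus: float = 1.0
    gamma_minus: float = 3.0
    phi: float = 0.05
    alpha: float = 0.1   # classification-gradient scale into the shape encoder
    beta: float = 1.0    # weight of the shape loss
    # augmentation
    augment: bool = True
    rotation_deg: float = 30.0
    crop_fraction: float = 0.875

    def __post_init__(self):
        for name in ("image_size", "batch_size", "learning_rate", "epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def loss_params(self) -> AsymLossParams:
        return AsymLossParams(self.gamma_plus, self.gamma_minus, self.phi)

    @property
    def joint_weights(self) -> JointLossWeights:
        return JointLossWeights(self.alpha, self.beta)

    @classmethod
    def tiny(cls, **overrides) -> "TrainConfig":
        """CPU-sized profile for experiments and tests."""
        base = dict(image_size=64, batch_size=8, depth="tiny", epochs=10)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def from_yaml(cls, path: str) -> "TrainConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
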