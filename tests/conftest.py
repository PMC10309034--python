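import numpy as np
import pytest

from stnet.config import TrainConfig
from stnet.synthetic import generate_dataset, split_manifest


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """38-sample imbalanced dataset (10 malignant / 28 benign), half masked."""
    out = tmp_path_factory.mktemp("lesions")
    manifest = generate_dataset(10, 28, mask_fraction=0.5, image_size=64,
                                seed=7, out_dir=out)
    return split_manifest(manifest, (6, 2, 2), seed=7)


@pytest.fixture(scope="session")
def quick_config():
    """A config that trains for a handful of steps (pipeline plumbing tests)."""
    return TrainConfig.tiny(seed=0, epochs=1, max_steps=3, augment=False)


def finite_difference(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of scalar-valued f with respect to x."""
    grad = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        grad[idx] = (fp - fm) / (2 * eps)
    return grad
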