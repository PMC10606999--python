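import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from simexplain import (BackboneSpec, LabeledDataset, LabeledImage,
                        SiameseNetwork, SyntheticSpec, generate_shape_dataset)


@pytest.fixture(scope="session")
def small_shapes():
    """3-class, 6-per-class, 32x32 shape dataset with masks (fast unit runs)."""
    spec = SyntheticSpec(n_classes=3, n_per_class=6, image_size=(32, 32),
                         shape_size_range=(10, 14), noise_level=0.25, seed=5)
    return generate_shape_dataset(spec)


@pytest.fixture(scope="session")
def tiny_model():
    """Fixed-weight network small enough for finite-difference oracles."""
    spec = BackboneSpec(input_size=(16, 16), channels=(3, 4, 5), embedding_dim=6)
    return SiameseNetwork(spec, seed=3)


def make_images(class_sizes: dict[str, int], hw: int = 8, seed: int = 0) -> LabeledDataset:
    """Programmatic dataset of flat-colored images, one class per entry."""
    rng = np.random.default_rng(seed)
    images = []
    for cls, n in class_sizes.items():
        for i in range(n):
            px = np.full((hw, hw, 3), rng.integers(0, 256), dtype=np.uint8)
            images.append(LabeledImage(px, cls, f"{cls}/{i}"))
    return LabeledDataset(images, classes=list(class_sizes))
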