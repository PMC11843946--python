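import numpy as np
import pytest

from leafcolor.imaging import ColorFeatures
from leafcolor.synthetic import SyntheticLeafSpec, SyntheticStudySpec, make_leaf_image, make_study_dataset


@pytest.fixture(scope="session")
def default_leaf():
    """Noise-free synthetic leaf painted (120, 80, 60)."""
    return make_leaf_image(SyntheticLeafSpec(base_color=(120, 80, 60)))


@pytest.fixture(scope="session")
def noisy_leaf():
    """Synthetic leaf with sd-5 channel noise."""
    return make_leaf_image(
        SyntheticLeafSpec(base_color=(60, 120, 45), channel_noise_sd=5.0, seed=11)
    )


@pytest.fixture(scope="session")
def study():
    """Default n=320 study table with its ground-truth sidecar."""
    return make_study_dataset(SyntheticStudySpec(seed=7))


def random_features(rng: np.random.Generator, n: int) -> list[ColorFeatures]:
    """Random but structurally valid mean-feature records."""
    out = []
    for i in range(n):
        R, G, B = rng.uniform(0, 255, 3)
        total = R + G + B
        out.append(
            ColorFeatures(
                leaf_id=f"rand_{i}", pixel_count=int(rng.integers(5000, 50000)),
                R=R, G=G, B=B,
                H=float(rng.uniform(0, 360)), S=float(rng.uniform(0, 1)),
                V=float(rng.uniform(0, 1)),
                L=float(rng.uniform(0, 100)), a=float(rng.uniform(-60, 60)),
                b_lab=float(rng.uniform(-60, 60)),
                r=R / total, g=G / total, b=B / total,
            )
        )
    return out
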