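import numpy as np
import pytest

from cytoscreen import (
    Bethesda,
    CellImage,
    OrdinalClassifier,
    generate_crop,
    load_reference_matrix,
)


@pytest.fixture(scope="session")
def stage1_cm():
    return load_reference_matrix(1)


@pytest.fixture(scope="session")
def stage2_cm():
    return load_reference_matrix(2)


@pytest.fixture()
def flat_image():
    """Uniform mid-gray 32x32 RGB image."""
    return CellImage(pixels=np.full((32, 32, 3), 128, dtype=np.uint8), id="flat")


@pytest.fixture()
def random_image():
    rng = np.random.default_rng(42)
    return CellImage(
        pixels=rng.integers(0, 256, size=(24, 40, 3), dtype=np.uint8), id="rand"
    )


@pytest.fixture(scope="session")
def trained_classifier():
    """Ordinal classifier fitted once on clean single-cluster crops."""
    rng = np.random.default_rng(2024)
    crops, labels = [], []
    for k in range(1, 7):
        for _ in range(30):
            crops.append(generate_crop(k, seed=int(rng.integers(2**31 - 1))))
            labels.append(Bethesda(k))
    return OrdinalClassifier().fit(crops, labels, smoothing_n=2, seed=0)
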