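import numpy as np
import pytest

from hornmap import HaplotypePanel, MarkerMap


def make_map(n_markers: int, spacing: int = 100, chromosome: str = "1") -> MarkerMap:
    return MarkerMap(
        chromosome,
        tuple((f"M{j:04d}", spacing * (j + 1)) for j in range(n_markers)),
    )


def make_panel(matrix, breed: str = "B01", spacing: int = 100) -> HaplotypePanel:
    H = np.asarray(matrix, dtype=np.uint8)
    ids = [f"{breed}_{i}" for i in range(H.shape[0] // 2)]
    return HaplotypePanel(breed, make_map(H.shape[1], spacing), H, ids)


@pytest.fixture
def tiny_map():
    return make_map(3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
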