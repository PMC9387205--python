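import numpy as np
import pytest

from chromacloud import GamutModel, PointCloud3


@pytest.fixture(scope="session")
def gamut() -> GamutModel:
    return GamutModel()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture()
def gaussian_cloud(rng) -> PointCloud3:
    """Seeded isotropic Gaussian cloud (σ = 1), 120 points."""
    coords = rng.normal(0.0, 1.0, size=(120, 3))
    return PointCloud3([f"p{i:03d}" for i in range(120)], coords)


def pairwise(coords: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import pdist

    return pdist(np.asarray(coords, dtype=float))


def group_separation(coords: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(mean within-group distance, mean between-group distance)."""
    from scipy.spatial.distance import squareform

    d = squareform(pairwise(coords))
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(labels), 1)
    return float(d[iu][same[iu]].mean()), float(d[iu][~same[iu]].mean())
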