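import numpy as np
import pytest

from soyphen.cloud import PointCloud
from soyphen import synth


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_cloud(rng):
    """1000 random points in a unit box, with colors."""
    pts = rng.uniform(0, 1, (1000, 3))
    cols = rng.integers(0, 256, (1000, 3), dtype=np.int64)
    return PointCloud(pts, cols)


@pytest.fixture(scope="session")
def default_plant():
    """One default synthetic scene + truth, shared across tests."""
    return synth.make_plant(synth.SyntheticPlantSpec(seed=1))


def sunflower_disk(n: int, r: float = 1.0) -> np.ndarray:
    """Low-discrepancy uniform covering of a disk (boundary included)."""
    i = np.arange(1, n + 1)
    golden = (1 + 5**0.5) / 2
    theta = 2 * np.pi * i / golden**2
    rad = r * np.sqrt((i - 0.5) / n)
    return np.stack([rad * np.cos(theta), rad * np.sin(theta)], axis=1)
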