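import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make reference.py importable

from rqadetect.embedding import EmbeddingParams, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_trajectory(points: np.ndarray) -> Trajectory:
    """Wrap a raw (n, m) point cloud as a 1-delay Trajectory."""
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, None]
    n, m = points.shape
    return Trajectory(points, EmbeddingParams(tau=1, m=m),
                      source_len=n + m - 1)


def random_symmetric_rp(rng: np.random.Generator, n: int,
                        density: float = 0.3) -> np.ndarray:
    """Random symmetric binary matrix with unit diagonal."""
    upper = rng.random((n, n)) < density
    R = np.triu(upper, 1)
    R = R | R.T
    np.fill_diagonal(R, True)
    return R
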