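import numpy as np
import pytest

from nnclust.core import Assignment, DataMatrix
from nnclust.synthetic import BlobSpec, gaussian_blobs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    return DataMatrix(np.array([[1.0, 0.0], [3.0, 0.0], [5.0, 10.0]]))


@pytest.fixture
def small_assignment():
    return Assignment(labels=np.array([0, 0, 1]), K=2)


@pytest.fixture
def separated_blobs():
    """Three well-separated labeled blobs, 20 points each."""
    spec = BlobSpec(n_per_cluster=(20, 20, 20), p=3, separation=10.0, noise_sd=1.0, seed=7)
    return gaussian_blobs(spec)
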