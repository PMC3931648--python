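import numpy as np
import pytest

from accelknn.io import Dataset, LabeledSample
from accelknn.knn import NeighborVote


def make_dataset(coords, labels=None, sample_rate=20.0):
    """Build a Dataset from an (n, 3) array and optional label list."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    labels = labels if labels is not None else [None] * n
    samples = tuple(
        LabeledSample(t=i / sample_rate, x=float(c[0]), y=float(c[1]),
                      z=float(c[2]), label=labels[i])
        for i, c in enumerate(coords)
    )
    return Dataset(samples=samples, sample_rate=sample_rate)


def random_labeled_dataset(rng, n=50, n_labels=3, scale=1.0):
    coords = rng.normal(0, scale, size=(n, 3))
    labels = [f"B{rng.integers(n_labels)}" for _ in range(n)]
    return make_dataset(coords, labels)


def make_vote(predicted, prob, query_index=0):
    """Minimal NeighborVote carrying just a winner and its confidence."""
    return NeighborVote(
        query_index=query_index,
        neighbor_distances=(0.0,),
        neighbor_labels=(predicted,),
        winning_label=predicted,
        prob=prob,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
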