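"""K-nearest-neighbour classification of raw tri-axial acceleration.

A query sample is assigned the majority label of its k nearest training
samples under Euclidean distance in the raw (x, y, z) feature space, together
with the confidence output ``prob`` — the proportion of the k neighbours that
belong to the winning class (n_wc / k).  No feature scaling is applied: the
three axes share units (g).

Tie rules (both deterministic given the seed):

* distance ties at the k-th neighbour rank are resolved by taking the
  lexicographically-first training indices, keeping the neighbourhood size
  exactly k so the ``prob`` denominator is well defined;
* vote ties between labels with equal maximal count are broken uniformly at
  random among the tied labels, driven by ``rng_seed`` (and the query index),
  mirroring conventional KNN routines while staying reproducible.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from accelknn.io import Dataset

__all__ = ["NeighborVote", "euclidean_distance", "classify_point", "classify_dataset"]


@dataclass(frozen=True)
class NeighborVote:
    """Outcome of one KNN query: the k neighbours, the winner, and prob."""

    query_index: int
    neighbor_distances: tuple[float, ...]
    neighbor_labels: tuple[str, ...]
    winning_label: str
    prob: float

    def __post_init__(self) -> None:
        if len(self.neighbor_distances) != len(self.neighbor_labels):
            raise ValueError("neighbour distances and labels must have equal length")
        if not 0.0 < self.prob <= 1.0:
            raise ValueError(f"prob must lie in (0, 1], got {self.prob}")


def euclidean_distance(
    a: Sequence[float], b: Sequence[float]
) -> float:
    """Euclidean distance between two acceleration triples, in g.

    d(a, b) = sqrt(sum over the three axes of the squared coordinate
    differences).
    """
    ax, ay, az = (float(v) for v in a)
    bx, by, bz = (float(v) for v in b)
    for v in (ax, ay, az, bx, by, bz):
        if not math.isfinite(v):
            raise ValueError(f"non-finite coordinate in distance computation: {v!r}")
    return math.sqrt((ax - bx) ** 2 + (ay - by) ** 2 + (az - bz) ** 2)


def _training_arrays(training: Dataset) -> tuple[np.ndarray, list[str]]:
    if not training.fully_labeled:
        raise ValueError("training dataset must be fully labelled")
    labels = list(training.labels())
    return training.coords(), labels  # type: ignore[return-value]


def _vote(
    dist_row: np.ndarray,
    train_labels: Sequence[str],
    k: int,
    rng: np.random.Generator,
    query_index: int,
) -> NeighborVote:
    # stable argsort -> lexicographically-first indices among distance ties
    order = np.argsort(dist_row, kind="stable")[:k]
    neigh_labels = tuple(train_labels[i] for i in order)
    counts = Counter(neigh_labels)
    top = max(counts.values())
    tied = sorted(lab for lab, c in counts.items() if c == top)
    winner = tied[0] if len(tied) == 1 else tied[int(rng.integers(len(tied)))]
    return NeighborVote(
        query_index=query_index,
        neighbor_distances=tuple(float(dist_row[i]) for i in order),
        neighbor_labels=neigh_labels,
        winning_label=winner,
        prob=counts[winner] / k,
    )


def classify_point(
    query: Sequence[float],
    training: Dataset,
    k: int = 3,
    rng_seed: int = 0,
    query_index: int = 0,
) -> NeighborVote:
    """Classify one acceleration triple against a fully labelled training set.

    The neighbour set is exactly the k training points of least Euclidean
    distance to the query; the winning label has the maximal vote count and
    ``prob`` is its share of the k votes.

    Parameters
    ----------
    query : (x, y, z) acceleration triple in g.
    training : fully labelled :class:`~accelknn.io.Dataset` with >= k samples.
    k : number of neighbours (>= 1); defaults to 3.
    rng_seed : seed driving vote tie-breaks.
    query_index : position of the query in its test set; part of the
        tie-break stream so batch and single-point classification agree.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(training):
        raise ValueError(f"k={k} exceeds training size {len(training)}")
    coords, labels = _training_arrays(training)
    q = np.asarray(query, dtype=float).reshape(3)
    if not np.all(np.isfinite(q)):
        raise ValueError(f"query must be finite, got {query!r}")
    dist = np.sqrt(((coords - q) ** 2).sum(axis=1))
    rng = np.random.default_rng([rng_seed, query_index])
    return _vote(dist, labels, k, rng, query_index)


def classify_dataset(
    test: Dataset,
    training: Dataset,
    k: int = 3,
    rng_seed: int = 0,
) -> list[NeighborVote]:
    """Classify every sample of ``test``, in order, against ``training``.

    Equivalent to calling :func:`classify_point` sample by sample (with the
    matching ``query_index``), but computes the full distance matrix in one
    vectorised pass.  Deterministic given ``rng_seed``.
    """
    if len(test) == 0:
        raise ValueError("test dataset must be non-empty")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(training):
        raise ValueError(f"k={k} exceeds training size {len(training)}")
    coords, labels = _training_arrays(training)
    queries = test.coords()
    # (n_test, n_train) pairwise Euclidean distances
    diff = queries[:, None, :] - coords[None, :, :]
    dists = np.sqrt((diff**2).sum(axis=2))
    votes = []
    for i in range(len(test)):
        rng = np.random.default_rng([rng_seed, i])
        votes.append(_vote(dists[i], labels, k, rng, i))
    return votes
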