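"""Kennard–Stone sequential sample selection.

The classic chemometrics recipe for a representative calibration split:
start from the pair of samples at maximum Euclidean distance, then
repeatedly add the candidate whose minimum distance to the already-selected
set is largest.  Deterministic (ties broken by lowest index); the remaining
samples form the test set.  A ~2:1 train:test split is the conventional
choice for e-nose feature sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .errors import InvalidParameterError


@dataclass
class SplitResult:
    train_indices: list[int]   # ordered by selection step
    test_indices: list[int]


def kennard_stone_split(features: np.ndarray, n_train: int) -> SplitResult:
    """Select ``n_train`` samples by the sequential max-min distance rule."""
    X = np.asarray(features, dtype=float)
    N = X.shape[0]
    if not 2 <= n_train < N:
        raise InvalidParameterError(f"n_train must be in [2, {N - 1}]; got {n_train}")

    dist = squareform(pdist(X))
    # first pair: maximum pairwise distance; row-major argmax gives the
    # lexicographically smallest (i, j) among ties
    i, j = np.unravel_index(np.argmax(dist), dist.shape)
    if i > j:
        i, j = j, i
    selected = [int(i), int(j)]
    in_set = np.zeros(N, dtype=bool)
    in_set[[i, j]] = True
    min_dist = np.minimum(dist[i], dist[j])

    while len(selected) < n_train:
        candidate_score = np.where(in_set, -np.inf, min_dist)
        nxt = int(np.argmax(candidate_score))
        selected.append(nxt)
        in_set[nxt] = True
        min_dist = np.minimum(min_dist, dist[nxt])

    test = [int(k) for k in np.flatnonzero(~in_set)]
    return SplitResult(train_indices=selected, test_indices=test)


def kennard_stone_split_per_class(
    features: np.ndarray, labels: np.ndarray, train_fraction: float = 0.7
) -> SplitResult:
    """Apply Kennard–Stone within each class, preserving per-class proportions.

    ``n_train`` per class is ``round(train_fraction * n_class)``; train
    indices are concatenated in class order (selection order within class).
    """
    if not 0 < train_fraction < 1:
        raise InvalidParameterError("train_fraction must be in (0, 1)")
    y = np.asarray(labels).ravel()
    train: list[int] = []
    test: list[int] = []
    for c in np.unique(y):
        rows = np.flatnonzero(y == c)
        # half-up rounding, robust to float representation (0.7*65 -> 46)
        n_train = int(np.floor(train_fraction * rows.size + 0.5 + 1e-9))
        n_train = min(max(n_train, 2), rows.size - 1)
        split = kennard_stone_split(np.asarray(features)[rows], n_train)
        train.extend(int(rows[k]) for k in split.train_indices)
        test.extend(int(rows[k]) for k in split.test_indices)
    return SplitResult(train_indices=train, test_indices=sorted(test))
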