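"""Shared kNN machinery: split, feature transform, vote-based prediction.

The classifier is deliberately minimal — k nearest training samples by
Euclidean distance, class probability = neighbor-vote fraction — because the
tie rule must be explicit for reproducibility at k=10 with 3 classes: a vote
tie goes to the tied class with the smaller summed neighbor distance, any
remaining tie to the fixed class order normal < low < high.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, fields

import numpy as np
from sklearn.model_selection import train_test_split

CLASS_ORDER = ["normal", "low", "high"]
_CLASS_CODE = {c: i for i, c in enumerate(CLASS_ORDER)}


@dataclass(frozen=True)
class KNNConfig:
    """Hyperparameters of the train/validate kNN protocol.

    Defaults follow the published protocol: 10 neighbors, Euclidean
    distance, a random 50:50 train/validation split.  The split is
    stratified by class by default so all three classes appear in both
    halves; ``transform`` is log2(x+1) followed by per-gene z-scoring fit on
    the training half (``raw`` mirrors a literal Euclidean distance on
    FPKM_UQ).  With ``n_repeats`` > 1 accuracy is averaged over splits
    seeded ``seed .. seed+n_repeats-1``.
    """

    k_neighbors: int = 10
    metric: str = "euclidean"
    split_fraction: float = 0.5
    stratified: bool = True
    transform: str = "log2p1_zscore"
    seed: int = 0
    n_repeats: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.metric != "euclidean":
            raise ValueError("only the euclidean metric is supported")
        if self.transform not in ("log2p1_zscore", "raw"):
            raise ValueError(f"unknown transform {self.transform!r}")

    def hash(self) -> str:
        payload = ";".join(f"{f.name}={getattr(self, f.name)}" for f in fields(self))
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def encode_labels(labels) -> np.ndarray:
    """Map class names to integer codes in the fixed class order."""
    try:
        return np.array([_CLASS_CODE[c] for c in labels])
    except KeyError as err:
        raise ValueError(f"unknown class label {err.args[0]!r}") from None


def split_indices(labels: np.ndarray, config: KNNConfig) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic (train, test) index split; stratified by default."""
    idx = np.arange(len(labels))
    train, test = train_test_split(
        idx,
        test_size=config.split_fraction,
        random_state=config.seed,
        stratify=labels if config.stratified else None,
        shuffle=True,
    )
    return np.sort(train), np.sort(test)


def fit_transform(train: np.ndarray, test: np.ndarray, transform: str) -> tuple[np.ndarray, np.ndarray]:
    """Apply the feature transform, fitting scale parameters on train only.

    Arrays are samples x genes.  Constant genes get unit scale.
    """
    if transform == "raw":
        return train.astype(float), test.astype(float)
    train = np.log2(train + 1.0)
    test = np.log2(test + 1.0)
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def vote_probabilities(
    dist: np.ndarray, y_train: np.ndarray, k: int, n_classes: int = 3, squared: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Class-vote fractions and tie-broken predictions from a distance matrix.

    ``dist`` is (n_test, n_train).  ``squared=True`` marks the input as
    squared Euclidean distances: neighbor selection is unchanged (monotone),
    and the tie rule still compares true summed distances, computed on the k
    neighbors only.  Returns (proba (n_test, n_classes), predicted codes).
    """
    n_test, n_train = dist.shape
    if n_train < k:
        raise ValueError(f"k={k} exceeds {n_train} training samples")
    nbr = np.argpartition(dist, k - 1, axis=1)[:, :k]
    nbr_labels = y_train[nbr]
    nbr_dist = np.take_along_axis(dist, nbr, axis=1)
    if squared:
        nbr_dist = np.sqrt(nbr_dist)

    votes = np.zeros((n_test, n_classes), dtype=np.int64)
    sum_dist = np.zeros((n_test, n_classes))
    for c in range(n_classes):
        in_class = nbr_labels == c
        votes[:, c] = in_class.sum(axis=1)
        sum_dist[:, c] = np.where(in_class, nbr_dist, 0.0).sum(axis=1)

    proba = votes / k
    tied = votes == votes.max(axis=1, keepdims=True)
    tie_key = np.where(tied, sum_dist, np.inf)
    pred = tie_key.argmin(axis=1)  # argmin takes the first (fixed class order) on exact ties
    return proba, pred


def canonical_order(x_train: np.ndarray, y_train: np.ndarray) -> np.ndarray:
    """Training-sample ordering independent of input permutation.

    Sorting by feature values (then label) makes neighbor selection under
    exact distance ties reproducible regardless of how the caller ordered
    the training set.
    """
    return np.lexsort((y_train, *x_train.T[::-1]))


def pairwise_euclidean(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Euclidean distances between rows of a (n, d) and b (m, d) -> (n, m)."""
    # explicit subtraction is exact (no catastrophic cancellation), and these
    # matrices are small enough that the memory cost does not matter
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    return np.sqrt(d2)
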