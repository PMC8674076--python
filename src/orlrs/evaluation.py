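"""External clustering-validity metrics: ACC and NMI.

ACC is the fraction of samples correctly labelled under the best one-to-one
mapping between predicted and true cluster names, found by maximum-weight
assignment (Hungarian algorithm) on the contingency table.  NMI is the
mutual information between the two partitions normalized by the arithmetic
mean of their entropies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import normalized_mutual_info_score
from sklearn.metrics.cluster import contingency_matrix

__all__ = ["LabelPair", "clustering_accuracy", "nmi"]


@dataclass
class LabelPair:
    """A ground-truth / predicted label vector pair of equal length."""

    truth: np.ndarray
    predicted: np.ndarray

    def __post_init__(self) -> None:
        self.truth = np.asarray(self.truth, dtype=int)
        self.predicted = np.asarray(self.predicted, dtype=int)
        if self.truth.ndim != 1 or self.predicted.ndim != 1:
            raise ValueError("labels must be 1-D vectors")
        if self.truth.size != self.predicted.size:
            raise ValueError(
                f"length mismatch: {self.truth.size} truth vs "
                f"{self.predicted.size} predicted labels"
            )
        if self.truth.size < 1:
            raise ValueError("need at least one sample")
        if self.truth.min() < 0 or self.predicted.min() < 0:
            raise ValueError("labels must be non-negative integers")

    @property
    def n(self) -> int:
        return self.truth.size


def clustering_accuracy(pair: LabelPair) -> float:
    """Best-mapping clustering accuracy in [0, 1].

    The contingency table between truth and prediction is padded to square
    with zero-weight dummies (the predicted cluster count may differ from the
    true one), and the optimal one-to-one relabelling is the maximum-weight
    assignment.  Invariant to any renaming of predicted labels.
    """
    table = contingency_matrix(pair.truth, pair.predicted)
    r, s = table.shape
    d = max(r, s)
    padded = np.zeros((d, d), dtype=table.dtype)
    padded[:r, :s] = table
    rows, cols = linear_sum_assignment(padded, maximize=True)
    return float(padded[rows, cols].sum()) / pair.n


def nmi(pair: LabelPair) -> float:
    """Normalized mutual information M(S,C) / ((H(S)+H(C))/2) in [0, 1].

    Degenerate partitions: if both sides are single-class the partitions are
    identical and the value is 1; if only one side is single-class the mutual
    information is 0 and so is the score (avoiding 0/0).
    """
    t_single = np.unique(pair.truth).size == 1
    p_single = np.unique(pair.predicted).size == 1
    if t_single and p_single:
        return 1.0
    if t_single or p_single:
        return 0.0
    return float(
        normalized_mutual_info_score(
            pair.truth, pair.predicted, average_method="arithmetic"
        )
    )
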