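"""Cluster-count selection by repeated internal-validity voting.

Four internal indices are supported: Calinski-Harabasz (CH), mean silhouette
width (SI), the gap statistic (Gap) and Davies-Bouldin (DB).  The cluster
count is chosen by the mode of many repetitions: each repetition clusters
the data once per candidate k with a fresh random k-means start, records the
arg-best k under the chosen index, and the distribution of these votes is
summarized.  A criterion is *decisive* when its modal k captures more than
half of the repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .consensus import kmeans

#: Indices where larger is better; DB is the only smaller-is-better index.
HIGHER_IS_BETTER = {"CH": True, "SI": True, "Gap": True, "DB": False}


@dataclass
class CriterionVote:
    """Vote distribution of one index over repeated evaluations."""

    criterion: str
    votes: dict[int, int]
    n_reps: int

    @property
    def mode_k(self) -> int:
        best = max(self.votes.values())
        return min(k for k, c in self.votes.items() if c == best)

    @property
    def mode_fraction(self) -> float:
        return self.votes[self.mode_k] / self.n_reps

    @property
    def decisive(self) -> bool:
        return self.mode_fraction > 0.5

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion,
            "votes": {str(k): v for k, v in sorted(self.votes.items())},
            "mode_k": self.mode_k,
            "mode_fraction": self.mode_fraction,
            "decisive": self.decisive,
        }


def _within_dispersion(x: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for lab in np.unique(labels):
        pts = x[labels == lab]
        w += ((pts - pts.mean(axis=0)) ** 2).sum()
    return w


def gap_statistic(
    x: np.ndarray,
    labels: np.ndarray,
    seed: int | None = None,
    n_refs: int = 10,
) -> float:
    """Tibshirani gap: reference log-dispersion minus observed log-dispersion.

    Reference sets are uniform over each feature's observed range and are
    clustered with the same k (single-start Lloyd); larger gaps indicate
    stronger structure than featurewise-uniform noise.
    """
    rng = np.random.default_rng(seed)
    k = len(np.unique(labels))
    log_w = np.log(_within_dispersion(x, labels))
    lo, hi = x.min(axis=0), x.max(axis=0)
    ref_logs = []
    for _ in range(n_refs):
        ref = lo + rng.random(x.shape) * (hi - lo)
        ref_labels = kmeans(ref, k, int(rng.integers(2 ** 31)))
        ref_logs.append(np.log(_within_dispersion(ref, ref_labels)))
    return float(np.mean(ref_logs) - log_w)


def internal_index(
    data,
    labels,
    criterion: str,
    seed: int | None = None,
) -> float:
    """Evaluate one internal validity index for a given labelling.

    CH = (between-SS/(k-1)) / (within-SS/(n-k)); SI = mean silhouette width
    (Euclidean); DB = mean over clusters of the worst pairwise
    (scatter_i + scatter_j) / centroid-distance; Gap is stochastic and uses
    ``seed``.  Higher is better for CH/SI/Gap, lower for DB.
    """
    x = np.asarray(getattr(data, "values", data), dtype=float)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 non-empty clusters")
    if x.shape[0] <= len(uniq):
        raise ValueError("need more points than clusters")
    if criterion == "CH":
        return float(calinski_harabasz_score(x, labels))
    if criterion == "DB":
        return float(davies_bouldin_score(x, labels))
    if criterion == "SI":
        if counts.min() < 1:
            raise ValueError("silhouette requires non-empty clusters")
        return float(silhouette_score(x, labels, metric="euclidean"))
    if criterion == "Gap":
        return gap_statistic(x, labels, seed=seed)
    raise ValueError(f"unknown criterion {criterion!r}")


def vote_best_k(
    data,
    k_range=range(2, 11),
    n_reps: int = 500,
    criterion: str = "CH",
    seed: int = 0,
) -> CriterionVote:
    """Mode-of-repetitions cluster-count vote under one validity index.

    Per repetition, every candidate k is clustered once with a single-start
    k-means and the arg-best k is recorded (ties toward the smaller k).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    x = np.asarray(getattr(data, "values", data), dtype=float)
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2 or ks[-1] >= x.shape[0]:
        raise ValueError("k_range must lie within {2, ..., n-1}")
    rng = np.random.default_rng(seed)
    votes: dict[int, int] = {}
    sign = 1.0 if HIGHER_IS_BETTER[criterion] else -1.0
    for _ in range(n_reps):
        best_k, best_score = None, -np.inf
        for k in ks:
            labels = kmeans(x, k, int(rng.integers(2 ** 31)))
            if len(np.unique(labels)) < 2:
                continue
            score = sign * internal_index(
                x, labels, criterion, seed=int(rng.integers(2 ** 31))
            )
            if score > best_score:   # strict: ties keep the smaller k
                best_k, best_score = k, score
        if best_k is not None:
            votes[best_k] = votes.get(best_k, 0) + 1
    return CriterionVote(criterion, votes, n_reps)
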