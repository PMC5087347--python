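"""Feature quality scores: multi-class ReliefF and the F-score filter.

ReliefF scores a feature by how well it separates each sample from its nearest
neighbours of other classes (misses) relative to its nearest neighbours of the
same class (hits). For every sample R_i, with k hits H_j and, per other class
C, k misses M_j(C), each feature weight is updated

    W(f) -= sum_j diff(f, R_i, H_j) / (m k)
    W(f) += sum_{C != class(R_i)} [P(C) / (1 - P(class(R_i)))]
            * sum_j diff(f, R_i, M_j(C)) / (m k)

where m is the number of samples iterated (all of the scoring set here),
P(C) is the empirical class prior of the scoring set, and

    diff(f, R1, R2) = |value(f, R1) - value(f, R2)| / (max(f) - min(f))

with the range taken over the scoring set. Neighbours are found by Euclidean
distance over all (normalized) features; ties are broken by lowest sample
index so the output is deterministic and invariant to sample order. A sample
is never its own hit. Each update term is a mean of diffs in [0, 1] scaled by
prior ratios summing to at most 1, so every final weight lies in [-1, 1].

The F-score of feature i over l classes with n_j samples in class j is

    F_i = sum_j n_j (xbar_ij - xbar_i)^2 / sum_j sum_k (x_kij - xbar_ij)^2

— between-class scatter of the class means over pooled within-class scatter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureTable


@dataclass(frozen=True)
class ReliefFConfig:
    """ReliefF hyperparameters.

    k is the neighbour count (default 10, a safe general-purpose choice);
    every sample of the scoring set is iterated, so m equals the set size.
    """

    k: int = 10

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass
class FeatureWeights:
    """Per-feature importance scores with a descending ranking."""

    weights: np.ndarray
    ranking: np.ndarray  # feature indices, best first; ties → lowest index
    class_priors: dict[str, float]
    method: str

    @property
    def n_features(self) -> int:
        return self.weights.shape[0]


def _rank_descending(weights: np.ndarray) -> np.ndarray:
    # stable sort on -w: equal weights keep ascending index order
    return np.argsort(-weights, kind="stable")


def diff(
    f: int,
    r1: np.ndarray,
    r2: np.ndarray,
    feature_range: tuple[np.ndarray, np.ndarray],
) -> float:
    """Range-scaled absolute feature difference between two samples, in [0, 1].

    A constant feature (zero range) carries no information and yields 0.
    """
    fmin, fmax = feature_range
    span = fmax[f] - fmin[f]
    if span <= 0:
        return 0.0
    return float(abs(r1[f] - r2[f]) / span)


def relieff(table: FeatureTable, config: ReliefFConfig | None = None) -> FeatureWeights:
    """Multi-class ReliefF weights of every feature of the scoring set."""
    config = config or ReliefFConfig()
    X = np.asarray(table.values, dtype=float)
    y = np.asarray(table.labels)
    if np.isnan(X).any():
        raise ValueError("feature table contains NaN")
    n, p = X.shape
    k = config.k

    classes, counts = np.unique(y, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt <= k:
            raise ValueError(
                f"class {cls!r} has {cnt} samples; ReliefF with k={k} needs more than k per class"
            )
    priors = {str(c): cnt / n for c, cnt in zip(classes, counts)}
    class_idx = {c: np.flatnonzero(y == c) for c in classes}

    span = X.max(axis=0) - X.min(axis=0)
    safe_span = np.where(span > 0, span, np.inf)  # constant feature → diff 0

    m = n
    W = np.zeros(p)
    for i in range(n):
        d = np.sum((X - X[i]) ** 2, axis=1)  # squared distances; ordering only
        own = y[i]
        same = class_idx[own]
        order = same[np.argsort(d[same], kind="stable")]
        hits = order[order != i][:k]  # never its own hit
        W -= np.sum(np.abs(X[hits] - X[i]) / safe_span, axis=0) / (m * k)
        denom = 1.0 - priors[str(own)]
        for c in classes:
            if c == own:
                continue
            cand = class_idx[c]
            misses = cand[np.argsort(d[cand], kind="stable")][:k]
            contrib = np.sum(np.abs(X[misses] - X[i]) / safe_span, axis=0)
            W += (priors[str(c)] / denom) * contrib / (m * k)

    return FeatureWeights(
        weights=W, ranking=_rank_descending(W), class_priors=priors, method="relieff"
    )


def fscore(table: FeatureTable) -> FeatureWeights:
    """F-score (between/within class scatter ratio) of every feature."""
    X = np.asarray(table.values, dtype=float)
    y = np.asarray(table.labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("F-score needs at least 2 classes")
    n = len(y)
    grand = X.mean(axis=0)
    between = np.zeros(X.shape[1])
    within = np.zeros(X.shape[1])
    for c, n_j in zip(classes, counts):
        Xc = X[y == c]
        mu_c = Xc.mean(axis=0)
        between += n_j * (mu_c - grand) ** 2
        within += np.sum((Xc - mu_c) ** 2, axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        F = between / within
    degenerate = (within == 0) & (between == 0)
    F[degenerate] = 0.0  # constant feature: defined as 0
    infinite = (within == 0) & (between > 0)
    if np.any(infinite):
        warnings.warn(
            f"{int(infinite.sum())} feature(s) have zero within-class scatter with "
            "nonzero between-class scatter; F-score is +inf and ranks first",
            RuntimeWarning,
            stacklevel=2,
        )
        F[infinite] = np.inf

    priors = {str(c): cnt / n for c, cnt in zip(classes, counts)}
    return FeatureWeights(
        weights=F, ranking=_rank_descending(F), class_priors=priors, method="fscore"
    )
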