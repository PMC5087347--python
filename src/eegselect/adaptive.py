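"""X-MRCS: classifier-in-the-loop refinement of channel weights.

Starting from the MRCS weights W_0(T), each iteration i

1. ranks channels by W_i and evaluates the accuracy curve S_i(n) — mean
   cross-validated accuracy of the wrapped classifier on the features of the
   top-n channels, n = 1..n_channels (all features of a selected channel are
   fed to the classifier);
2. computes each rank slot's relative contribution
   C_i(n) = (S_i(n) - S_i(n-1)) / S_i(n-1), which may be negative;
3. stops when every negative contribution is smaller than epsilon in absolute
   value (vacuously when none is negative), or after max_iterations updates;
4. otherwise updates W_{i+1}(T) = W_i(T) × (1 + C_i(n_T)) where n_T is the
   channel's current rank, and re-ranks.

C(1) has no S(0) to compare against and is defined as 0, so the top channel's
weight is never changed by its own slot (it still moves relative to others).
The loop only ever touches the channel-selection table it is given; validation
data stays outside.

The wrapped classifier is an RBF-kernel SVM with one-vs-one multi-class
strategy and library-default parameters (C = 1, gamma = 1/n_features),
evaluated by five repetitions of stratified 10-fold cross-validation. With a
fixed seed the whole trace is reproducible bit-for-bit; identical channel
prefixes are memoized across iterations so stabilized rankings cost nothing
to re-evaluate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.svm import SVC

from .features import FeatureTable
from .selection import ChannelWeights
from .weighting import _rank_descending


@dataclass(frozen=True)
class ClassifierSpec:
    """Wrapped classifier + cross-validation scheme.

    Defaults follow common SVM practice: RBF kernel, penalty C = 1,
    kernel width gamma = 1/n_features ("auto"), one-vs-one multi-class
    (sklearn's SVC is inherently one-vs-one), five 10-fold CVs.
    """

    kind: str = "svm-rbf"
    C: float = 1.0
    gamma: str | float = "auto"
    cv_folds: int = 10
    cv_repeats: int = 5
    seed: int = 0

    def make_classifier(self) -> SVC:
        if self.kind != "svm-rbf":
            raise ValueError(f"unsupported classifier kind {self.kind!r}")
        return SVC(kernel="rbf", C=self.C, gamma=self.gamma)

    def make_cv(self) -> RepeatedStratifiedKFold:
        return RepeatedStratifiedKFold(
            n_splits=self.cv_folds, n_repeats=self.cv_repeats, random_state=self.seed
        )


def cross_validated_accuracy(
    X: np.ndarray, y: np.ndarray, clf: ClassifierSpec
) -> np.ndarray:
    """Per-fold correct-classification fractions (cv_repeats × cv_folds,)."""
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < clf.cv_folds:
        lacking = classes[counts.argmin()]
        raise ValueError(
            f"class {lacking!r} has fewer samples ({counts.min()}) than folds "
            f"({clf.cv_folds}); stratification would leave folds without it"
        )
    accs = []
    for train, test in clf.make_cv().split(X, y):
        model = clf.make_classifier().fit(X[train], y[train])
        accs.append(float(np.mean(model.predict(X[test]) == y[test])))
    return np.asarray(accs)


def accuracy_curve(
    table: FeatureTable,
    ranking: np.ndarray,
    clf: ClassifierSpec,
    cache: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean CV accuracy S(n) for the top-n channels of *ranking*, n = 1..n_channels.

    Returns ``(S, per_fold)`` with ``per_fold`` shaped (n_channels, n_folds).
    ``cache`` (keyed by channel-prefix tuple) memoizes fold evaluations across
    calls with identical prefixes.
    """
    ranking = np.asarray(ranking)
    if sorted(ranking.tolist()) != list(range(table.n_channels)):
        raise ValueError("ranking must be a permutation of all channels")
    y = table.labels
    folds = []
    for n in range(1, len(ranking) + 1):
        prefix = tuple(int(c) for c in ranking[:n])
        if cache is not None and prefix in cache:
            accs = cache[prefix]
        else:
            cols = table.features_of_channels(prefix)
            accs = cross_validated_accuracy(table.values[:, cols], y, clf)
            if cache is not None:
                cache[prefix] = accs
        folds.append(accs)
    per_fold = np.stack(folds)
    return per_fold.mean(axis=1), per_fold


def contribution(curve: np.ndarray) -> np.ndarray:
    """Relative accuracy change C(n) = (S(n) − S(n−1)) / S(n−1); C(1) := 0."""
    S = np.asarray(curve, dtype=float)
    if np.any(S[:-1] <= 0):
        raise ValueError("S(n-1) must be positive to define a relative contribution")
    C = np.zeros_like(S)
    C[1:] = (S[1:] - S[:-1]) / S[:-1]
    return C


def update_weights(
    weights: np.ndarray, ranking: np.ndarray, contributions: np.ndarray
) -> np.ndarray:
    """Multiplicative update W(T) ← W(T) × (1 + C(n_T)) under the current ranking."""
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0):
        warnings.warn(
            "negative channel weight at update time: a positive contribution will "
            "decrease it further (multiplicative update applied literally)",
            RuntimeWarning,
            stacklevel=2,
        )
    new = weights.copy()
    for rank_pos, ch in enumerate(np.asarray(ranking)):
        new[ch] = weights[ch] * (1.0 + contributions[rank_pos])
    return new


@dataclass
class AdjustState:
    """Snapshot of one X-MRCS iteration."""

    iteration: int
    weights: np.ndarray
    ranking: np.ndarray
    curve: np.ndarray
    contributions: np.ndarray


@dataclass
class XMRCSResult:
    """Final channel weights plus the full iteration trace."""

    channel_weights: ChannelWeights
    trace: list[AdjustState]
    converged: bool

    @property
    def n_iterations(self) -> int:
        return len(self.trace)


def _max_negative(contributions: np.ndarray) -> float:
    neg = contributions[contributions < 0]
    return float(np.abs(neg).max()) if neg.size else 0.0


def xmrcs(
    table: FeatureTable,
    init: ChannelWeights,
    clf: ClassifierSpec | None = None,
    epsilon: float = 0.01,
    max_iterations: int = 50,
) -> XMRCSResult:
    """Run the full X-MRCS adjustment loop on the channel-selection table.

    *init* should be the MRCS weights (mean ReliefF weight per channel).
    Stops when the largest |negative contribution| drops below *epsilon*
    (``converged=True``) or after *max_iterations* weight updates
    (``converged=False``). Returns the final weights, ranking and trace.
    """
    clf = clf or ClassifierSpec()
    weights = np.asarray(init.weights, dtype=float).copy()
    ranking = _rank_descending(weights)
    cache: dict = {}
    trace: list[AdjustState] = []
    converged = False
    iteration = 0
    while True:
        S, _ = accuracy_curve(table, ranking, clf, cache=cache)
        C = contribution(S)
        trace.append(
            AdjustState(
                iteration=iteration,
                weights=weights.copy(),
                ranking=ranking.copy(),
                curve=S,
                contributions=C,
            )
        )
        if _max_negative(C) < epsilon:
            converged = True
            break
        if iteration >= max_iterations:
            break
        weights = update_weights(weights, ranking, C)
        ranking = _rank_descending(weights)
        iteration += 1
    final = ChannelWeights(
        weights=weights,
        ranking=ranking,
        provenance="xmrcs",
        channel_names=init.channel_names,
    )
    return XMRCSResult(channel_weights=final, trace=trace, converged=converged)
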