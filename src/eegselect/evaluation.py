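"""Performance validation: accuracy curves, band proportions, paired comparisons.

The validation harness mirrors the selection protocol's other half: given an
ordered channel (or feature) ranking produced on the channel-selection set, it
measures mean ± sd cross-validated accuracy on the held-out
performance-validation set for every prefix length. Folds are stratified by
class; by default they split at the sample level, with an optional
trial-grouped mode since sibling segments of one trial are correlated and can
inflate sample-level fold accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import RepeatedStratifiedKFold

from .adaptive import ClassifierSpec, cross_validated_accuracy
from .features import FeatureTable
from .weighting import FeatureWeights


@dataclass
class AccuracyCurve:
    """Mean ± sd accuracy as a function of the number of selected channels/features."""

    n_selected: np.ndarray
    mean_accuracy: np.ndarray
    sd_accuracy: np.ndarray
    per_fold: np.ndarray | None = None  # (len(n_selected), n_folds)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_selected": self.n_selected,
                "mean_accuracy": self.mean_accuracy,
                "sd_accuracy": self.sd_accuracy,
            }
        )


def _grouped_accuracy(
    X: np.ndarray, y: np.ndarray, groups: np.ndarray, clf: ClassifierSpec
) -> np.ndarray:
    """CV accuracies with whole trials kept in one fold (stratified over trials)."""
    trial_ids, first_idx = np.unique(groups, return_index=True)
    trial_labels = y[first_idx]
    cv = RepeatedStratifiedKFold(
        n_splits=clf.cv_folds, n_repeats=clf.cv_repeats, random_state=clf.seed
    )
    accs = []
    for tr, te in cv.split(trial_ids.reshape(-1, 1), trial_labels):
        train = np.isin(groups, trial_ids[tr])
        test = np.isin(groups, trial_ids[te])
        model = clf.make_classifier().fit(X[train], y[train])
        accs.append(float(np.mean(model.predict(X[test]) == y[test])))
    return np.asarray(accs)


def validate_selection(
    selection: Sequence[int],
    validation_table: FeatureTable,
    clf: ClassifierSpec | None = None,
    selection_trials: np.ndarray | None = None,
    kind: str = "channels",
    group_by_trial: bool = False,
) -> AccuracyCurve:
    """Accuracy curve over prefixes of an ordered channel (or feature) ranking.

    ``selection_trials`` — trial ids of the channel-selection set; if given,
    any overlap with the validation table's trials is a hard error (leakage).
    ``kind`` — "channels" feeds all features of the top-n channels at prefix n;
    "features" feeds exactly the top-n features.
    """
    clf = clf or ClassifierSpec()
    if selection_trials is not None:
        shared = np.intersect1d(
            np.unique(selection_trials), np.unique(validation_table.trial_of_sample)
        )
        if shared.size:
            raise ValueError(
                f"leakage: trials {shared.tolist()} appear in both the selection "
                "and validation sets"
            )
    if kind not in ("channels", "features"):
        raise ValueError("kind must be 'channels' or 'features'")
    y = validation_table.labels
    folds = []
    ns = np.arange(1, len(selection) + 1)
    for n in ns:
        if kind == "channels":
            cols = validation_table.features_of_channels(selection[:n])
        else:
            cols = np.asarray(selection[:n], dtype=int)
        X = validation_table.values[:, cols]
        if group_by_trial:
            accs = _grouped_accuracy(X, y, validation_table.trial_of_sample, clf)
        else:
            accs = cross_validated_accuracy(X, y, clf)
        folds.append(accs)
    per_fold = np.stack(folds)
    return AccuracyCurve(
        n_selected=ns,
        mean_accuracy=per_fold.mean(axis=1),
        sd_accuracy=per_fold.std(axis=1),
        per_fold=per_fold,
    )


@dataclass
class BandProportionTable:
    """Fraction of top-N features per band, one row per cutoff.

    Counts are kept as exact integers; ``proportions`` divides with rational
    arithmetic so every row sums to exactly 1.
    """

    cutoffs: list[int]
    band_names: list[str]
    counts: np.ndarray  # (len(cutoffs), len(band_names)) integer counts

    @property
    def proportions(self) -> np.ndarray:
        out = np.empty(self.counts.shape)
        for i, n in enumerate(self.cutoffs):
            for j in range(len(self.band_names)):
                out[i, j] = float(Fraction(int(self.counts[i, j]), int(n)))
        return out

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.proportions, index=pd.Index(self.cutoffs, name="top_n"), columns=self.band_names
        )


def band_proportions(
    weightings: FeatureWeights | Sequence[FeatureWeights],
    feature_bands: np.ndarray,
    cutoffs: Sequence[int],
    band_names: Sequence[str] | None = None,
) -> BandProportionTable | pd.DataFrame:
    """Band membership of the top-N features at each cutoff.

    With a single weighting, returns exact counts/proportions; with several
    (e.g. one per subject) returns the subject-averaged proportion frame.
    """
    feature_bands = np.asarray(feature_bands)
    if band_names is None:
        band_names = list(dict.fromkeys(feature_bands.tolist()))
    single = isinstance(weightings, FeatureWeights)
    fw_list = [weightings] if single else list(weightings)
    tables = []
    for fw in fw_list:
        if max(cutoffs) > fw.n_features:
            raise ValueError("cutoff exceeds number of features")
        counts = np.zeros((len(cutoffs), len(band_names)), dtype=int)
        for i, n in enumerate(cutoffs):
            top_bands = feature_bands[fw.ranking[:n]]
            for j, b in enumerate(band_names):
                counts[i, j] = int(np.sum(top_bands == b))
        tables.append(
            BandProportionTable(list(cutoffs), list(band_names), counts)
        )
    if single:
        return tables[0]
    frames = [t.as_frame() for t in tables]
    return sum(frames[1:], frames[0]) / len(frames)


def paired_comparison(
    per_subject_a: np.ndarray, per_subject_b: np.ndarray
) -> np.ndarray:
    """Two-sided paired t-test p-value at each prefix length.

    Inputs are (n_subjects, n_prefix) accuracy matrices on the same subject
    and prefix grids. Identical columns give p = 1; a constant nonzero
    difference has zero within-pair variance, is degenerate, and is flagged
    with a warning (p = NaN).
    """
    a = np.atleast_2d(np.asarray(per_subject_a, dtype=float))
    b = np.atleast_2d(np.asarray(per_subject_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("curves must share subjects and prefix grid")
    if a.shape[0] < 2:
        raise ValueError("paired t-test needs at least 2 subjects")
    pvals = np.empty(a.shape[1])
    for j in range(a.shape[1]):
        d = a[:, j] - b[:, j]
        if np.allclose(d.std(), 0.0):
            if np.allclose(d, 0.0):
                pvals[j] = 1.0  # t = 0 by convention
            else:
                warnings.warn(
                    f"degenerate paired comparison at column {j}: constant nonzero "
                    "difference (zero within-pair variance)",
                    RuntimeWarning,
                    stacklevel=2,
                )
                pvals[j] = np.nan
        else:
            pvals[j] = sps.ttest_rel(a[:, j], b[:, j]).pvalue
    return pvals
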