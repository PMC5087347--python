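"""Channel selection strategies built on feature weights.

Three ways to go from per-feature scores to channels:

* ``channels_from_top_features`` — the classic feature-selection route: take the
  top-N features, keep the distinct channels that own them.
* ``mrcs`` — mean-ReliefF channel selection: a channel's weight is the
  arithmetic mean of its features' weights, W(T) = (1/N) Σ W(f_i).
* ``subject_independent`` — cross-subject aggregation: a channel's weight is
  the sum of its per-subject (MRCS) weights over all subjects.

All rankings break ties by lower channel index so curves are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .weighting import FeatureWeights, _rank_descending


@dataclass
class ChannelWeights:
    """Per-channel importance with a descending, tie-broken ranking."""

    weights: np.ndarray
    ranking: np.ndarray
    provenance: str  # "mrcs" | "xmrcs" | "subject_independent"
    channel_names: list[str] | None = None

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]


@dataclass
class ChannelSelection:
    """Ordered channel subset produced by one strategy."""

    selected: list[int]
    source: str
    n_features_requested: int | None = None


def channels_from_top_features(
    fw: FeatureWeights, feature_channels: np.ndarray, n: int
) -> ChannelSelection:
    """Distinct channels owning the N best features, ordered by first appearance."""
    if not 1 <= n <= fw.n_features:
        raise ValueError(f"N must lie in 1..{fw.n_features}")
    seen: list[int] = []
    for f in fw.ranking[:n]:
        ch = int(feature_channels[f])
        if ch not in seen:
            seen.append(ch)
    return ChannelSelection(selected=seen, source="topn-features", n_features_requested=n)


def mrcs(
    fw: FeatureWeights,
    feature_channels: np.ndarray,
    n_channels: int | None = None,
    channel_names: list[str] | None = None,
) -> ChannelWeights:
    """Mean of each channel's feature weights; the MRCS channel ranking."""
    feature_channels = np.asarray(feature_channels)
    if n_channels is None:
        n_channels = int(feature_channels.max()) + 1
    weights = np.empty(n_channels)
    for ch in range(n_channels):
        owned = fw.weights[feature_channels == ch]
        if owned.size == 0:
            raise ValueError(f"channel {ch} owns no features")
        weights[ch] = owned.mean()
    return ChannelWeights(
        weights=weights,
        ranking=_rank_descending(weights),
        provenance="mrcs",
        channel_names=channel_names,
    )


def subject_independent(per_subject: Sequence[ChannelWeights]) -> ChannelWeights:
    """Sum per-subject channel weights into one cross-subject ranking."""
    if len(per_subject) == 0:
        raise ValueError("need at least one subject")
    first = per_subject[0]
    for cw in per_subject[1:]:
        if cw.n_channels != first.n_channels:
            raise ValueError("subjects have mismatched channel counts")
        if (
            cw.channel_names is not None
            and first.channel_names is not None
            and cw.channel_names != first.channel_names
        ):
            raise ValueError("subjects have mismatched channel sets")
    total = np.sum([cw.weights for cw in per_subject], axis=0)
    return ChannelWeights(
        weights=total,
        ranking=_rank_descending(total),
        provenance="subject_independent",
        channel_names=first.channel_names,
    )
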