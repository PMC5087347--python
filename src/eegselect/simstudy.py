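"""Reproducible synthetic study scenarios for the selection stack.

Each function wires the full pipeline — generate → band-power features →
z-score → trial-level split → ReliefF → channel selection — into one of the
package's standard validation scenarios and reports a summary rate or curve:

* planted-channel recovery by MRCS on a full DEAP-shaped subject;
* planted-channel recovery by cross-subject aggregation over several subjects;
* chance-level control (no planted effect, permuted labels);
* demotion of a deliberately over-weighted noise channel by X-MRCS.

All randomness derives from a single base seed, so every scenario is
reproducible end to end.
"""

from __future__ import annotations

import warnings

import numpy as np

from .adaptive import ClassifierSpec, xmrcs
from .evaluation import validate_selection
from .features import extract_features, split_dataset, zscore
from .selection import ChannelWeights, mrcs, subject_independent
from .synthetic import GeneratorSpec, generate_subject
from .weighting import ReliefFConfig, _rank_descending, relieff

#: the standard planted-effect scenario: two informative channels with a
#: ×2-amplitude gamma component for one class each
PLANTED_CHANNELS: tuple[int, int] = (3, 17)
PLANTED_EFFECTS = {
    ("joy", 3, "gamma"): 2.0,
    ("fear", 17, "gamma"): 2.0,
}


def child_seeds(base_seed: int, n: int) -> np.ndarray:
    """Deterministic stream of n child seeds below 2**31."""
    return np.random.SeedSequence(base_seed).generate_state(n) % (2**31)


def deap_like_spec(seed: int, effects=None, **overrides) -> GeneratorSpec:
    """A 32-channel, 128-Hz, 40×60-s subject; effects default to none."""
    return GeneratorSpec(seed=int(seed), effect_map=dict(effects or {}), **overrides)


def subject_selection_tables(spec: GeneratorSpec, split_seed: int):
    """Generate a subject and return its (selection, validation) z-scored halves."""
    trials = generate_subject(spec)
    table = zscore(extract_features(trials))
    return split_dataset(table, seed=int(split_seed))


def mrcs_for_subject(spec: GeneratorSpec, split_seed: int, k: int = 10) -> ChannelWeights:
    """MRCS channel weights from the subject's channel-selection half."""
    sel, _ = subject_selection_tables(spec, split_seed)
    fw = relieff(sel, ReliefFConfig(k=k))
    return mrcs(fw, sel.feature_channels, sel.n_channels, sel.channel_names)


def mrcs_recovery_rate(
    n_seeds: int = 50,
    base_seed: int = 0,
    planted=PLANTED_CHANNELS,
    effects=None,
    top: int = 3,
) -> float:
    """Fraction of seeds for which MRCS ranks every planted channel in the top *top*."""
    effects = effects or PLANTED_EFFECTS
    seeds = child_seeds(base_seed, 2 * n_seeds).reshape(n_seeds, 2)
    hits = 0
    for gen_seed, split_seed in seeds:
        cw = mrcs_for_subject(deap_like_spec(gen_seed, effects), split_seed)
        if set(planted) <= set(int(c) for c in cw.ranking[:top]):
            hits += 1
    return hits / n_seeds


def subject_independent_recovery_rate(
    n_seeds: int = 30,
    base_seed: int = 0,
    n_subjects: int = 8,
    planted=PLANTED_CHANNELS,
    effects=None,
    top: int = 2,
    trial_duration: float = 20.0,
) -> float:
    """Fraction of seeds for which the cross-subject ranking puts the shared
    planted channels in the top *top*.

    Subjects share the planted channels but have independent noise; each
    subject uses a shortened trial (default 20 s → 200 samples) to keep the
    aggregate study compact.
    """
    effects = effects or PLANTED_EFFECTS
    seeds = child_seeds(base_seed, n_seeds)
    hits = 0
    for rep_seed in seeds:
        subj_seeds = child_seeds(int(rep_seed), 2 * n_subjects).reshape(n_subjects, 2)
        per_subject = [
            mrcs_for_subject(
                deap_like_spec(gs, effects, trial_duration=trial_duration), ss
            )
            for gs, ss in subj_seeds
        ]
        agg = subject_independent(per_subject)
        if set(planted) <= set(int(c) for c in agg.ranking[:top]):
            hits += 1
    return hits / n_seeds


def chance_level_curve(
    n_subjects: int = 8, base_seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Mean validated accuracy curve with no planted effect and permuted labels.

    For each subject: generate pure-noise trials, permute the trial ratings
    (breaking any residual trial→signal association), run the full
    selection-then-validation pipeline, and average the per-subject curves.
    Returns ``(n_selected, mean_curve)``; with four balanced classes the curve
    should hover at chance (0.25) at every prefix length.
    """
    seeds = child_seeds(base_seed, 3 * n_subjects).reshape(n_subjects, 3)
    curves = []
    for gen_seed, split_seed, perm_seed in seeds:
        spec = deap_like_spec(gen_seed)
        trials = generate_subject(spec)
        perm = np.random.default_rng(int(perm_seed)).permutation(trials.n_trials)
        trials.valence = trials.valence[perm]
        trials.arousal = trials.arousal[perm]
        table = zscore(extract_features(trials))
        sel, val = split_dataset(table, seed=int(split_seed))
        fw = relieff(sel)
        cw = mrcs(fw, sel.feature_channels, sel.n_channels)
        curve = validate_selection(
            [int(c) for c in cw.ranking],
            val,
            ClassifierSpec(seed=int(split_seed)),
            selection_trials=sel.trial_of_sample,
        )
        curves.append(curve.mean_accuracy)
        ns = curve.n_selected
    return ns, np.mean(curves, axis=0)


DEMOTION_EFFECTS = {
    ("joy", 1, "gamma"): 2.0,
    ("fear", 4, "beta"): 2.0,
    ("sadness", 6, "alpha"): 2.0,
}


def xmrcs_demotion_rate(
    n_seeds: int = 20,
    base_seed: int = 0,
    noise_channel: int = 0,
    epsilon: float = 0.01,
    max_iterations: int = 50,
) -> float:
    """Fraction of seeds for which X-MRCS demotes an over-weighted noise channel.

    An 8-channel subject carries three informative channels; a pure-noise
    channel is then handed the highest initial weight (a deliberately wrong
    MRCS estimate). The adjustment loop should discover its lack of
    contribution and let informative channels overtake it: demotion means its
    final rank is strictly worse than its initial rank 1.
    """
    import warnings

    seeds = child_seeds(base_seed, 3 * n_seeds).reshape(n_seeds, 3)
    demoted = 0
    for gen_seed, split_seed, clf_seed in seeds:
        spec = deap_like_spec(
            gen_seed,
            DEMOTION_EFFECTS,
            n_channels=8,
            n_trials=24,
            trial_duration=20.0,
        )
        sel, _ = subject_selection_tables(spec, split_seed)
        fw = relieff(sel)
        cw = mrcs(fw, sel.feature_channels, sel.n_channels, sel.channel_names)
        weights = cw.weights.copy()
        weights[noise_channel] = weights.max() + abs(weights.max()) * 0.1 + 0.01
        init = ChannelWeights(
            weights=weights,
            ranking=_rank_descending(weights),
            provenance="mrcs",
            channel_names=cw.channel_names,
        )
        initial_pos = int(np.flatnonzero(init.ranking == noise_channel)[0])
        with warnings.catch_warnings():
            # the planted-noise setup makes negative weights routine; the
            # per-update warning would only drown the study's summary
            warnings.simplefilter("ignore", RuntimeWarning)
            result = xmrcs(
                sel,
                init,
                ClassifierSpec(seed=int(clf_seed)),
                epsilon=epsilon,
                max_iterations=max_iterations,
            )
        final_pos = int(
            np.flatnonzero(result.channel_weights.ranking == noise_channel)[0]
        )
        if final_pos > initial_pos:
            demoted += 1
    return demoted / n_seeds
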