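"""Adjust channel weights with the classifier in the loop (X-MRCS).

Starts from MRCS weights in which a pure-noise channel was deliberately given
the top weight, then lets the accuracy-contribution loop demote it.
"""

import warnings

import numpy as np

from eegselect import ClassifierSpec, GeneratorSpec, extract_features, mrcs, split_dataset, xmrcs, zscore
from eegselect.selection import ChannelWeights
from eegselect.synthetic import generate_subject
from eegselect.weighting import ReliefFConfig, _rank_descending, relieff

spec = GeneratorSpec(
    seed=3,
    n_channels=8,
    n_trials=24,
    trial_duration=20.0,
    effect_map={
        ("joy", 1, "gamma"): 2.0,
        ("fear", 4, "beta"): 2.0,
        ("sadness", 6, "alpha"): 2.0,
    },
)
table = zscore(extract_features(generate_subject(spec)))
sel, _ = split_dataset(table, seed=3)

fw = relieff(sel, ReliefFConfig(k=10))
cw = mrcs(fw, sel.feature_channels, sel.n_channels, sel.channel_names)
weights = cw.weights.copy()
weights[0] = weights.max() + 0.05  # hand the noise channel the top weight
init = ChannelWeights(weights, _rank_descending(weights), "mrcs", cw.channel_names)
print("initial ranking:", [sel.channel_names[c] for c in init.ranking])

with warnings.catch_warnings():
    warnings.simplefilter("ignore", RuntimeWarning)  # negative noise weights
    result = xmrcs(sel, init, ClassifierSpec(cv_folds=5, cv_repeats=2, seed=3))

print(f"converged: {result.converged} after {result.n_iterations} curve evaluations")
for state in result.trace[:3]:
    pos = int(np.flatnonzero(state.ranking == 0)[0]) + 1
    print(f"  iter {state.iteration}: noise channel at rank {pos}, "
          f"S(1..3) = {np.round(state.curve[:3], 3)}")
final_pos = int(np.flatnonzero(result.channel_weights.ranking == 0)[0]) + 1
print(f"final rank of the noise channel: {final_pos} (started at 1)")
# A rank > 1 means the loop detected that the channel contributes nothing to
# classification accuracy and let informative channels overtake it.
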