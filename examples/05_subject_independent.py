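"""Aggregate channel weights across subjects into one common ranking.

Four synthetic subjects share the same two informative channels but have
independent noise; summing their per-subject MRCS weights recovers the shared
channels at the top of the cross-subject ranking.
"""

from eegselect import subject_independent
from eegselect.montage import DEAP_CHANNELS, lobe_of
from eegselect.simstudy import PLANTED_EFFECTS, child_seeds, deap_like_spec, mrcs_for_subject

seeds = child_seeds(base_seed=9, n=8).reshape(4, 2)
per_subject = [
    mrcs_for_subject(deap_like_spec(gs, PLANTED_EFFECTS, trial_duration=20.0), ss)
    for gs, ss in seeds
]
for i, cw in enumerate(per_subject):
    print(f"subject {i}: top-3 channels {[DEAP_CHANNELS[c] for c in cw.ranking[:3]]}")

agg = subject_independent(per_subject)
print("\ncross-subject ranking (top 5):")
for rank, ch in enumerate(agg.ranking[:5], start=1):
    print(f"  {rank}. {DEAP_CHANNELS[ch]:>4}  weight {agg.weights[ch]:+.4f}  "
          f"({lobe_of(DEAP_CHANNELS[ch])})")
# The planted channels F7 and AF4 should occupy ranks 1-2: subject-specific
# noise averages out while the shared effect accumulates.
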