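"""Select channels by MRCS and validate the ranking on held-out trials.

Splits a planted subject's trials 50/50, computes MRCS channel weights on the
selection half, and measures the SVM accuracy curve on the validation half.
"""

from eegselect import (
    ClassifierSpec,
    GeneratorSpec,
    extract_features,
    generate_subject,
    mrcs,
    split_dataset,
    validate_selection,
    zscore,
)
from eegselect.weighting import ReliefFConfig, relieff

spec = GeneratorSpec(
    seed=5,
    trial_duration=20.0,
    effect_map={("joy", 3, "gamma"): 2.0, ("fear", 17, "gamma"): 2.0},
)
table = zscore(extract_features(generate_subject(spec)))
sel, val = split_dataset(table, seed=5)

fw = relieff(sel, ReliefFConfig(k=10))
cw = mrcs(fw, sel.feature_channels, sel.n_channels, sel.channel_names)
names = [sel.channel_names[c] for c in cw.ranking[:5]]
print(f"MRCS top-5 channels: {', '.join(names)}")

curve = validate_selection(
    [int(c) for c in cw.ranking],
    val,
    ClassifierSpec(seed=5),
    selection_trials=sel.trial_of_sample,
)
for n in (1, 2, 4, 8, 16, 32):
    print(f"top-{n:2d} channels: accuracy {curve.mean_accuracy[n-1]:.3f} "
          f"± {curve.sd_accuracy[n-1]:.3f}")
# Accuracy should jump once both planted channels are included and then
# plateau — extra channels add features but no new class information.
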