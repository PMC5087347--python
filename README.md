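# eegselect

ReliefF-based EEG sensor-channel selection for emotion-state classification.

Multi-channel EEG systems record 32+ electrodes, but for a practical
(wearable, real-time) emotion-recognition system most channels are noise or
redundancy: they add computation, cost and user inconvenience, and can even
hurt accuracy. `eegselect` implements and evaluates strategies that rank
whole *channels* — not just individual features — by their contribution to
discriminating four emotional states (joy, fear, sadness, relaxation)
defined by valence/arousal quadrants.

## What it computes

From trial-structured signals (trials × channels × time, each trial rated
1–9 for valence and arousal) the pipeline extracts band-power features per
4-s window — theta (4–8 Hz), alpha (8–13 Hz), beta (13–30 Hz), gamma
(30–45 Hz), power = (1/N)·Σ|X(k)|² of the band-filtered window — z-scores
them, and splits trials 50/50 into a channel-selection and a
performance-validation set. It then supports:

* **ReliefF feature weights** W(f): for each sample, k = 10 nearest hits
  H and per-class misses M(C) update

  W(f) ← W(f) − Σⱼ diff(f, R, Hⱼ)/(mk) + Σ_C [P(C)/(1−P(class(R)))] Σⱼ diff(f, R, Mⱼ(C))/(mk),

  with diff the range-scaled absolute difference; plus an **F-score** filter
  (between/within class scatter) for comparison.
* **Channel selection** three ways: channels owning the top-N features;
  **MRCS** — channel weight W(T) = mean of its features' ReliefF weights;
  and **X-MRCS** — iterative re-weighting W(T) ← W(T)·(1 + C(n_T)) by each
  channel's relative contribution C(n) = (S(n)−S(n−1))/S(n−1) to the SVM
  accuracy curve S(n), until negative contributions fall below ε = 0.01 (or
  50 iterations).
* **Subject-independent ranking**: W(T) = Σ_s W_s(T) across subjects.
* **Validation**: five stratified 10-fold cross-validations of an RBF SVM
  (one-vs-one, default C and γ) per prefix of the ranking, with band
  proportions among top-N features and paired t-tests between strategies.

A synthetic-subject generator reproduces the standard layout (32 channels,
128 Hz, 40 one-minute trials) with class-dependent band-power effects
planted in known channels, so every claim above is testable end to end
without access to gated recordings. See `docs/methods.md` for the full
model, defaults and limitations.

## Worked example

`examples/03_channel_selection.py` plants ×2-amplitude gamma effects in
channels F7 and AF4 of one synthetic subject, ranks channels by MRCS on half
of the trials, and validates on the held-out half:

```
MRCS top-5 channels: AF4, F7, T7, P4, Fz
top- 1 channels: accuracy 0.492 ± 0.115
top- 2 channels: accuracy 0.778 ± 0.108
top- 4 channels: accuracy 0.736 ± 0.116
top- 8 channels: accuracy 0.646 ± 0.158
top-16 channels: accuracy 0.530 ± 0.127
top-32 channels: accuracy 0.548 ± 0.122
```

Both planted channels are found first; accuracy jumps from near chance
(0.25 for four classes) to its ceiling once the second planted channel
enters, then *degrades* as uninformative channels dilute the SVM — the
motivating observation for channel reduction. The other examples cover the
generator, feature ranking, the X-MRCS demotion loop and subject-independent
aggregation; each prints its numbers with a line on what they mean.

The same stack is scriptable from the shell:

```bash
eegselect simulate --config gen.yaml --out subject.npz --seed 3
eegselect extract-features --in subject.npz --out features.tsv
eegselect rank --method relieff --k 10 --in features.tsv --out weights.tsv
eegselect select --strategy xmrcs --in features.tsv --out ranking.tsv
eegselect run --config run.yaml --out results/   # end to end
```

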