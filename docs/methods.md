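# Methods

`eegselect` implements a channel-selection stack for multi-channel,
trial-structured EEG in emotion-recognition settings: band-power features,
ReliefF (and F-score) feature weighting, three channel-selection strategies,
and an SVM cross-validation harness, together with a synthetic-subject
generator that makes the whole stack testable without access to gated
recordings. This note records the model, the defaults and why they are what
they are, the numerical choices, and what the synthetic studies do and do not
demonstrate.

## Protocol and data model

A *subject* is a set of trials — `trials × channels × time` at a fixed
sampling rate — each trial rated 1–9 on valence and arousal. The defaults
mirror a widely used preprocessed-emotion-EEG layout: 32 channels (10–20
montage, Geneva ordering), 128 Hz, 40 one-minute trials. Trials are labeled
by valence/arousal quadrant with the midpoint 5 on the high side: joy
(v ≥ 5, a ≥ 5), fear (v < 5, a ≥ 5), sadness (v < 5, a < 5), relaxation
(v ≥ 5, a < 5).

Each trial is cut into non-overlapping 4-s windows (15 per 60-s trial,
600 samples per subject); every window inherits its trial's label. Windows
are band-pass filtered into theta (4–8 Hz), alpha (8–13 Hz), beta (13–30 Hz)
and gamma (30–45 Hz) and each band's power is `(1/N)·Σ_k |X(k)|²` over all
N FFT bins of the filtered window (N = window length, 512 samples), giving
`channels × 4` features (128 by default). Features are z-scored per column.

Trials are then split 50/50 at the *trial* level, stratified by class: all
windows of a trial land on the same side. The selection half drives every
weighting and adjustment step; the validation half is only ever touched by
the evaluation harness, which enforces trial-disjointness as a hard error.

## Feature weighting

**ReliefF.** All weights start at zero; for every sample of the scoring set,
its k = 10 nearest same-class neighbours (hits) and, for each other class C,
its k nearest members (misses) are found by Euclidean distance over all
normalized features. Each feature's weight is decreased by the mean
range-scaled hit difference and increased by the prior-weighted mean miss
differences, `P(C)/(1 − P(class(R)))` being the prior ratio, everything
divided by `m·k` with m the scoring-set size (every sample is iterated; no
subsampling). Consequences worth stating:

* every weight lies in [−1, 1] by construction;
* a constant feature gets weight exactly 0 (its range-scaled difference is
  defined as 0);
* ties in neighbour distance are broken by lowest sample index, a sample is
  never its own hit, and the ranking tie-breaks by lowest feature index, so
  the output is deterministic and invariant to sample order;
* feature ranges, class priors and m are all taken from the scoring set
  (the set the loop iterates), not the full subject.

The neighbour search is written directly (squared-distance argsort with a
stable sort) rather than delegated to a neighbour library, so the test
suite's literal O(n²) oracle is a genuinely independent second route.

**F-score.** Per feature, the weighted squared deviation of class means from
the grand mean over pooled within-class scatter. Degenerate cases: zero
between- and within-class scatter → 0; zero within- with positive
between-class scatter → +inf, flagged with a warning and ranked first.

## Channel selection

* **Top-N-feature channels** — the distinct channels owning the N
  best-ranked features, ordered by first appearance; monotone in N.
* **MRCS** — a channel's weight is the arithmetic mean of its features'
  weights; ranking descending, ties to the lower channel index.
* **Subject-independent** — a channel's weight is the *sum* of its
  per-subject MRCS weights (a sum, not a mean, as the aggregation is defined;
  the ranking is unaffected by the 1/S factor either way).

## X-MRCS adjustment

Starting from the MRCS weights, each iteration evaluates the accuracy curve
S(n) — mean cross-validated accuracy of the wrapped classifier on all
features of the top-n channels — computes each rank slot's relative
contribution `C(n) = (S(n) − S(n−1))/S(n−1)`, and multiplies every channel's
weight by `1 + C(n_T)` at its current rank before re-ranking. The loop stops
when no negative contribution reaches ε = 0.01 in absolute value (vacuously
when none is negative) or after 50 updates, in which case the last state is
returned with a non-convergence flag rather than an error.

Decisions the update formula leaves open, and what this implementation does:

* **C(1)** has no S(0); it is defined as 0, so the top channel's weight is
  never changed by its own slot (it can still be overtaken).
* **Negative weights** invert the intended update direction under the
  multiplicative rule; the rule is applied literally and a runtime warning is
  emitted whenever a weight is negative at update time. Negative MRCS weights
  are common for uninformative channels, so the warning mostly documents
  movements in the noise floor of the ranking.
* The contribution used in an update is the one computed under the *previous*
  ranking (the indices of the update rule say as much); the curve is then
  recomputed from scratch under the new ranking. Identical channel prefixes
  are memoized across iterations — with a deterministic classifier and fixed
  fold seed this is a pure cache, and once the ranking stabilizes further
  iterations cost nothing.
* ε compares against the contribution *value* (0.01 ↔ a 1% relative change).
* The loop only ever sees the channel-selection table; tests assert the
  validation half cannot leak in.

The wrapped classifier is an RBF-kernel SVM with one-vs-one multi-class
handling and library defaults — penalty C = 1 and kernel width
γ = 1/n_features (`gamma="auto"`; features are z-scored, so this is
practically indistinguishable from variance-scaled γ) — evaluated by five
repetitions of stratified 10-fold cross-validation with distinct fold splits
per repetition. Stratification is used because quadrant classes are rarely
perfectly balanced in real ratings and unstratified folds can lose a class
entirely; fold splits are at the sample level by default (a trial-grouped
mode exists because sibling windows of one trial are correlated, which
inflates sample-level fold accuracy — a caveat, not a default, to keep the
standard protocol).

Normalization statistics are fitted on the full subject before splitting by
default (matching the "over all samples" convention); this leaks marginal
feature scale — not labels — across the split, and a fit-on-selection-only
mode is available via `zscore(table, stats=...)`.

## Synthetic subjects

The generator emulates the trial-structured layout above. Background noise
is white Gaussian (optionally 1/f-shaped); planted effects are *band-limited
Gaussian noise* — filtered white noise, not pure tones, so band spectra
resemble EEG and band power is not degenerate — added to the trials of one
class in one channel and band. The planted component's standard deviation is
`multiplier × noise_sd × √(bandwidth/Nyquist)`, i.e. *multiplier* times the
background amplitude in that band, so a multiplier m raises that band's
expected power by the factor 1 + m² for the effect class. Ratings are drawn
uniformly inside the quadrant of the trial's class. Everything is
deterministic given the seed, including the order effects are added (sorted
effect-map keys).

What the generator does **not** model: volume conduction and inter-electrode
correlation, ocular/muscle artifacts, non-stationarity within a trial, and
1/f background by default. Passing the recovery studies therefore shows the
pipeline's statistical machinery is sound — not that comparable accuracy
would be reached on real recordings, where effects are weaker, correlated
across channels and non-stationary.

## Numerical choices

* **Band filters**: zero-phase 4th-order Butterworth, applied
  forward-backward (odd extension of 3×(taps) samples, steady-state initial
  conditions) — standard phase-neutral EEG practice. The implementation is
  written against `lfilter` directly and matches `scipy.signal.filtfilt`
  bit-for-bit; it exists because the one-shot library call was a measured
  hotspot at this call shape.
* **Band power** reads the power formula literally: filter first, then sum
  *all* FFT bins of the filtered window. Summing band bins of the raw window
  differs only by filter leakage. The conjugate-symmetry shortcut
  (`rfft`-based full-bin sum) is exact for real signals. No FFT taper is
  applied; adjacent Butterworth bands cross at −3 dB, so the four band powers
  of a 4–45 Hz signal reconstruct its total power to within roll-off
  tolerance (the suite asserts 15%).
* **z-score** uses the population (divide-by-n) standard deviation;
  constant columns become zeros with a warning.
* **σ = 0, range = 0, S(n−1) ≤ 0, empty classes** are all guarded with
  explicit errors or documented conventions rather than NaNs.
* The paired comparison between strategy curves is a two-sided paired t-test
  per prefix length; identical curves give p = 1 by convention, constant
  nonzero differences (zero within-pair variance) are flagged as degenerate.

## Study problem sizes

The Monte-Carlo suites fix their problem sizes a priori from standard-error
arguments, and their thresholds are never adapted to outcomes:

* *MRCS planted recovery*: full-size subjects (600 samples), two planted
  channels at multiplier 2, 50 seeds; both channels must reach the top 3.
* *Subject-independent recovery*: 8 subjects per replicate with 20-s trials
  (200 samples each, the same planted channels, independent noise),
  30 seeds; both channels must reach the top 2.
* *Chance-level control*: no effects, trial labels permuted, the full
  selection-then-validation pipeline per subject, averaged over 8 subjects.
  Per prefix the mean's standard error is ≈0.9 percentage points
  (300 validation samples × 8 subjects), so the 3-pp acceptance band sits at
  ≈3.3 SE.
* *X-MRCS demotion*: 8-channel subjects (24 trials × 20 s), three planted
  channels, one pure-noise channel handed the top initial weight, 20 seeds;
  demotion means a strictly worse final rank.

## Known limitations

* Sample-level CV folds overstate accuracy whenever sibling windows of one
  trial span folds; the trial-grouped mode exists for that reason.
* ReliefF distances use all normalized features; no band-restricted or
  alternative metrics.
* The X-MRCS result is classifier-specific by construction; nothing is
  claimed about transfer to other classifiers.
* The generator's exchangeable white-noise channels make planted effects
  easier to find than real, spatially correlated EEG effects; recovery rates
  here are upper bounds on what identical settings would achieve on real
  data.
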