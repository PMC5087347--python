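"""Labeling, segmentation, band power, normalization and the trial-level split."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegselect.features import (
    BandDefinition,
    band_power,
    bandpass,
    default_band_definitions,
    label_trial,
    segment_trials,
    split_dataset,
    zscore,
)
from conftest import make_table
from _oracles import dft_band_power_oracle

FS = 128.0
BANDS = {b.name: b for b in default_band_definitions()}


class TestLabeling:
    @pytest.mark.parametrize(
        "valence,arousal,expected",
        [
            (5.0, 5.0, "joy"),
            (4.9, 5.0, "fear"),
            (1.0, 1.0, "sadness"),
            (5.0, 4.9, "relaxation"),
            (9.0, 9.0, "joy"),
            (4.999, 4.999, "sadness"),
        ],
    )
    def test_quadrant_rule(self, valence, arousal, expected):
        assert label_trial(valence, arousal) == expected

    @pytest.mark.parametrize("valence,arousal", [(0.5, 5.0), (5.0, 9.5), (-1, 3)])
    def test_out_of_range_rating_rejected(self, valence, arousal):
        with pytest.raises(ValueError):
            label_trial(valence, arousal)

    @given(
        valence=st.floats(1.0, 9.0, allow_nan=False),
        arousal=st.floats(1.0, 9.0, allow_nan=False),
    )
    @settings(max_examples=50, derandomize=True)
    def test_label_consistent_with_midpoint_rule(self, valence, arousal):
        label = label_trial(valence, arousal)
        high_v, high_a = valence >= 5, arousal >= 5
        assert label == {
            (True, True): "joy",
            (False, True): "fear",
            (False, False): "sadness",
            (True, False): "relaxation",
        }[(high_v, high_a)]


class TestSegmentation:
    def test_sixty_second_trial_gives_fifteen_windows(self, rng):
        signals = rng.standard_normal((2, 3, int(60 * FS)))
        segs, owner = segment_trials(signals, FS, window=4.0)
        assert segs.shape == (30, 3, 512)
        assert np.array_equal(owner, np.repeat([0, 1], 15))

    def test_forty_trials_give_six_hundred_samples(self, rng):
        signals = rng.standard_normal((40, 1, int(60 * FS)))
        segs, _ = segment_trials(signals, FS, window=4.0)
        assert segs.shape[0] == 600

    def test_window_equal_to_trial_gives_one_segment(self, rng):
        signals = rng.standard_normal((1, 2, 512))
        segs, _ = segment_trials(signals, FS, window=4.0)
        assert segs.shape == (1, 2, 512)

    def test_segments_partition_the_used_portion(self, rng):
        signals = rng.standard_normal((1, 2, 1300))  # 1300 = 2×512 + remainder
        segs, _ = segment_trials(signals, FS, window=4.0)
        assert segs.shape[0] == 2
        reconstructed = np.concatenate([segs[0], segs[1]], axis=-1)
        assert np.array_equal(reconstructed, signals[0, :, :1024])

    def test_window_longer_than_trial_rejected(self, rng):
        with pytest.raises(ValueError):
            segment_trials(rng.standard_normal((1, 1, 256)), FS, window=4.0)


class TestBandPower:
    def test_zero_signal_has_zero_power(self):
        assert band_power(np.zeros(512), BANDS["alpha"], FS) == 0.0

    def test_alpha_tone_matches_literal_dft_oracle(self):
        """A 10 Hz unit tone in the alpha band: the implementation must agree
        with an explicit O(N²) DFT + full-bin power sum on the same filtered
        segment, and sit within 1% of the analytic N/2 tone power."""
        t = np.arange(512) / FS
        tone = np.sin(2 * np.pi * 10.0 * t)
        got = band_power(tone, BANDS["alpha"], FS)
        filtered = bandpass(tone, BANDS["alpha"], FS)
        oracle = dft_band_power_oracle(filtered)
        assert got == pytest.approx(oracle, rel=1e-9)
        assert got == pytest.approx(256.0, rel=0.01)  # sum sin² = N/2

    def test_tone_outside_band_is_suppressed(self):
        t = np.arange(512) / FS
        tone = np.sin(2 * np.pi * 10.0 * t)
        assert band_power(tone, BANDS["gamma"], FS) < 0.01 * 256.0

    def test_band_powers_sum_to_broadband_power(self, rng):
        """theta+alpha+beta+gamma of a 4-45 Hz band-limited signal recovers its
        total power up to filter roll-off (documented 15% tolerance)."""
        wide = BandDefinition("wide", 4.0, 45.0)
        x = bandpass(rng.standard_normal(2048), wide, FS)
        total = float(np.sum(x**2))
        parts = sum(
            float(np.sum(bandpass(x, b, FS) ** 2)) for b in BANDS.values()
        )
        assert parts == pytest.approx(total, rel=0.15)

    def test_fft_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            band_power(np.zeros(256), BANDS["alpha"], FS, n_fft=512)


class TestZscore:
    def test_matches_direct_formula(self):
        table = make_table(np.array([[1.0], [2.0], [3.0]]), ["a", "b", "c"], n_bands=1)
        out = zscore(table)
        sd = np.sqrt(2.0 / 3.0)  # population convention
        np.testing.assert_allclose(out.values[:, 0], np.array([-1, 0, 1]) / sd)
        assert out.mean[0] == 2.0

    def test_idempotent_on_standardized_input(self, rng):
        X = rng.standard_normal((50, 4))
        X = (X - X.mean(0)) / X.std(0)
        out = zscore(make_table(X, ["a", "b"] * 25, n_bands=4))
        np.testing.assert_allclose(out.values, X, atol=1e-12)

    def test_constant_column_zeroed_with_warning(self):
        table = make_table(np.array([[5.0], [5.0], [5.0]]), list("abc"), n_bands=1)
        with pytest.warns(RuntimeWarning, match="constant"):
            out = zscore(table)
        assert np.all(out.values == 0.0)

    def test_stats_reusable_on_held_out_samples(self, rng):
        fit = make_table(rng.standard_normal((40, 2)), ["a", "b"] * 20, n_bands=2)
        fitted = zscore(fit)
        held = make_table(rng.standard_normal((10, 2)), ["a", "b"] * 5, n_bands=2)
        out = zscore(held, stats=(fitted.mean, fitted.std))
        np.testing.assert_allclose(out.values, (held.values - fitted.mean) / fitted.std)


class TestSplit:
    def _table(self, trials_per_class=10, segs=3):
        labels, trial_ids = [], []
        t = 0
        for cls in ("joy", "fear", "sadness", "relaxation"):
            for _ in range(trials_per_class):
                labels += [cls] * segs
                trial_ids += [t] * segs
                t += 1
        n = len(labels)
        return make_table(
            np.arange(n * 4, dtype=float).reshape(n, 4),
            labels,
            trial_of_sample=trial_ids,
        )

    def test_even_classes_split_in_half_by_trial(self):
        sel, val = split_dataset(self._table(), seed=5)
        for part in (sel, val):
            counts = {
                cls: len(np.unique(part.trial_of_sample[part.labels == cls]))
                for cls in np.unique(part.labels)
            }
            assert all(v == 5 for v in counts.values())

    def test_no_trial_appears_on_both_sides(self):
        sel, val = split_dataset(self._table(), seed=5)
        assert not set(sel.trial_of_sample) & set(val.trial_of_sample)
        # all segments of a trial travel together
        assert len(sel.trial_of_sample) + len(val.trial_of_sample) == 120

    def test_same_seed_reproduces_split(self):
        a_sel, _ = split_dataset(self._table(), seed=5)
        b_sel, _ = split_dataset(self._table(), seed=5)
        assert np.array_equal(a_sel.trial_of_sample, b_sel.trial_of_sample)
        c_sel, _ = split_dataset(self._table(), seed=6)
        assert not np.array_equal(a_sel.trial_of_sample, c_sel.trial_of_sample)

    def test_class_with_single_trial_is_named_in_error(self):
        table = self._table(trials_per_class=1)
        with pytest.raises(ValueError, match="fear"):
            split_dataset(table, seed=0)

    def test_subject_filter_requires_five_trials_per_class(self):
        from eegselect.features import subject_passes_filter

        assert subject_passes_filter(self._table(trials_per_class=5))
        assert not subject_passes_filter(self._table(trials_per_class=4))
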