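"""ReliefF and F-score against literal-formula oracles and their invariants."""

import numpy as np
import pytest

from eegselect.weighting import FeatureWeights, ReliefFConfig, diff, fscore, relieff
from conftest import gaussian_table, make_table
from _oracles import fscore_oracle, relieff_oracle


class TestDiff:
    def test_direct_formula(self):
        r1, r2 = np.array([0.3]), np.array([0.7])
        rng = (np.array([0.0]), np.array([1.0]))
        assert diff(0, r1, r2, rng) == pytest.approx(0.4)

    def test_identical_samples_give_zero(self):
        r = np.array([0.42])
        assert diff(0, r, r, (np.array([0.0]), np.array([1.0]))) == 0.0

    def test_extremes_give_one(self):
        rng = (np.array([-2.0]), np.array([3.0]))
        assert diff(0, np.array([-2.0]), np.array([3.0]), rng) == 1.0

    def test_constant_feature_defined_as_zero(self):
        rng = (np.array([1.0]), np.array([1.0]))
        assert diff(0, np.array([1.0]), np.array([1.0]), rng) == 0.0


class TestReliefF:
    def test_constant_feature_weight_exactly_zero(self, rng):
        X = rng.standard_normal((24, 4))
        X[:, 2] = 7.0
        table = make_table(X, ["a", "b"] * 12, n_bands=2)
        fw = relieff(table, ReliefFConfig(k=2))
        assert fw.weights[2] == 0.0

    def test_toy_instance_matches_hand_oracle(self):
        """Six samples, two classes, two features, k=1: exhaustive literal
        application of the update and diff formulas."""
        X = np.array(
            [[0.0, 0.1], [0.1, 0.0], [0.9, 1.0], [1.0, 0.9], [0.5, 0.4], [0.4, 0.6]]
        )
        y = np.array(["a", "a", "b", "b", "a", "b"])
        fw = relieff(make_table(X, y, n_bands=2), ReliefFConfig(k=1))
        np.testing.assert_allclose(fw.weights, relieff_oracle(X, y, k=1), atol=1e-14)

    @pytest.mark.parametrize(
        "n_per_class,n_features,k,classes",
        [
            (10, 4, 3, ("a", "b")),
            (15, 8, 5, ("a", "b", "c")),
            (12, 12, 10, ("joy", "fear", "sadness", "relaxation")),
        ],
    )
    def test_matches_brute_force_oracle(self, rng, n_per_class, n_features, k, classes):
        table = gaussian_table(
            n_per_class, n_features, rng, class_shift={0: 0.8}, classes=classes
        )
        fw = relieff(table, ReliefFConfig(k=k))
        oracle = relieff_oracle(table.values, table.labels, k=k)
        np.testing.assert_allclose(fw.weights, oracle, atol=1e-12)

    def test_weights_bounded_in_unit_interval(self, rng):
        table = gaussian_table(12, 12, rng, class_shift={0: 2.0, 3: 1.0})
        fw = relieff(table, ReliefFConfig(k=5))
        assert np.all(fw.weights >= -1.0) and np.all(fw.weights <= 1.0)

    def test_invariant_to_sample_order(self, rng):
        table = gaussian_table(10, 6, rng, class_shift={1: 1.0}, classes=("a", "b"), n_bands=2)
        perm = rng.permutation(table.n_samples)
        shuffled = make_table(table.values[perm], table.labels[perm], n_bands=2)
        a = relieff(table, ReliefFConfig(k=3)).weights
        b = relieff(shuffled, ReliefFConfig(k=3)).weights
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_planted_feature_ranked_first(self, rng):
        table = gaussian_table(50, 20, rng, class_shift={7: 1.5})
        fw = relieff(table, ReliefFConfig(k=10))
        assert fw.ranking[0] == 7

    def test_small_class_named_in_error(self, rng):
        X = rng.standard_normal((12, 4))
        y = np.array(["a"] * 9 + ["tiny"] * 3)
        with pytest.raises(ValueError, match="tiny"):
            relieff(make_table(X, y, n_bands=2), ReliefFConfig(k=3))

    def test_nan_feature_rejected(self, rng):
        X = rng.standard_normal((20, 4))
        X[3, 1] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            relieff(make_table(X, ["a", "b"] * 10, n_bands=2), ReliefFConfig(k=2))

    def test_priors_estimated_from_scoring_set(self, rng):
        X = rng.standard_normal((30, 2))
        y = np.array(["a"] * 20 + ["b"] * 10)
        fw = relieff(make_table(X, y, n_bands=2), ReliefFConfig(k=4))
        assert fw.class_priors == {"a": 2 / 3, "b": 1 / 3}
        assert sorted(fw.ranking.tolist()) == [0, 1]


class TestFscore:
    def test_constant_feature_is_zero(self):
        X = np.column_stack([np.full(8, 3.0), np.arange(8.0)])
        fw = fscore(make_table(X, ["a", "b"] * 4, n_bands=2))
        assert fw.weights[0] == 0.0

    def test_matches_literal_formula(self, rng):
        table = gaussian_table(9, 6, rng, class_shift={2: 1.0}, classes=("a", "b", "c"), n_bands=2)
        np.testing.assert_allclose(
            fscore(table).weights, fscore_oracle(table.values, table.labels), rtol=1e-12
        )

    def test_separated_classes_give_large_f(self):
        eps = 1e-3
        X = np.array([[0.0], [eps], [1.0], [1.0 + eps]])
        fw = fscore(make_table(X, ["a", "a", "b", "b"], n_bands=1))
        assert fw.weights[0] == pytest.approx(
            fscore_oracle(X, np.array(["a", "a", "b", "b"]))[0]
        )
        assert fw.weights[0] > 1e5

    def test_duplicating_samples_leaves_f_unchanged(self, rng):
        table = gaussian_table(8, 4, rng, class_shift={1: 1.0}, classes=("a", "b"))
        doubled = make_table(
            np.vstack([table.values, table.values]),
            np.concatenate([table.labels, table.labels]),
            n_bands=4,
        )
        np.testing.assert_allclose(
            fscore(table).weights, fscore(doubled).weights, rtol=1e-12
        )

    def test_zero_within_scatter_flagged_infinite_and_ranked_first(self):
        X = np.column_stack([np.array([0.0, 0.0, 1.0, 1.0]), np.arange(4.0)])
        with pytest.warns(RuntimeWarning, match="zero within-class"):
            fw = fscore(make_table(X, ["a", "a", "b", "b"], n_bands=2))
        assert np.isinf(fw.weights[0]) and fw.ranking[0] == 0

    def test_label_permutation_destroys_signal_on_average(self, rng):
        table = gaussian_table(20, 1, rng, class_shift={0: 2.0}, classes=("a", "b"), n_bands=1)
        original = fscore(table).weights[0]
        permuted = []
        for _ in range(30):
            y = rng.permutation(table.labels)
            permuted.append(fscore(make_table(table.values, y, n_bands=1)).weights[0])
        assert np.mean(permuted) < original / 10


def test_ranking_is_descending_permutation(rng):
    table = gaussian_table(10, 8, rng, class_shift={3: 1.0})
    for fw in (relieff(table, ReliefFConfig(k=3)), fscore(table)):
        assert isinstance(fw, FeatureWeights)
        assert sorted(fw.ranking.tolist()) == list(range(8))
        w = fw.weights[fw.ranking]
        assert np.all(w[:-1] >= w[1:])
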