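"""Tests for ReliefF weighting, chi-square ranking and the RFIChi2 sweep."""

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from ledpatnet.selection import (
    SelectionResult,
    chi2_scores,
    relieff_weights,
    rfichi2_select,
)


def small_problem(rng, n=60, n_noise=20):
    """Binary problem: feature 0 equals the label, the rest pure noise."""
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, n_noise + 1))
    X[:, 0] = y
    return X, y


class TestReliefF:
    def test_label_copy_feature_has_maximal_positive_weight(self, rng):
        X, y = small_problem(rng)
        w = relieff_weights((X, y), k_neighbors=5)
        assert w[0] > 0
        assert w[0] == max(w)

    def test_noise_weights_near_zero_with_both_signs(self, rng):
        n = 500
        y = np.repeat([0, 1], n // 2)
        X = rng.normal(size=(n, 12))
        w = relieff_weights((X, y), k_neighbors=10)
        assert np.max(np.abs(w)) < 0.05
        assert (w < 0).any() and (w > 0).any()

    def test_duplicated_columns_get_identical_weights(self, rng):
        X, y = small_problem(rng, n=40, n_noise=5)
        Xdup = np.hstack([X, X[:, [2]]])
        w = relieff_weights((Xdup, y), k_neighbors=5)
        assert w[2] == pytest.approx(w[-1], abs=1e-12)

    def test_constant_feature_weight_zero(self, rng):
        X, y = small_problem(rng, n=40, n_noise=3)
        X[:, 1] = 7.0
        w = relieff_weights((X, y), k_neighbors=5)
        assert w[1] == 0.0

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            relieff_weights((rng.normal(size=(20, 3)), np.zeros(20)))


class TestChi2Scores:
    def test_label_indicator_scores_highest(self, rng):
        X, y = small_problem(rng, n=100)
        s = chi2_scores((X, y))
        assert np.argmax(s) == 0

    def test_constant_feature_scores_zero(self, rng):
        X, y = small_problem(rng, n=40)
        X[:, 3] = -2.0
        assert chi2_scores((X, y))[3] == 0.0

    def test_observation_permutation_invariance(self, rng):
        X, y = small_problem(rng, n=80)
        perm = rng.permutation(80)
        np.testing.assert_allclose(chi2_scores((X, y)), chi2_scores((X[perm], y[perm])))

    def test_matches_contingency_table_oracle(self, rng):
        """Binned statistic equals scipy's chi-square on the same table."""
        X, y = small_problem(rng, n=120, n_noise=6)
        n_bins = 10
        scores = chi2_scores((X, y), n_bins=n_bins)
        for j in range(X.shape[1]):
            col = X[:, j]
            edges = np.linspace(col.min(), col.max(), n_bins + 1)
            binned = np.clip(np.digitize(col, edges[1:-1]), 0, n_bins - 1)
            table = np.zeros((n_bins, 2))
            for b, c in zip(binned, y):
                table[b, c] += 1
            table = table[table.sum(axis=1) > 0]
            expected = chi2_contingency(table, correction=False).statistic
            assert scores[j] == pytest.approx(expected, rel=1e-9)

    def test_null_scores_near_degrees_of_freedom(self, rng):
        # under independence the statistic's mean is its degrees of freedom
        n, reps = 400, 40
        y = np.repeat([0, 1], n // 2)
        stats = [
            chi2_scores((rng.uniform(size=(n, 1)), y), n_bins=10)[0] for _ in range(reps)
        ]
        dof = (10 - 1) * (2 - 1)
        assert abs(np.mean(stats) - dof) < 3.0


@pytest.fixture(scope="module")
def planted():
    """30 informative features among 300 noise ones, two classes."""
    rng = np.random.default_rng(77)
    n, n_inf, n_noise = 120, 30, 300
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(size=(n, n_inf + n_noise))
    shift = rng.choice([-1.0, 1.0], size=n_inf)
    X[:, :n_inf] += np.where(y[:, None] == 1, shift, -shift)
    return X, y


@pytest.fixture(scope="module")
def result(planted):
    X, y = planted
    return rfichi2_select((X, y), size_range=(40, 120), folds=5, seed=11)


class TestRFIChi2:
    def test_pruning_soundness(self, result):
        assert (result.relieff_weights[result.selected] >= 0).all()
        assert (result.relieff_weights[result.kept_after_relieff] >= 0).all()
        assert np.isin(result.selected, result.kept_after_relieff).all()

    def test_selected_is_ranked_prefix(self, result):
        assert result.selected.size == result.chosen_size
        np.testing.assert_array_equal(
            result.selected, result.chi2_order[: result.chosen_size]
        )

    def test_chosen_size_minimizes_loss_with_parsimony_tie_break(self, result):
        best = min(result.loss_curve.values())
        assert result.loss_curve[result.chosen_size] == best
        smaller_ties = [
            s
            for s, l in result.loss_curve.items()
            if l == best and s < result.chosen_size
        ]
        assert not smaller_ties

    def test_planted_features_recovered(self, planted, result):
        X, y = planted
        recovery = np.isin(np.arange(30), result.selected).mean()
        assert recovery >= 0.8

    def test_reproducible_under_same_seed(self, planted, result):
        X, y = planted
        again = rfichi2_select((X, y), size_range=(40, 120), folds=5, seed=11)
        assert again.chosen_size == result.chosen_size
        np.testing.assert_array_equal(again.selected, result.selected)
        assert again.loss_curve == result.loss_curve

    def test_loss_curve_consistent_with_direct_reevaluation(self, planted, result):
        """Re-scoring the returned subset with the same partition and seed
        reproduces the sweep's recorded loss."""
        from ledpatnet.classify import cross_val_predictions

        X, y = planted
        pred, _ = cross_val_predictions(
            X[:, result.selected], y, folds=5, seed=result.seed
        )
        assert np.mean(pred != y) == pytest.approx(
            result.loss_curve[result.chosen_size], abs=1e-12
        )

    def test_candidate_count_matches_range(self, result):
        assert len(result.loss_curve) == 120 - 40 + 1
        assert min(result.loss_curve) == 40 and max(result.loss_curve) == 120

    def test_range_clipped_to_survivors_with_warning(self, rng, caplog):
        X, y = small_problem(rng, n=40, n_noise=10)
        with caplog.at_level("WARNING"):
            res = rfichi2_select((X, y), size_range=(2, 500), folds=4, seed=3)
        assert "clipped" in caplog.text
        assert max(res.loss_curve) == res.kept_after_relieff.size

    def test_nested_prefix_containment(self, result):
        # top-s sets are nested by construction of the ranked order
        order = result.chi2_order
        assert set(order[:50]) < set(order[:80])

    def test_serialization_round_trip(self, result, tmp_path):
        path = str(tmp_path / "selection.json")
        result.save(path)
        back = SelectionResult.load(path)
        assert back.chosen_size == result.chosen_size
        np.testing.assert_array_equal(back.selected, result.selected)
        assert back.loss_curve == result.loss_curve
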