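import numpy as np
import pytest

from motorimagery import (
    FeatureMatrix,
    GridSpec,
    SVMConfig,
    evaluate,
    grid_search,
    rbf_kernel,
    train_svm,
)


def _clouds(rng, n=40, sep=8.0, d=2):
    X = np.vstack([rng.standard_normal((n, d)) - sep / 2,
                   rng.standard_normal((n, d)) + sep / 2])
    y = np.repeat([0, 1], n)
    return FeatureMatrix(X, [f"f{i}" for i in range(d)], y)


class TestRBFKernel:
    def test_zero_distance_gives_one(self):
        u = np.array([0.3, -1.2, 7.0])
        assert rbf_kernel(u, u, gamma=0.7) == 1.0

    def test_hand_computed_value(self):
        assert rbf_kernel((0.0, 0.0), (1.0, 1.0), gamma=0.5) == pytest.approx(
            np.exp(-1.0), abs=1e-12
        )

    def test_vanishing_gamma_limit_is_one(self):
        assert rbf_kernel((0.0, 0.0), (5.0, 5.0), gamma=1e-12) == pytest.approx(1.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            rbf_kernel(np.zeros(2), np.zeros(3), gamma=1.0)


class TestTrainSVM:
    def test_symmetric_pair_has_boundary_at_zero(self):
        F = FeatureMatrix(np.array([[-1.0], [1.0]]), ["x"], np.array([0, 1]))
        model = train_svm(F, SVMConfig(c=1e6, gamma=1.0))
        assert abs(model.decision_function(np.array([[0.0]]))[0]) < 1e-6
        np.testing.assert_array_equal(model.predict(F.values), [0, 1])

    def test_separable_clouds_fit_perfectly(self, rng):
        F = _clouds(rng)
        model = train_svm(F, SVMConfig(c=10, gamma=1.0))
        assert np.mean(model.predict(F.values) == F.labels) == 1.0

    def test_kkt_margin_on_non_support_points(self, rng):
        F = _clouds(rng, n=50)
        model = train_svm(F, SVMConfig(c=10, gamma=1.0))
        scaled_all = np.arange(F.n_segments)
        non_sv = np.setdiff1d(scaled_all, model.svc.support_)
        assert len(non_sv) > 0
        sign = np.where(F.labels[non_sv] == model.classes[1], 1.0, -1.0)
        margin = sign * model.decision_function(F.values[non_sv])
        assert np.all(margin >= 1 - 1e-6)

    def test_duplicated_training_set_gives_identical_decisions(self, rng):
        F = _clouds(rng)
        F2 = FeatureMatrix(
            np.vstack([F.values, F.values]),
            F.feature_names,
            np.concatenate([F.labels, F.labels]),
        )
        probe = rng.standard_normal((50, 2)) * 3
        d1 = train_svm(F, SVMConfig(c=5, gamma=0.5)).decision_function(probe)
        d2 = train_svm(F2, SVMConfig(c=5, gamma=0.5)).decision_function(probe)
        np.testing.assert_allclose(d1, d2, atol=1e-6)

    def test_increasing_c_never_hurts_training_accuracy(self, rng):
        F = _clouds(rng, n=30)  # separable
        accs = []
        for c in (0.01, 0.1, 1.0, 10.0, 100.0):
            model = train_svm(F, SVMConfig(c=c, gamma=1.0))
            accs.append(np.mean(model.predict(F.values) == F.labels))
        assert all(b >= a - 1e-12 for a, b in zip(accs, accs[1:]))

    def test_single_class_and_nonfinite_rejected(self, rng):
        F = FeatureMatrix(rng.standard_normal((10, 2)), ["a", "b"], np.zeros(10, int))
        with pytest.raises(ValueError, match="single class"):
            train_svm(F)
        F2 = _clouds(rng, n=5)
        F2.values[0, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            train_svm(F2)


class TestGridSearch:
    def test_single_cell_grid_returns_that_cell(self, rng):
        F = _clouds(rng, n=25)
        grid = GridSpec(c_values=(7.0,), gamma_values=(0.4,), folds=5, seed=1)
        rep = grid_search(F, grid)
        assert rep.best_config == SVMConfig(c=7.0, gamma=0.4)
        assert rep.mean_accuracy == pytest.approx(rep.grid_accuracies[0, 0])
        assert len(rep.fold_accuracies) == 5

    def test_separable_features_exceed_95_percent(self, rng):
        F = _clouds(rng, n=30)
        rep = grid_search(F, GridSpec(c_values=(1, 10), gamma_values=(0.5, 1.0),
                                      folds=5, seed=0))
        assert rep.grid_accuracies.max() >= 95.0

    def test_tie_breaks_toward_smallest_c_then_gamma(self, rng):
        F = _clouds(rng, n=25, sep=10.0)  # trivially separable: all cells tie at 100
        rep = grid_search(F, GridSpec(c_values=(1, 10), gamma_values=(0.5, 1.0),
                                      folds=5, seed=0))
        assert np.all(rep.grid_accuracies == 100.0)
        assert rep.best_config == SVMConfig(c=1, gamma=0.5)

    def test_bit_for_bit_reproducible_under_fixed_seed(self, rng):
        F = _clouds(rng, n=20, sep=1.5)
        grid = GridSpec(c_values=(1, 10), gamma_values=(0.3, 1.0), folds=4, seed=9)
        r1 = grid_search(F, grid)
        r2 = grid_search(F, grid)
        np.testing.assert_array_equal(r1.grid_accuracies, r2.grid_accuracies)
        np.testing.assert_array_equal(r1.fold_accuracies, r2.fold_accuracies)
        np.testing.assert_array_equal(r1.cumulative_errors, r2.cumulative_errors)
        assert r1.best_config == r2.best_config

    def test_shuffled_labels_stay_near_chance(self):
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((200, 6))
            y = rng.integers(0, 2, 200)
            F = FeatureMatrix(X, [f"f{i}" for i in range(6)], y)
            rep = grid_search(F, GridSpec(c_values=(1, 10), gamma_values=(0.5, 2.0),
                                          folds=5, seed=seed))
            accs.append(rep.grid_accuracies.max())  # selection-bias-inflated
        assert abs(np.mean(accs) - 50) < 10

    def test_optimal_config_beats_grid_minimum(self, rng):
        F = _clouds(rng, n=30, sep=3.0)
        # gamma 1e-3 makes the kernel matrix nearly constant -> near-chance cell
        rep = grid_search(F, GridSpec(c_values=(1.0,), gamma_values=(0.001, 1.0),
                                      folds=5, seed=0))
        assert rep.mean_accuracy > rep.grid_accuracies.min()

    def test_confusion_counts_sum_to_evaluated_segments(self, rng):
        F = _clouds(rng, n=20, sep=1.0)
        rep = grid_search(F, GridSpec(c_values=(1,), gamma_values=(1.0,), folds=4,
                                      seed=0))
        assert rep.confusion.sum() == F.n_segments
        assert rep.cumulative_errors[-1] == rep.confusion.sum() - np.trace(rep.confusion)

    def test_too_few_trials_per_class_rejected(self, rng):
        F = _clouds(rng, n=4)
        with pytest.raises(ValueError, match="fewer than"):
            grid_search(F, GridSpec(c_values=(1,), gamma_values=(1.0,), folds=5))

    def test_grid_spec_rejects_nonpositive_values(self):
        with pytest.raises(ValueError):
            GridSpec(c_values=(0.0, 1.0))
        with pytest.raises(ValueError):
            GridSpec(gamma_values=(-0.1,))


class TestEvaluate:
    def test_resubstitution_on_separable_data_is_perfect(self, rng):
        F = _clouds(rng)
        acc, confusion = evaluate(F, F, SVMConfig(c=10, gamma=1.0))
        assert acc == 100.0
        assert np.trace(confusion) == F.n_segments

    def test_accuracy_plus_error_rate_is_exactly_100(self, rng):
        F_tr = _clouds(rng, n=30, sep=1.0)
        F_te = _clouds(rng, n=20, sep=1.0)
        acc, confusion = evaluate(F_tr, F_te)
        errors = confusion.sum() - np.trace(confusion)
        assert acc + 100.0 * errors / confusion.sum() == pytest.approx(100.0)

    def test_trial_leakage_rejected(self, rng):
        F = _clouds(rng, n=10)
        F_tr = FeatureMatrix(F.values, F.feature_names, F.labels,
                             trial_ids=np.arange(20))
        F_te = FeatureMatrix(F.values[:4], F.feature_names, F.labels[:4],
                             trial_ids=np.array([0, 1, 2, 3]))
        with pytest.raises(ValueError, match="leakage"):
            evaluate(F_tr, F_te)
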