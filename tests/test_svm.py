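import numpy as np
import pytest

from eegdecode import (FeatureMatrix, HyperGrid, HyperParams, decision_function,
                       fit, predict, prepare_features, rbf_kernel)
from eegdecode.svm import GRID_PRESETS, KernelModel, _canonical_order


def toy_matrix(X, y, groups=None):
    X = np.asarray(X, dtype=float)
    return FeatureMatrix(
        rows=X, labels=np.asarray(y),
        groups=np.asarray(groups if groups is not None
                          else ["g0"] * X.shape[0]),
        n_channels=1, n_times=X.shape[1],
        channel_names=["c0"], times_ms=np.arange(X.shape[1], dtype=float),
    )


class TestRBFKernel:
    def test_zero_distance_is_one(self):
        a = np.array([1.0, -2.0, 3.0])
        assert rbf_kernel(a, a, gamma=0.7) == pytest.approx(1.0)

    def test_hand_value(self):
        # ||a-b||^2 = 4, gamma = 0.25 -> e^{-1}
        a, b = np.array([0.0, 0.0]), np.array([2.0, 0.0])
        assert rbf_kernel(a, b, 0.25) == pytest.approx(np.exp(-1), abs=1e-9)
        assert rbf_kernel(a, b, 0.25) == pytest.approx(0.367879, abs=1e-6)

    def test_small_gamma_limit(self):
        a, b = np.array([0.0, 0.0]), np.array([5.0, 5.0])
        assert rbf_kernel(a, b, 1e-12) == pytest.approx(1.0, abs=1e-9)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            rbf_kernel(np.zeros(3), np.zeros(4), 1.0)

    def test_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.normal(size=(2, 6))
            v = rbf_kernel(a, b, rng.uniform(0.01, 5))
            assert 0.0 < v <= 1.0


class TestGrid:
    def test_presets_are_10_by_10_with_printed_endpoints(self):
        for name, (c_lo, c_hi, g_lo, g_hi) in GRID_PRESETS.items():
            grid = HyperGrid.preset(name)
            assert grid.n_combinations == 100
            assert grid.c_values[0] == pytest.approx(c_lo)
            assert grid.c_values[-1] == pytest.approx(c_hi)
            assert grid.gamma_values[0] == pytest.approx(g_lo)
            assert grid.gamma_values[-1] == pytest.approx(g_hi)

    def test_log_spacing(self):
        grid = HyperGrid.preset("single_trial")
        ratios = grid.gamma_values[1:] / grid.gamma_values[:-1]
        assert np.allclose(ratios, ratios[0])

    def test_invalid_params_raise(self):
        with pytest.raises(ValueError):
            HyperParams(c=-1.0, gamma=1.0)
        with pytest.raises(ValueError):
            HyperGrid(np.array([1.0]), np.array([0.0]))

    def test_snap_to_nearest(self):
        grid = HyperGrid.preset("pseudotrial")
        hp = grid.snap(7.2, 3.7e-4)
        assert hp.c in grid.c_values and hp.gamma in grid.gamma_values


class TestFitContract:
    def test_alpha_vector_full_length_with_zeros_retained(self, pseudo_features,
                                                          pseudo_model):
        assert pseudo_model.alphas.shape == (pseudo_features.n_rows,)
        assert pseudo_model.n_support == np.count_nonzero(pseudo_model.alphas)

    def test_alpha_bound_and_sign(self, pseudo_model):
        assert np.all(np.abs(pseudo_model.alphas) <= pseudo_model.c + 1e-9)
        nz = pseudo_model.alphas != 0
        assert np.all(np.sign(pseudo_model.alphas[nz])
                      == pseudo_model.training_labels[nz])

    def test_separable_toy_problem(self):
        fm = toy_matrix([[0.0, 0.0], [4.0, 4.0]], [-1, 1])
        m = fit(fm, HyperParams(10.0, 0.5))
        assert predict(m, np.array([0.0, 0.0])) == -1
        assert predict(m, np.array([4.0, 4.0])) == 1

    def test_single_class_raises(self):
        fm = toy_matrix([[0.0], [1.0]], [1, 1])
        with pytest.raises(ValueError):
            fit(fm, HyperParams(1.0, 1.0))

    def test_row_permutation_invariance(self, small_dataset, tiny_grid):
        fm = prepare_features(small_dataset, "pseudotrial")
        rng = np.random.default_rng(3)
        perm = rng.permutation(fm.n_rows)
        shuffled = FeatureMatrix(fm.rows[perm], fm.labels[perm], fm.groups[perm],
                                 fm.n_channels, fm.n_times, fm.channel_names,
                                 fm.times_ms, fm.trial_index[perm])
        hp = HyperParams(2.0, 3e-4)
        a, b = fit(fm, hp), fit(shuffled, hp)
        np.testing.assert_array_equal(a.alphas, b.alphas)
        assert a.bias == b.bias

    def test_canonical_order_sorts_by_subject_then_trial(self):
        fm = toy_matrix(np.arange(8, dtype=float).reshape(4, 2), [1, -1, 1, -1],
                        groups=["s2", "s1", "s2", "s1"])
        fm.trial_index = np.array([1, 0, 0, 1])
        order = _canonical_order(fm)
        assert list(fm.groups[order]) == ["s1", "s1", "s2", "s2"]
        assert list(fm.trial_index[order]) == [0, 1, 0, 1]


class TestDecisionFunction:
    def test_single_support_vector_at_origin(self):
        m = KernelModel(alphas=np.array([1.0]), bias=0.0, gamma=0.3, c=1.0,
                        training_rows=np.zeros((1, 2)),
                        training_labels=np.array([1]))
        assert decision_function(m, np.zeros(2)) == pytest.approx(1.0)

    def test_linear_in_bias(self, pseudo_model, pseudo_features):
        import dataclasses
        x = pseudo_features.rows[0]
        shifted = dataclasses.replace(pseudo_model, bias=pseudo_model.bias + 0.25)
        assert decision_function(shifted, x) == pytest.approx(
            decision_function(pseudo_model, x) + 0.25)

    def test_brute_force_sum_oracle(self, pseudo_model, pseudo_features):
        x = pseudo_features.rows[17]
        brute = pseudo_model.bias
        for alpha, xn in zip(pseudo_model.alphas, pseudo_model.training_rows):
            brute += alpha * rbf_kernel(xn, x, pseudo_model.gamma)
        assert decision_function(pseudo_model, x) == pytest.approx(brute, abs=1e-10)

    def test_matches_sklearn_decision_function(self, pseudo_features):
        """Independent cross-check of the dual-form summation against libsvm."""
        from sklearn.svm import SVC
        hp = HyperParams(2.0, 3e-4)
        m = fit(pseudo_features, hp)
        svc = SVC(C=hp.c, gamma=hp.gamma, kernel="rbf")
        svc.fit(m.training_rows, m.training_labels)
        ours = decision_function(m, pseudo_features.rows[:10])
        theirs = svc.decision_function(pseudo_features.rows[:10])
        np.testing.assert_allclose(ours, theirs, atol=1e-6)

    def test_length_mismatch_raises(self, pseudo_model):
        with pytest.raises(ValueError):
            decision_function(pseudo_model, np.zeros(3))

    def test_margin_consistency_on_training_points(self, pseudo_model):
        dec = decision_function(pseudo_model, pseudo_model.training_rows)
        confident = np.abs(dec) > 1
        pred = np.where(dec > 0, 1, -1)
        assert np.all(pred[confident] == pseudo_model.training_labels[confident])

    def test_tie_goes_to_inanimate(self):
        m = KernelModel(alphas=np.array([0.0]), bias=0.0, gamma=1.0, c=1.0,
                        training_rows=np.zeros((1, 2)),
                        training_labels=np.array([1]))
        assert predict(m, np.ones(2)) == -1
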