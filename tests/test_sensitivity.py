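import dataclasses

import numpy as np
import pytest

from eegdecode import decision_function, kernel_gradient, sensitivity_map
from eegdecode.sensitivity import ScalpTimeMap
from eegdecode.svm import KernelModel

from test_svm import toy_matrix


def random_model(rng, n=6, d=4):
    X = rng.normal(size=(n, d))
    y = rng.choice([-1, 1], size=n)
    while np.unique(y).size < 2:
        y = rng.choice([-1, 1], size=n)
    alphas = y * rng.uniform(0.0, 1.5, size=n)
    return KernelModel(alphas=alphas, bias=rng.normal(), c=1.5,
                       gamma=rng.uniform(0.05, 1.0),
                       training_rows=X, training_labels=y)


class TestKernelGradient:
    def test_gradient_vanishes_at_single_support_vector(self):
        m = KernelModel(alphas=np.array([2.0]), bias=0.1, gamma=0.7, c=3.0,
                        training_rows=np.array([[1.0, -1.0, 2.0]]),
                        training_labels=np.array([1]))
        np.testing.assert_allclose(
            kernel_gradient(m, np.array([1.0, -1.0, 2.0])), 0.0, atol=1e-15)

    def test_hand_value(self):
        # alpha=1, SV=(1,0), gamma=0.5, x=(0,0):
        # dfdx = 2*0.5*(1-0)*exp(-0.5) = exp(-0.5) on feature 0, 0 on feature 1
        m = KernelModel(alphas=np.array([1.0]), bias=0.0, gamma=0.5, c=1.0,
                        training_rows=np.array([[1.0, 0.0]]),
                        training_labels=np.array([1]))
        g = kernel_gradient(m, np.zeros(2))
        np.testing.assert_allclose(g, [np.exp(-0.5), 0.0], atol=1e-12)
        assert g[0] == pytest.approx(0.606531, abs=1e-6)

    def test_matches_finite_differences_on_100_random_models(self):
        """Analytic gradient vs central differences of the decision function."""
        rng = np.random.default_rng(42)
        step = 1e-5
        worst = 0.0
        for _ in range(100):
            m = random_model(rng)
            x = rng.normal(size=m.training_rows.shape[1])
            g = kernel_gradient(m, x)
            fd = np.empty_like(g)
            for j in range(x.size):
                e = np.zeros_like(x)
                e[j] = step
                fd[j] = (decision_function(m, x + e)
                         - decision_function(m, x - e)) / (2 * step)
            denom = max(np.linalg.norm(fd), 1e-12)
            worst = max(worst, np.linalg.norm(g - fd) / denom)
        assert worst < 1e-6

    def test_length_mismatch_raises(self):
        rng = np.random.default_rng(0)
        m = random_model(rng)
        with pytest.raises(ValueError):
            kernel_gradient(m, np.zeros(m.training_rows.shape[1] + 1))


class TestSensitivityMap:
    def test_mean_square_nonnegative(self, pseudo_model, pseudo_features):
        smap = sensitivity_map(pseudo_model, pseudo_features)
        assert smap.map_kind == "sensitivity"
        assert np.all(smap.values >= 0)
        assert smap.shape == (32, 60)

    def test_symmetric_two_point_problem_gives_symmetric_map(self):
        from eegdecode import fit, HyperParams
        fm = toy_matrix([[1.0, -1.0], [-1.0, 1.0]], [1, -1])
        m = fit(fm, HyperParams(5.0, 0.3))
        smap = sensitivity_map(m, fm)
        assert smap.values[0, 0] == pytest.approx(smap.values[0, 1], rel=1e-9)

    def test_brute_force_double_loop_oracle(self, pseudo_model, pseudo_features):
        sub = dataclasses.replace(
            pseudo_features,
            rows=pseudo_features.rows[:5],
            labels=pseudo_features.labels[:5],
            groups=pseudo_features.groups[:5],
            trial_index=pseudo_features.trial_index[:5])
        fast = sensitivity_map(pseudo_model, sub).values.ravel()
        grads = np.array([kernel_gradient(pseudo_model, x) for x in sub.rows])
        slow = np.mean(grads ** 2, axis=0)
        np.testing.assert_allclose(fast, slow, atol=1e-10)

    def test_scale_equivariance_in_alpha(self, pseudo_model, pseudo_features):
        scaled = dataclasses.replace(pseudo_model,
                                     alphas=3.0 * pseudo_model.alphas)
        base_sq = sensitivity_map(pseudo_model, pseudo_features).values
        base_sg = sensitivity_map(pseudo_model, pseudo_features,
                                  "mean_signed").values
        np.testing.assert_allclose(
            sensitivity_map(scaled, pseudo_features).values, 9.0 * base_sq,
            rtol=1e-9)
        np.testing.assert_allclose(
            sensitivity_map(scaled, pseudo_features, "mean_signed").values,
            3.0 * base_sg, rtol=1e-9, atol=1e-15)

    def test_empty_eval_points_raises(self, pseudo_model, pseudo_features):
        empty = dataclasses.replace(
            pseudo_features, rows=pseudo_features.rows[:0],
            labels=pseudo_features.labels[:0], groups=pseudo_features.groups[:0],
            trial_index=pseudo_features.trial_index[:0])
        with pytest.raises(ValueError):
            sensitivity_map(pseudo_model, empty)


class TestScalpTimeMap:
    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            ScalpTimeMap(np.zeros((2, 3)), ["a"], np.arange(3.0), "sensitivity")
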