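"""Kernel-derivative sensitivity maps for trained RBF-SVM classifiers.

A trained kernel classifier is a black box over 1920-dimensional
(channel x time) feature vectors.  The sensitivity map opens it by
differentiating the discriminant analytically: for the RBF kernel,

    d f(x) / d x_j = sum_n alpha_n * 2 gamma (x_{n,j} - x_j) exp(-gamma ||x_n - x||^2)

(the bias contributes nothing).  Aggregating the gradient over a set of
evaluation points — by default the model's own training observations — and
reshaping to channels x time yields a map of where in the scalp/time grid
the classifier's decision is sensitive to the input.  The default
aggregation is the mean squared derivative (the probabilistic
sensitivity-map convention), which is nonnegative; the signed mean is
exposed for inspection of effect direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics.pairwise import euclidean_distances

from .core_data import FeatureMatrix
from .svm import KernelModel

__all__ = ["ScalpTimeMap", "kernel_gradient", "sensitivity_map"]


@dataclass
class ScalpTimeMap:
    """A channels x time matrix with axis metadata.

    ``map_kind`` is one of ``sensitivity``, ``erp_difference``,
    ``effect_size``, ``t_statistic``.
    """

    values: np.ndarray
    channel_names: list[str]
    times_ms: np.ndarray
    map_kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.values.shape != (len(self.channel_names), self.times_ms.size):
            raise ValueError(
                f"map shape {self.values.shape} does not match "
                f"{len(self.channel_names)} channels x {self.times_ms.size} samples")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def kernel_gradient(m: KernelModel, x: np.ndarray) -> np.ndarray:
    """Analytic gradient of the decision function at ``x``.

    Exact derivative of ``decision_function``; the bias term vanishes.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size != m.training_rows.shape[1]:
        raise ValueError(
            f"x must be a vector of length {m.training_rows.shape[1]}")
    diff = m.training_rows - x                      # (n, d)
    k = np.exp(-m.gamma * np.einsum("nd,nd->n", diff, diff))
    return 2.0 * m.gamma * ((m.alphas * k) @ diff)


def _gradients(m: KernelModel, X: np.ndarray) -> np.ndarray:
    """Gradients at every row of X, shape (n_points, n_features)."""
    sq = euclidean_distances(X, m.training_rows, squared=True)  # (p, n)
    W = m.alphas * np.exp(-m.gamma * sq)                        # (p, n)
    # sum_n w_n (x_{n,j} - x_j) = (W @ Xn)_j - x_j * sum_n w_n
    return 2.0 * m.gamma * (W @ m.training_rows - X * W.sum(axis=1, keepdims=True))


def sensitivity_map(m: KernelModel, eval_points: FeatureMatrix | np.ndarray,
                    aggregation: str = "mean_square") -> ScalpTimeMap:
    """Aggregate the decision-function gradient over evaluation points.

    ``mean_square`` (default) returns the per-feature mean of the squared
    gradient; ``mean_signed`` the plain mean.  The flat feature axis is
    reshaped channel-major to a channels x time map.

    ``eval_points`` is typically the model's training data; any
    :class:`FeatureMatrix` with matching feature layout works.
    """
    if isinstance(eval_points, FeatureMatrix):
        X = eval_points.rows
        channel_names = list(eval_points.channel_names)
        times_ms = eval_points.times_ms
        n_channels, n_times = eval_points.n_channels, eval_points.n_times
    else:
        raise TypeError("eval_points must be a FeatureMatrix "
                        "(provides the channel/time layout)")
    if X.shape[0] == 0:
        raise ValueError("eval_points is empty")
    if X.shape[1] != m.training_rows.shape[1]:
        raise ValueError("eval point length does not match training rows")

    G = _gradients(m, X)
    if aggregation == "mean_square":
        flat = np.mean(G ** 2, axis=0)
    elif aggregation == "mean_signed":
        flat = np.mean(G, axis=0)
    else:
        raise ValueError(f"unknown aggregation: {aggregation!r}")

    return ScalpTimeMap(
        values=flat.reshape(n_channels, n_times),
        channel_names=channel_names,
        times_ms=np.asarray(times_ms, dtype=float),
        map_kind="sensitivity",
    )
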