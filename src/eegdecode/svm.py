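"""RBF-kernel SVM training contract and intersubject cross-validation schemes.

The classifier is the standard soft-margin SVM in dual form.  With training
observations x_n and labels y_n in {-1, +1} the discriminant is

    f(x) = sum_n alpha_n k(x_n, x) + b,      k(x_n, x) = exp(-gamma ||x_n - x||^2)

where alpha_n are the signed dual coefficients (alpha_n = y_n |alpha_n|,
|alpha_n| <= c), b the bias, gamma the kernel width and c the soft-margin
penalty.  The quadratic program is solved by scikit-learn's libsvm wrapper;
this module owns the model contract (full-length alpha vector with zeros
retained, retained training rows, an analytic decision function) which the
sensitivity-mapping stage differentiates.

Three intersubject evaluation schemes are provided, all leave-one-subject-out
(LOSO) at the outer level:

``loso_nested_cv``
    Basic nested LOSO: the inner loop selects (c, gamma) on the 14 training
    subjects by inner-LOSO validation accuracy; the outer subject is scored
    once with the selected parameters.
``loso_debiased_cv``
    Double holdout: each iteration leaves out one validation and one test
    subject (training on the remaining 13).  Optimal parameters are averaged
    over the validation subjects of each half of the cohort and transferred
    to score the test subjects of the other half, yielding exactly two
    transferred parameter sets.
``oracle_cv``
    Parameters are chosen to maximize the held-out subject's own test
    accuracy.  This is an optimistically biased upper bound on performance
    and is flagged as such in the result metadata.

Prediction ties (decision value exactly 0) go to the inanimate class (-1),
the majority class of the paradigm.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics.pairwise import euclidean_distances
from sklearn.svm import SVC

from .core_data import EpochedEEG, FeatureMatrix, flatten, zscore_trials
from .pseudotrial import average_categories

__all__ = [
    "HyperParams",
    "HyperGrid",
    "KernelModel",
    "CVResult",
    "SubjectResult",
    "rbf_kernel",
    "fit",
    "decision_function",
    "predict",
    "prepare_features",
    "loso_nested_cv",
    "loso_debiased_cv",
    "oracle_cv",
]

#: (c_min, c_max, gamma_min, gamma_max) of the named 10x10 search grids.
GRID_PRESETS: dict[str, tuple[float, float, float, float]] = {
    "single_trial": (0.05, 10.0, 2.5e-7, 5e-3),
    "debiased": (0.25, 15.0, 5e-7, 2.5e-2),
    "pseudotrial": (0.25, 15.0, 5e-7, 2.5e-2),
}


@dataclass(frozen=True)
class HyperParams:
    """Soft-margin penalty ``c`` and RBF width ``gamma``; both > 0."""

    c: float
    gamma: float

    def __post_init__(self) -> None:
        if self.c <= 0 or self.gamma <= 0:
            raise ValueError("c and gamma must be positive")


@dataclass
class HyperGrid:
    """A c x gamma search grid (10 x 10 = 100 combinations for the presets).

    Grid values are logarithmically spaced between the preset endpoints,
    endpoints included.
    """

    c_values: np.ndarray
    gamma_values: np.ndarray

    def __post_init__(self) -> None:
        self.c_values = np.asarray(self.c_values, dtype=float)
        self.gamma_values = np.asarray(self.gamma_values, dtype=float)
        if self.c_values.size == 0 or self.gamma_values.size == 0:
            raise ValueError("grid must be nonempty")
        if np.any(self.c_values <= 0) or np.any(self.gamma_values <= 0):
            raise ValueError("grid values must be positive")

    @classmethod
    def preset(cls, name: str, n_values: int = 10) -> "HyperGrid":
        try:
            c_lo, c_hi, g_lo, g_hi = GRID_PRESETS[name]
        except KeyError:
            raise ValueError(
                f"unknown preset {name!r}; choose from {sorted(GRID_PRESETS)}"
            ) from None
        return cls(np.geomspace(c_lo, c_hi, n_values),
                   np.geomspace(g_lo, g_hi, n_values))

    @property
    def n_combinations(self) -> int:
        return self.c_values.size * self.gamma_values.size

    def combinations(self) -> list[HyperParams]:
        return [HyperParams(c, g)
                for c, g in itertools.product(self.c_values, self.gamma_values)]

    def snap(self, c: float, gamma: float) -> HyperParams:
        """Nearest grid point: linear distance for c, log distance for gamma."""
        ci = int(np.argmin(np.abs(self.c_values - c)))
        gi = int(np.argmin(np.abs(np.log(self.gamma_values) - np.log(gamma))))
        return HyperParams(float(self.c_values[ci]), float(self.gamma_values[gi]))


@dataclass
class KernelModel:
    """Trained dual-form RBF SVM.

    ``alphas`` holds one signed dual coefficient per training row (zeros
    retained for non-support vectors); ``training_rows`` and
    ``training_labels`` are the canonical-order training data; ``bias`` is
    the intercept b of the discriminant.
    """

    alphas: np.ndarray
    bias: float
    gamma: float
    c: float
    training_rows: np.ndarray
    training_labels: np.ndarray

    @property
    def n_support(self) -> int:
        return int(np.count_nonzero(self.alphas))


@dataclass
class SubjectResult:
    """Outcome for one held-out subject."""

    subject_id: str
    accuracy: float
    params: HyperParams
    n_test: int
    p_value: float | None = None


@dataclass
class CVResult:
    """Per-subject accuracies plus scheme metadata.

    ``biased`` marks schemes whose accuracy estimate is optimistic (oracle
    parameter selection on the test subject itself).
    """

    scheme: str
    train_unit: str
    test_unit: str
    subjects: list[SubjectResult]
    biased: bool = False
    notes: dict = field(default_factory=dict)

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([s.accuracy for s in self.subjects])

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]


# ---------------------------------------------------------------------------
# Kernel and model contract
# ---------------------------------------------------------------------------

def rbf_kernel(a: np.ndarray, b: np.ndarray, gamma: float) -> float:
    """exp(-gamma * ||a - b||^2); lies in (0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    diff = a - b
    return float(np.exp(-gamma * diff.dot(diff)))


def _canonical_order(fm: FeatureMatrix) -> np.ndarray:
    """Sort rows by (subject id, trial index): permutation-invariant order."""
    return np.lexsort((fm.trial_index, fm.groups))


def fit(train: FeatureMatrix, hp: HyperParams,
        precomputed_sq: np.ndarray | None = None) -> KernelModel:
    """Train the soft-margin RBF SVM; deterministic for a given dataset.

    Training rows are sorted canonically by (subject, trial) before the
    solve, so row order in ``train`` does not affect the result.  The full
    signed dual-coefficient vector (zeros retained) and the training rows
    are stored on the model.

    Parameters
    ----------
    train
        Feature matrix with labels in {-1, +1}; both classes must be present.
    hp
        Penalty and kernel width.
    precomputed_sq
        Optional pairwise squared-distance matrix of ``train.rows`` (in the
        given row order), reused across fits at different hyperparameters.
    """
    labels = np.asarray(train.labels)
    if np.unique(labels).size < 2:
        raise ValueError("training set must contain both classes")

    order = _canonical_order(train)
    X = np.ascontiguousarray(train.rows[order])
    y = labels[order]

    if precomputed_sq is None:
        sq = euclidean_distances(X, squared=True)
    else:
        sq = precomputed_sq[np.ix_(order, order)]
    K = np.exp(-hp.gamma * sq)

    svc = SVC(C=hp.c, kernel="precomputed")
    svc.fit(K, y)

    alphas = np.zeros(X.shape[0])
    alphas[svc.support_] = svc.dual_coef_[0]
    return KernelModel(
        alphas=alphas,
        bias=float(svc.intercept_[0]),
        gamma=hp.gamma,
        c=hp.c,
        training_rows=X,
        training_labels=y,
    )


def decision_function(m: KernelModel, x: np.ndarray) -> float | np.ndarray:
    """f(x) = sum_n alpha_n exp(-gamma ||x_n - x||^2) + b.

    Accepts a single feature vector (returns a scalar) or a matrix of row
    vectors (returns one value per row).
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != m.training_rows.shape[1]:
        raise ValueError(
            f"feature length {X.shape[1]} does not match training rows "
            f"({m.training_rows.shape[1]})")
    sq = euclidean_distances(X, m.training_rows, squared=True)
    values = np.exp(-m.gamma * sq) @ m.alphas + m.bias
    return float(values[0]) if single else values


def predict(m: KernelModel, x: np.ndarray) -> int | np.ndarray:
    """Sign of the decision value; exact ties go to the inanimate class (-1)."""
    f = decision_function(m, x)
    if np.isscalar(f):
        return 1 if f > 0 else -1
    return np.where(np.asarray(f) > 0, 1, -1)


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------

def prepare_features(data: EpochedEEG, unit: str,
                     zscore_order: str = "after_averaging") -> FeatureMatrix:
    """Flatten the dataset into classifier observations of the given unit.

    ``unit="single_trial"`` z-scores every trial and flattens it.
    ``unit="pseudotrial"`` averages trials within (subject, category) and
    z-scores whichever unit enters the classifier: with the default
    ``zscore_order="after_averaging"`` the pseudotrials themselves are
    z-scored; with ``"before_averaging"`` the single trials are z-scored
    first and the averages are used as-is.
    """
    if unit == "single_trial":
        return flatten(zscore_trials(data))
    if unit == "pseudotrial":
        if zscore_order == "after_averaging":
            return flatten(zscore_trials(average_categories(data)))
        if zscore_order == "before_averaging":
            return flatten(average_categories(zscore_trials(data)))
        raise ValueError(f"unknown zscore_order: {zscore_order!r}")
    raise ValueError(f"unknown unit: {unit!r}")


class _GramCache:
    """Pairwise squared distances over a fixed row set, kernel per gamma."""

    def __init__(self, X: np.ndarray, X_other: np.ndarray | None = None):
        self.sq = euclidean_distances(
            X if X_other is None else X_other, X, squared=True)
        self._gamma: float | None = None
        self._K: np.ndarray | None = None

    def kernel(self, gamma: float) -> np.ndarray:
        if gamma != self._gamma:
            self._K = np.exp(-gamma * self.sq)
            self._gamma = gamma
        return self._K


def _accuracy(decisions: np.ndarray, truth: np.ndarray) -> float:
    pred = np.where(decisions > 0, 1, -1)
    return float(np.mean(pred == truth))


def _fit_precomputed(K_tr: np.ndarray, y: np.ndarray, c: float) -> SVC:
    svc = SVC(C=c, kernel="precomputed")
    svc.fit(K_tr, y)
    return svc


def _select_best(grid: HyperGrid, score: np.ndarray) -> tuple[int, int]:
    """Best (c index, gamma index) by score; ties -> smallest c, then gamma."""
    c_order = np.argsort(grid.c_values, kind="stable")
    g_order = np.argsort(grid.gamma_values, kind="stable")
    best, best_score = None, -np.inf
    for ci in c_order:
        for gi in g_order:
            if score[ci, gi] > best_score:
                best, best_score = (int(ci), int(gi)), float(score[ci, gi])
    return best


def _subject_row_indices(fm: FeatureMatrix, subject_ids: Sequence[str]
                         ) -> dict[str, np.ndarray]:
    return {s: np.flatnonzero(fm.groups == s) for s in subject_ids}


def _check_subject_count(data: EpochedEEG, minimum: int, scheme: str) -> None:
    if data.n_subjects < minimum:
        raise ValueError(f"{scheme} requires at least {minimum} subjects "
                         f"(got {data.n_subjects})")


# ---------------------------------------------------------------------------
# Cross-validation schemes
# ---------------------------------------------------------------------------

def loso_nested_cv(data: EpochedEEG, grid: HyperGrid,
                   mode: str = "pseudotrial",
                   test_unit: str = "pseudotrial",
                   zscore_order: str = "after_averaging",
                   n_perm: int | None = None,
                   seed: int = 0) -> CVResult:
    """Nested leave-one-subject-out cross-validation.

    Outer loop: each subject is held out for testing exactly once.  Inner
    loop: leave-one-subject-out over the remaining training subjects; the
    (c, gamma) combination with the best mean inner validation accuracy is
    selected (ties broken toward smaller c, then smaller gamma), the model
    is refit on all training subjects and scored on the held-out subject's
    ``test_unit`` observations.

    Because the training set of inner fold (outer=s, validation=v) depends
    only on the unordered pair {s, v}, each pair is fit once and evaluated
    on both members, halving the inner-loop cost.

    When ``n_perm`` is given, a label-permutation test of each held-out
    subject's accuracy is run (see :func:`eegdecode.eval_stats.permutation_test`).
    """
    _check_subject_count(data, 3, "nested LOSO")
    train_fm = prepare_features(data, mode, zscore_order)
    test_fm = (train_fm if test_unit == mode
               else prepare_features(data, test_unit, zscore_order))
    ids = list(data.subject_ids)
    n = len(ids)
    tr_rows = _subject_row_indices(train_fm, ids)
    te_rows = _subject_row_indices(test_fm, ids)

    gram = _GramCache(train_fm.rows)
    cross = None if test_fm is train_fm else _GramCache(train_fm.rows, test_fm.rows)

    n_c, n_g = grid.c_values.size, grid.gamma_values.size
    # val_acc[ci, gi, outer, val]: accuracy on `val` when both outer and val
    # are excluded from training
    val_acc = np.full((n_c, n_g, n, n), np.nan)

    for gi, gamma in enumerate(grid.gamma_values):
        K = gram.kernel(gamma)
        for a in range(n):
            for b in range(a + 1, n):
                keep = np.concatenate([tr_rows[ids[i]] for i in range(n)
                                       if i not in (a, b)])
                y = train_fm.labels[keep]
                K_tr = K[np.ix_(keep, keep)]
                for ci, c in enumerate(grid.c_values):
                    svc = _fit_precomputed(K_tr, y, c)
                    for ev in (a, b):
                        rows = tr_rows[ids[ev]]
                        dec = svc.decision_function(K[np.ix_(rows, keep)])
                        acc = _accuracy(dec, train_fm.labels[rows])
                        outer = b if ev == a else a
                        val_acc[ci, gi, outer, ev] = acc

    subjects: list[SubjectResult] = []
    rng = np.random.default_rng(seed)
    for s in range(n):
        inner_mean = np.nanmean(val_acc[:, :, s, :], axis=2)
        ci, gi = _select_best(grid, inner_mean)
        hp = HyperParams(float(grid.c_values[ci]), float(grid.gamma_values[gi]))

        keep = np.concatenate([tr_rows[ids[i]] for i in range(n) if i != s])
        K = gram.kernel(hp.gamma)
        svc = _fit_precomputed(K[np.ix_(keep, keep)], train_fm.labels[keep], hp.c)
        rows = te_rows[ids[s]]
        K_test = (K if cross is None else cross.kernel(hp.gamma))[np.ix_(rows, keep)]
        dec = svc.decision_function(K_test)
        truth = test_fm.labels[rows]
        pred = np.where(dec > 0, 1, -1)
        acc = float(np.mean(pred == truth))

        p_value = None
        if n_perm:
            from .eval_stats import permutation_test
            p_value = permutation_test(truth, pred, n_perm=n_perm,
                                       seed=int(rng.integers(2 ** 31)))
        subjects.append(SubjectResult(ids[s], acc, hp, rows.size, p_value))

    return CVResult(
        scheme="nested_loso", train_unit=mode, test_unit=test_unit,
        subjects=subjects,
        notes={"zscore_order": zscore_order,
               "n_train_rows": int(train_fm.n_rows - train_fm.n_rows // n)},
    )


def _debiased_iterations(ids: list[str]) -> tuple[list[tuple[str, str]],
                                                  list[str], list[str]]:
    """(validation, test) pairs; each subject validates exactly once.

    The cohort is split into a first half A and second half B (B gets the
    extra subject for odd counts).  Validation subjects from A are paired
    with test subjects from B and vice versa; with |B| > |A| one subject of
    A is tested twice (its accuracies are averaged).
    """
    n = len(ids)
    half_a, half_b = ids[: n // 2], ids[n // 2:]
    pairs = [(half_a[k], half_b[k % len(half_b)]) for k in range(len(half_a))]
    pairs += [(half_b[k], half_a[k % len(half_a)]) for k in range(len(half_b))]
    return pairs, half_a, half_b


def loso_debiased_cv(data: EpochedEEG, grid: HyperGrid,
                     mode: str = "single_trial",
                     test_unit: str = "single_trial",
                     zscore_order: str = "after_averaging") -> CVResult:
    """Double-holdout LOSO with transferred mean parameters.

    Each of the ``n_subjects`` iterations holds out one validation and one
    test subject and trains on the rest.  Grid search maximizes accuracy on
    the validation subject.  The per-half mean optimal parameters
    (arithmetic mean of c, geometric mean of gamma, snapped to the nearest
    grid point) are transferred to score the test subjects of the *other*
    half, so exactly two transferred parameter sets are produced.
    """
    _check_subject_count(data, 4, "debiased LOSO")
    train_fm = prepare_features(data, mode, zscore_order)
    test_fm = (train_fm if test_unit == mode
               else prepare_features(data, test_unit, zscore_order))
    ids = list(data.subject_ids)
    tr_rows = _subject_row_indices(train_fm, ids)
    te_rows = _subject_row_indices(test_fm, ids)
    gram = _GramCache(train_fm.rows)
    cross = None if test_fm is train_fm else _GramCache(train_fm.rows, test_fm.rows)

    pairs, half_a, half_b = _debiased_iterations(ids)

    n_c, n_g = grid.c_values.size, grid.gamma_values.size
    best_params: dict[str, HyperParams] = {}
    for val, test in pairs:
        if val in best_params:
            continue
        keep = np.concatenate([tr_rows[s] for s in ids if s not in (val, test)])
        y = train_fm.labels[keep]
        vrows = tr_rows[val]
        score = np.zeros((n_c, n_g))
        for gi, gamma in enumerate(grid.gamma_values):
            K = gram.kernel(gamma)
            K_tr = K[np.ix_(keep, keep)]
            K_val = K[np.ix_(vrows, keep)]
            for ci, c in enumerate(grid.c_values):
                svc = _fit_precomputed(K_tr, y, c)
                score[ci, gi] = _accuracy(svc.decision_function(K_val),
                                          train_fm.labels[vrows])
        ci, gi = _select_best(grid, score)
        best_params[val] = HyperParams(float(grid.c_values[ci]),
                                       float(grid.gamma_values[gi]))

    def _mean_params(validators: list[str]) -> HyperParams:
        cs = np.array([best_params[v].c for v in validators])
        gs = np.array([best_params[v].gamma for v in validators])
        return grid.snap(float(cs.mean()), float(np.exp(np.log(gs).mean())))

    transferred = {"A": _mean_params(half_a), "B": _mean_params(half_b)}

    # score test subjects with the parameters transferred from the other half
    acc_lists: dict[str, list[float]] = {s: [] for s in ids}
    used_params: dict[str, HyperParams] = {}
    for val, test in pairs:
        hp = transferred["A" if val in half_a else "B"]
        used_params[test] = hp
        keep = np.concatenate([tr_rows[s] for s in ids if s not in (val, test)])
        K = gram.kernel(hp.gamma)
        svc = _fit_precomputed(K[np.ix_(keep, keep)], train_fm.labels[keep], hp.c)
        rows = te_rows[test]
        K_test = (K if cross is None else cross.kernel(hp.gamma))[np.ix_(rows, keep)]
        acc = _accuracy(svc.decision_function(K_test), test_fm.labels[rows])
        acc_lists[test].append(acc)

    subjects = [SubjectResult(s, float(np.mean(acc_lists[s])), used_params[s],
                              te_rows[s].size)
                for s in ids if acc_lists[s]]
    return CVResult(
        scheme="debiased_loso", train_unit=mode, test_unit=test_unit,
        subjects=subjects,
        notes={
            "zscore_order": zscore_order,
            "transferred_params": {
                h: {"c": p.c, "gamma": p.gamma} for h, p in transferred.items()},
            "validation_optima": {
                v: {"c": p.c, "gamma": p.gamma} for v, p in best_params.items()},
        },
    )


def oracle_cv(data: EpochedEEG, grid: HyperGrid,
              mode: str = "pseudotrial",
              test_unit: str = "pseudotrial",
              zscore_order: str = "after_averaging") -> CVResult:
    """Upper performance bound: parameters chosen on the test subject itself.

    For each held-out subject the grid combination maximizing that subject's
    own test accuracy is reported.  The estimate is optimistically biased by
    construction; ``result.biased`` is True.
    """
    _check_subject_count(data, 3, "oracle LOSO")
    train_fm = prepare_features(data, mode, zscore_order)
    test_fm = (train_fm if test_unit == mode
               else prepare_features(data, test_unit, zscore_order))
    ids = list(data.subject_ids)
    tr_rows = _subject_row_indices(train_fm, ids)
    te_rows = _subject_row_indices(test_fm, ids)
    gram = _GramCache(train_fm.rows)
    cross = None if test_fm is train_fm else _GramCache(train_fm.rows, test_fm.rows)

    n_c, n_g = grid.c_values.size, grid.gamma_values.size
    subjects: list[SubjectResult] = []
    for s in ids:
        keep = np.concatenate([tr_rows[t] for t in ids if t != s])
        y = train_fm.labels[keep]
        rows = te_rows[s]
        truth = test_fm.labels[rows]
        score = np.zeros((n_c, n_g))
        for gi, gamma in enumerate(grid.gamma_values):
            K = gram.kernel(gamma)
            K_tr = K[np.ix_(keep, keep)]
            K_test = (K if cross is None else cross.kernel(gamma))[np.ix_(rows, keep)]
            for ci, c in enumerate(grid.c_values):
                svc = _fit_precomputed(K_tr, y, c)
                score[ci, gi] = _accuracy(svc.decision_function(K_test), truth)
        ci, gi = _select_best(grid, score)
        subjects.append(SubjectResult(
            s, float(score[ci, gi]),
            HyperParams(float(grid.c_values[ci]), float(grid.gamma_values[gi])),
            rows.size))

    return CVResult(
        scheme="oracle_loso", train_unit=mode, test_unit=test_unit,
        subjects=subjects, biased=True,
        notes={"zscore_order": zscore_order,
               "warning": "parameters selected on the test subject; "
                          "accuracy is an optimistic upper bound"},
    )
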