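"""Significance and uncertainty of decoding accuracies.

Covers the label-permutation test of a held-out subject's accuracy, the
standard error of leave-one-subject-out accuracies with a dependence
correction for overlapping training sets, and the paired comparison of two
cross-validated classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "permutation_test",
    "corrected_sem",
    "SemResult",
    "compare_classifiers",
    "PairedComparison",
]


def permutation_test(true_labels: np.ndarray, predicted_labels: np.ndarray,
                     n_perm: int = 1000, seed: int = 0) -> float:
    """Permutation p-value for the accuracy of fixed predictions.

    The true labels are shuffled against the fixed predictions ``n_perm``
    times; the p-value uses the add-one convention

        p = (1 + #{permuted accuracy >= observed}) / (n_perm + 1)

    so it can never be exactly zero.
    """
    truth = np.asarray(true_labels)
    pred = np.asarray(predicted_labels)
    if truth.shape != pred.shape:
        raise ValueError("true and predicted labels must have equal length")
    if np.unique(truth).size < 2:
        raise ValueError("true labels contain a single class")

    observed = np.mean(pred == truth)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(truth)
        if np.mean(pred == perm) >= observed:
            count += 1
    return (1 + count) / (n_perm + 1)


@dataclass
class SemResult:
    """Naive and dependence-corrected SEM of cross-validated accuracies."""

    corrected: float
    naive: float
    rho: float
    n_folds: int


def corrected_sem(per_subject_accuracies: np.ndarray,
                  n_train: int, n_test: int) -> SemResult:
    """Standard error of the mean LOSO accuracy, corrected for fold dependence.

    Leave-one-subject-out folds share most of their training data, so fold
    accuracies are positively correlated and the naive ``sd / sqrt(K)``
    understates uncertainty.  The implemented variance correction inflates
    it by the test/train size ratio:

        SEM = sd * sqrt(1/K + rho),   rho = n_test / n_train

    The naive SEM is always co-reported.
    """
    acc = np.asarray(per_subject_accuracies, dtype=float)
    if acc.size < 2:
        raise ValueError("need at least 2 folds")
    if n_train <= 0 or n_test <= 0:
        raise ValueError("n_train and n_test must be positive")
    sd = float(acc.std(ddof=1))
    k = acc.size
    rho = n_test / n_train
    return SemResult(
        corrected=sd * float(np.sqrt(1.0 / k + rho)),
        naive=sd / float(np.sqrt(k)),
        rho=rho,
        n_folds=k,
    )


@dataclass
class PairedComparison:
    """Paired t-test of two classifiers' per-subject accuracies."""

    t_statistic: float
    p_value: float
    mean_difference: float
    ci_low: float
    ci_high: float
    n_pairs: int
    degenerate: bool = False


def compare_classifiers(cv_a, cv_b, ci_level: float = 0.95) -> PairedComparison:
    """Paired t-test across subjects of ``cv_a`` vs ``cv_b`` accuracies.

    Both results must cover the same subjects in any order.  If the
    per-subject differences have zero variance the comparison is flagged
    degenerate (t undefined unless the mean difference is also zero).
    """
    ids_a, ids_b = cv_a.subject_ids(), cv_b.subject_ids()
    if sorted(ids_a) != sorted(ids_b):
        raise ValueError("classifier results cover different subjects")
    acc_a = dict(zip(ids_a, cv_a.accuracies))
    acc_b = dict(zip(ids_b, cv_b.accuracies))
    diffs = np.array([acc_a[s] - acc_b[s] for s in sorted(ids_a)])

    n = diffs.size
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    if sd < 1e-12:  # constant differences up to floating-point noise
        t = 0.0 if mean == 0.0 else float(np.sign(mean) * np.inf)
        p = 1.0 if mean == 0.0 else 0.0
        return PairedComparison(t, p, mean, mean, mean, n, degenerate=True)

    se = sd / np.sqrt(n)
    t = mean / se
    p = float(2.0 * stats.t.sf(abs(t), df=n - 1))
    tcrit = float(stats.t.ppf(0.5 + ci_level / 2.0, df=n - 1))
    return PairedComparison(float(t), p, mean,
                            mean - tcrit * se, mean + tcrit * se, n)
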