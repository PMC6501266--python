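"""ERP averages, animate-inanimate difference maps and paired-t significance maps.

Subject-level class means are the analysis unit throughout: an ERP is the
mean over a subject's trials of one class, grand averages weight subjects
equally, and the significance map is a paired t-test across subjects of the
animate vs inanimate subject means, Bonferroni-corrected either over the 60
time samples of a channel-averaged trace or over the full
60 x n_channels map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_data import EpochedEEG
from .sensitivity import ScalpTimeMap

__all__ = [
    "ERPSet",
    "TTestMapResult",
    "POSTERIOR_TRACE_CHANNELS",
    "compute_erps",
    "erp_difference_map",
    "paired_ttest_map",
]

#: Channels averaged for the posterior ERP trace test.
POSTERIOR_TRACE_CHANNELS: tuple[str, ...] = ("O1", "O2", "Oz", "PO3", "PO4")


@dataclass
class ERPSet:
    """Per-subject and grand-average class ERPs.

    ``subject_means`` has shape (n_subjects, 2, n_channels, n_times) with
    class axis ordered (animate, inanimate).  Grand averages are unweighted
    means over subjects; ``grand_sem`` is the between-subject standard error
    of the grand average (ddof=1).
    """

    subject_means: np.ndarray
    grand_animate: np.ndarray
    grand_inanimate: np.ndarray
    grand_sem: np.ndarray
    subject_ids: list[str]
    channel_names: list[str]
    times_ms: np.ndarray


@dataclass
class TTestMapResult:
    """Paired-t map plus its Bonferroni significance mask."""

    t_map: ScalpTimeMap
    significant: np.ndarray
    alpha: float
    n_comparisons: int
    correction_scope: str


def compute_erps(d: EpochedEEG) -> ERPSet:
    """Class-mean waveforms per subject and unweighted grand averages.

    Raises
    ------
    ValueError
        If some subject lacks trials of either class.
    """
    n_s = d.n_subjects
    subject_means = np.empty((n_s, 2, d.n_channels, d.n_times))
    for s in range(n_s):
        for k, label in enumerate((1, -1)):
            mask = d.animacy_labels[s] == label
            if not mask.any():
                cls = "animate" if label == 1 else "inanimate"
                raise ValueError(
                    f"subject {d.subject_ids[s]} has no {cls} trials")
            subject_means[s, k] = d.data[s, mask].mean(axis=0)

    grand = subject_means.mean(axis=0)
    sem = (subject_means.std(axis=0, ddof=1) / np.sqrt(n_s)
           if n_s > 1 else np.zeros_like(grand))
    return ERPSet(
        subject_means=subject_means,
        grand_animate=grand[0],
        grand_inanimate=grand[1],
        grand_sem=sem,
        subject_ids=list(d.subject_ids),
        channel_names=list(d.channel_names),
        times_ms=d.times_ms.copy(),
    )


def erp_difference_map(e: ERPSet) -> ScalpTimeMap:
    """Grand animate mean minus grand inanimate mean (channels x time)."""
    return ScalpTimeMap(
        values=e.grand_animate - e.grand_inanimate,
        channel_names=list(e.channel_names),
        times_ms=e.times_ms.copy(),
        map_kind="erp_difference",
    )


def paired_ttest_map(e: ERPSet, alpha: float = 0.05,
                     correction_scope: str = "time_by_channel",
                     trace_channels: tuple[str, ...] = POSTERIOR_TRACE_CHANNELS,
                     ) -> TTestMapResult:
    """Paired t-test of animate vs inanimate subject means, Bonferroni-corrected.

    ``correction_scope="time_by_channel"`` tests every (channel, time) cell
    with threshold ``alpha / (n_times * n_channels)``.
    ``correction_scope="time_only"`` averages the waveforms over
    ``trace_channels`` first and tests the resulting 60-sample trace at
    ``alpha / n_times``.

    Cells with zero variance across subjects get t = +/-inf and are flagged
    significant iff their mean difference is nonzero.
    """
    n_s = e.subject_means.shape[0]
    if n_s < 3:
        raise ValueError("paired t-test requires at least 3 subjects")

    diffs = e.subject_means[:, 0] - e.subject_means[:, 1]  # (n_s, ch, t)
    if correction_scope == "time_by_channel":
        channel_names = list(e.channel_names)
    elif correction_scope == "time_only":
        ch_idx = [e.channel_names.index(c) for c in trace_channels
                  if c in e.channel_names]
        if not ch_idx:
            raise ValueError("none of the trace channels are in the montage")
        diffs = diffs[:, ch_idx].mean(axis=1, keepdims=True)
        channel_names = ["+".join(trace_channels)]
    else:
        raise ValueError(f"unknown correction_scope: {correction_scope!r}")

    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n_s))

    zero_var = sd == 0
    t[zero_var] = np.where(mean[zero_var] > 0, np.inf,
                           np.where(mean[zero_var] < 0, -np.inf, 0.0))

    n_comparisons = t.size
    threshold = alpha / n_comparisons
    p = 2.0 * stats.t.sf(np.abs(np.where(np.isinf(t), 0.0, t)), df=n_s - 1)
    p[np.isinf(t)] = 0.0
    significant = p < threshold
    # zero-variance, zero-mean cells carry no evidence
    significant[zero_var & (mean == 0)] = False

    t_map = ScalpTimeMap(values=t, channel_names=channel_names,
                         times_ms=e.times_ms.copy(), map_kind="t_statistic")
    return TTestMapResult(t_map=t_map, significant=significant, alpha=alpha,
                          n_comparisons=n_comparisons,
                          correction_scope=correction_scope)
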