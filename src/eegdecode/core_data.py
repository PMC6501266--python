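"""Epoched EEG container, validation, per-trial normalization and feature flattening.

The central object is :class:`EpochedEEG`: a rectangular ``(subject, trial,
channel, time)`` array of epoched, preprocessed EEG together with per-trial
category and animacy labels.  Every downstream stage (pseudotrial averaging,
SVM training, sensitivity mapping, ERP statistics) consumes this container or
the flat :class:`FeatureMatrix` derived from it.

Conventions
-----------
* Animacy labels are ``+1`` for animate and ``-1`` for inanimate trials.
* The default paradigm epoch is 60 samples at 100 Hz covering the half-open
  window [-100, 500) ms, i.e. t = -100, -90, ..., 490 ms.
* Feature flattening is channel-major: feature ``j`` maps to channel
  ``j // n_times`` and time sample ``j % n_times``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DEFAULT_MONTAGE_32",
    "EpochedEEG",
    "FeatureMatrix",
    "ValidationReport",
    "validate_dataset",
    "zscore_trials",
    "flatten",
    "unflatten",
]

#: Canonical 32-channel dry-electrode montage (10-10 labels), posterior row
#: includes the occipital/parietal channels where visual responses dominate.
DEFAULT_MONTAGE_32: tuple[str, ...] = (
    "Fp1", "Fp2", "AF3", "AF4", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "PO3", "PO4", "O1", "Oz", "O2",
)


@dataclass
class EpochedEEG:
    """Rectangular epoched EEG dataset.

    Parameters
    ----------
    data
        Array of shape ``(n_subjects, n_trials, n_channels, n_times)``.
    subject_ids
        One identifier per subject, in data order.
    category_labels
        Integer category per (subject, trial), values in ``1..n_categories``.
    animacy_labels
        Per-(subject, trial) animacy, ``+1`` animate / ``-1`` inanimate.
        Must be a deterministic function of the category.
    channel_names
        Montage labels in channel order.
    times_ms
        Sample time stamps in milliseconds relative to stimulus onset;
        strictly increasing and uniformly spaced at ``1000 / sampling_rate_hz``.
    sampling_rate_hz
        Sampling rate of the epoch grid.
    """

    data: np.ndarray
    subject_ids: list[str]
    category_labels: np.ndarray
    animacy_labels: np.ndarray
    channel_names: list[str]
    times_ms: np.ndarray
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.category_labels = np.asarray(self.category_labels, dtype=int)
        self.animacy_labels = np.asarray(self.animacy_labels, dtype=int)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.subject_ids = list(self.subject_ids)
        self.channel_names = list(self.channel_names)

    # -- shape accessors ---------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def n_times(self) -> int:
        return self.data.shape[3]

    def subject_index(self, subject_id: str) -> int:
        try:
            return self.subject_ids.index(subject_id)
        except ValueError:
            raise KeyError(f"unknown subject id: {subject_id!r}") from None

    def copy(self) -> "EpochedEEG":
        return EpochedEEG(
            data=self.data.copy(),
            subject_ids=list(self.subject_ids),
            category_labels=self.category_labels.copy(),
            animacy_labels=self.animacy_labels.copy(),
            channel_names=list(self.channel_names),
            times_ms=self.times_ms.copy(),
            sampling_rate_hz=self.sampling_rate_hz,
        )


@dataclass
class FeatureMatrix:
    """Flat observation matrix: one row per trial (or pseudotrial).

    ``rows`` has shape ``(n_rows, n_channels * n_times)`` in channel-major
    order; ``labels`` is the per-row animacy in {-1, +1}; ``groups`` the
    per-row subject id.  The feature index maps bijectively to a
    ``(channel, time_sample)`` pair via ``feature_to_channel_time``.
    """

    rows: np.ndarray
    labels: np.ndarray
    groups: np.ndarray
    n_channels: int
    n_times: int
    channel_names: list[str] = field(default_factory=list)
    times_ms: np.ndarray | None = None
    #: per-row within-subject trial index; together with ``groups`` it defines
    #: the canonical (subject, trial) row order used to make SVM training
    #: deterministic under row permutations
    trial_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.trial_index is None:
            self.trial_index = np.arange(self.rows.shape[0])

    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]

    @property
    def n_features(self) -> int:
        return self.rows.shape[1]

    def feature_to_channel_time(self, j: int) -> tuple[int, int]:
        """Map a feature index to its (channel, time_sample) pair."""
        if not 0 <= j < self.n_features:
            raise IndexError(f"feature index {j} out of range")
        return j // self.n_times, j % self.n_times

    def channel_time_to_feature(self, channel: int, time_sample: int) -> int:
        if not (0 <= channel < self.n_channels and 0 <= time_sample < self.n_times):
            raise IndexError("channel/time index out of range")
        return channel * self.n_times + time_sample

    def subset(self, subject_ids: Sequence[str]) -> "FeatureMatrix":
        wanted = set(subject_ids)
        mask = np.array([g in wanted for g in self.groups])
        return FeatureMatrix(
            rows=self.rows[mask],
            labels=self.labels[mask],
            groups=self.groups[mask],
            n_channels=self.n_channels,
            n_times=self.n_times,
            channel_names=list(self.channel_names),
            times_ms=None if self.times_ms is None else self.times_ms.copy(),
            trial_index=self.trial_index[mask],
        )


@dataclass
class ValidationCheck:
    name: str
    passed: bool
    detail: str = ""


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_dataset`: one entry per invariant."""

    checks: list[ValidationCheck]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def failures(self) -> list[ValidationCheck]:
        return [c for c in self.checks if not c.passed]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        status = "PASS" if self.passed else "FAIL"
        lines = [f"<ValidationReport {status}>"]
        for c in self.checks:
            lines.append(f"  [{'ok' if c.passed else 'FAIL'}] {c.name}"
                         + (f": {c.detail}" if c.detail else ""))
        return "\n".join(lines)


def validate_dataset(d: EpochedEEG) -> ValidationReport:
    """Check the container invariants; never raises, returns a report.

    Checks: label arrays match the (subject, trial) extent; animacy is a
    deterministic function of category; the time axis is strictly increasing
    and uniformly spaced at ``1000 / sampling_rate_hz``; animacy values lie
    in {-1, +1}.
    """
    checks: list[ValidationCheck] = []
    st_shape = d.data.shape[:2]

    ok = d.category_labels.shape == st_shape and d.animacy_labels.shape == st_shape
    checks.append(ValidationCheck(
        "label shapes match data",
        ok,
        "" if ok else f"data {st_shape}, category {d.category_labels.shape}, "
                      f"animacy {d.animacy_labels.shape}",
    ))

    ok = len(d.subject_ids) == d.data.shape[0]
    checks.append(ValidationCheck(
        "subject_ids length", ok,
        "" if ok else f"{len(d.subject_ids)} ids for {d.data.shape[0]} subjects"))

    ok = len(d.channel_names) == d.data.shape[2]
    checks.append(ValidationCheck(
        "channel_names length", ok,
        "" if ok else f"{len(d.channel_names)} names for {d.data.shape[2]} channels"))

    values = np.unique(d.animacy_labels)
    ok = bool(np.all(np.isin(values, (-1, 1))))
    checks.append(ValidationCheck(
        "animacy values in {-1,+1}", ok,
        "" if ok else f"found values {values.tolist()}"))

    # animacy must be a deterministic function of category
    bad_categories = []
    for cat in np.unique(d.category_labels):
        anim = np.unique(d.animacy_labels[d.category_labels == cat])
        if anim.size > 1:
            bad_categories.append(int(cat))
    checks.append(ValidationCheck(
        "animacy deterministic per category",
        not bad_categories,
        "" if not bad_categories
        else f"categories with mixed animacy: {bad_categories}"))

    if d.times_ms.size >= 2:
        steps = np.diff(d.times_ms)
        increasing = bool(np.all(steps > 0))
        expected = 1000.0 / d.sampling_rate_hz
        uniform = increasing and bool(np.allclose(steps, expected, rtol=1e-9, atol=1e-9))
        checks.append(ValidationCheck(
            "time axis strictly increasing", increasing,
            "" if increasing else "time axis not increasing"))
        checks.append(ValidationCheck(
            "time axis uniform at 1000/fs", uniform,
            "" if uniform else "time axis not uniform"))
    else:
        checks.append(ValidationCheck("time axis strictly increasing", True))
        checks.append(ValidationCheck("time axis uniform at 1000/fs", True))

    ok = d.times_ms.size == d.data.shape[3]
    checks.append(ValidationCheck(
        "times_ms length", ok,
        "" if ok else f"{d.times_ms.size} stamps for {d.data.shape[3]} samples"))

    return ValidationReport(checks)


def zscore_trials(d: EpochedEEG) -> EpochedEEG:
    """Normalize every trial to zero mean, unit standard deviation.

    The mean and standard deviation are taken jointly across the trial's
    channel x time block (population convention, divide by n).  Idempotent;
    labels and metadata are untouched.

    Raises
    ------
    ValueError
        If any (subject, trial) block is constant (zero variance).
    """
    block = d.data.reshape(d.n_subjects, d.n_trials, -1)
    mean = block.mean(axis=2, keepdims=True)
    sd = block.std(axis=2, keepdims=True)  # population sd (ddof=0)
    degenerate = np.argwhere(sd[:, :, 0] == 0.0)
    if degenerate.size:
        s, t = degenerate[0]
        raise ValueError(
            f"constant trial: subject index {int(s)} "
            f"({d.subject_ids[int(s)]}), trial {int(t)} has zero variance")
    z = (block - mean) / sd
    out = d.copy()
    out.data = z.reshape(d.data.shape)
    return out


def flatten(d: EpochedEEG, subjects: Sequence[str] | None = None) -> FeatureMatrix:
    """Flatten trials of the selected subjects into a feature matrix.

    Rows are ordered by subject (in ``d.subject_ids`` order restricted to
    the selection) then trial; features are channel-major then time.
    """
    if subjects is None:
        subjects = d.subject_ids
    idx = [d.subject_index(s) for s in subjects]

    rows = d.data[idx].reshape(len(idx) * d.n_trials, d.n_channels * d.n_times)
    labels = d.animacy_labels[idx].reshape(-1)
    groups = np.repeat([d.subject_ids[i] for i in idx], d.n_trials)
    return FeatureMatrix(
        rows=rows,
        labels=labels,
        groups=np.asarray(groups),
        n_channels=d.n_channels,
        n_times=d.n_times,
        channel_names=list(d.channel_names),
        times_ms=d.times_ms.copy(),
        trial_index=np.tile(np.arange(d.n_trials), len(idx)),
    )


def unflatten(fm: FeatureMatrix) -> np.ndarray:
    """Inverse of the per-row flattening: ``(n_rows, n_channels, n_times)``."""
    return fm.rows.reshape(fm.n_rows, fm.n_channels, fm.n_times)


def default_times_ms(n_times: int = 60, sampling_rate_hz: float = 100.0,
                     start_ms: float = -100.0) -> np.ndarray:
    """Left-aligned epoch grid: t = start, start + dt, ... (half-open window)."""
    dt = 1000.0 / sampling_rate_hz
    return start_ms + dt * np.arange(n_times)
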