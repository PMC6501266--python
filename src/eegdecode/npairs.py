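"""NPAIRS split-half resampling: scaling full-data maps into effect sizes.

NPAIRS (nonparametric prediction, activation, influence, and reproducibility
resampling) quantifies the uncertainty of a brain map by recomputing it on
two disjoint halves of the cohort and contrasting the results.  Here the
scheme scales a full-cohort map M_full into an effect-size map:

    sigma^2 = 1 / (S * T * N) * sum_{i,t,n} (M1^i - M2^i)_{t,n}^2
    M_hat   = M_full / sigma

where S is the number of random splits, M1^i and M2^i the maps computed on
the two partitions of split i, and the inner sum runs over all map elements
(channels x time).  With 15 subjects and partitions of 7, each split leaves
one random subject out.

The procedure is generic over any map-producing function (ERP difference
maps, SVM sensitivity maps, ...); factories for the standard map functions
are provided.  Any model fitting inside ``map_fn`` must be deterministic
given the subject subset — hyperparameters are fixed inputs (e.g. the
transferred parameters of the debiased CV), not re-optimized per split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .core_data import EpochedEEG
from .sensitivity import ScalpTimeMap, sensitivity_map
from .svm import HyperParams, fit, prepare_features

__all__ = [
    "NPAIRSConfig",
    "EffectSizeResult",
    "make_splits",
    "npairs_effect_size",
    "erp_difference_map_fn",
    "sensitivity_map_fn",
]


@dataclass
class NPAIRSConfig:
    """Number of splits, partition size and RNG seed."""

    n_splits: int = 100
    partition_size: int = 7
    rng_seed: int = 0

    def validate(self, n_subjects: int) -> None:
        if self.n_splits < 2:
            raise ValueError("n_splits must be >= 2")
        if self.partition_size < 1:
            raise ValueError("partition_size must be >= 1")
        if 2 * self.partition_size > n_subjects:
            raise ValueError(
                f"2 * partition_size = {2 * self.partition_size} exceeds "
                f"the {n_subjects} available subjects")


@dataclass
class EffectSizeResult:
    """Full map, NPAIRS scale sigma, effect map and the split log."""

    full_map: ScalpTimeMap
    sigma: float
    effect_map: ScalpTimeMap
    split_log: list[tuple[tuple[str, ...], tuple[str, ...]]] = field(
        default_factory=list)


def make_splits(subject_ids: Sequence[str], cfg: NPAIRSConfig
                ) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """Draw ``cfg.n_splits`` random pairs of disjoint subject partitions.

    Subjects are sampled without replacement within a split; with 15
    subjects and partitions of 7, exactly one subject is left out per split.
    Reproducible from ``cfg.rng_seed``.
    """
    ids = list(subject_ids)
    cfg.validate(len(ids))
    rng = np.random.default_rng(cfg.rng_seed)
    splits = []
    for _ in range(cfg.n_splits):
        perm = rng.permutation(len(ids))
        k = cfg.partition_size
        p1 = tuple(ids[i] for i in perm[:k])
        p2 = tuple(ids[i] for i in perm[k:2 * k])
        splits.append((p1, p2))
    return splits


def npairs_effect_size(data: EpochedEEG,
                       map_fn: Callable[[EpochedEEG, Sequence[str]], ScalpTimeMap],
                       cfg: NPAIRSConfig | None = None) -> EffectSizeResult:
    """Scale ``map_fn`` over all subjects by its split-half variability.

    ``map_fn(data, subject_subset)`` must return a :class:`ScalpTimeMap`
    and be deterministic for a given subset.

    Raises
    ------
    ValueError
        If sigma is exactly zero ("degenerate resampling"), which signals
        constant data or a subset-independent map_fn.
    """
    cfg = cfg or NPAIRSConfig()
    splits = make_splits(data.subject_ids, cfg)

    sq_sum = 0.0
    n_elements = None
    for p1, p2 in splits:
        m1 = map_fn(data, p1).values
        m2 = map_fn(data, p2).values
        if n_elements is None:
            n_elements = m1.size
        sq_sum += float(np.sum((m1 - m2) ** 2))

    sigma = float(np.sqrt(sq_sum / (cfg.n_splits * n_elements)))
    if sigma == 0.0:
        raise ValueError("degenerate resampling: identical partition maps")

    full = map_fn(data, data.subject_ids)
    effect = ScalpTimeMap(
        values=full.values / sigma,
        channel_names=list(full.channel_names),
        times_ms=full.times_ms.copy(),
        map_kind="effect_size",
    )
    return EffectSizeResult(full_map=full, sigma=sigma, effect_map=effect,
                            split_log=splits)


# ---------------------------------------------------------------------------
# Standard map functions
# ---------------------------------------------------------------------------

def _subset(data: EpochedEEG, subjects: Sequence[str]) -> EpochedEEG:
    idx = [data.subject_index(s) for s in subjects]
    return EpochedEEG(
        data=data.data[idx],
        subject_ids=[data.subject_ids[i] for i in idx],
        category_labels=data.category_labels[idx],
        animacy_labels=data.animacy_labels[idx],
        channel_names=list(data.channel_names),
        times_ms=data.times_ms.copy(),
        sampling_rate_hz=data.sampling_rate_hz,
    )


def erp_difference_map_fn(data: EpochedEEG, subjects: Sequence[str]
                          ) -> ScalpTimeMap:
    """Animate-minus-inanimate grand-average ERP difference on a subject subset."""
    from .erp_stats import compute_erps, erp_difference_map
    return erp_difference_map(compute_erps(_subset(data, subjects)))


def sensitivity_map_fn(unit: str, params: HyperParams,
                       zscore_order: str = "after_averaging",
                       aggregation: str = "mean_square"
                       ) -> Callable[[EpochedEEG, Sequence[str]], ScalpTimeMap]:
    """Factory: train an SVM of the given unit on the subset at fixed
    hyperparameters and return its sensitivity map over the training rows."""

    def _fn(data: EpochedEEG, subjects: Sequence[str]) -> ScalpTimeMap:
        fm = prepare_features(_subset(data, subjects), unit, zscore_order)
        model = fit(fm, params)
        return sensitivity_map(model, fm, aggregation)

    return _fn
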