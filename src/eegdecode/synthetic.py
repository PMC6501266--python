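"""Synthetic epoched-EEG generator reproducing the visual animacy paradigm.

The simulator emulates the structure of a rapid natural-image experiment:
15 subjects view 23 semantic categories (10 animate, 13 inanimate) of 30
images each, presented in randomized category blocks, yielding 690 epoched
trials per subject (300 animate, 390 inanimate) on a 32-channel montage at
100 Hz over [-100, 500) ms.

Each simulated trial is the sum of

* a common visual evoked template (Gaussian-windowed deflections: an early
  posterior negativity near 90 ms, a positivity near 140 ms, and P3a/P3b-like
  components at 250-320 ms), weighted toward occipito-parietal channels;
* a subject-specific multiplicative gain (lognormal) and latency shift
  (uniform, +/- jitter), modelling intersubject ERP variability;
* for animate trials only, a class-dependent component confined to the
  configured effect channels and time window (Hann-windowed bump); and
* independent Gaussian sensor noise (optionally AR(1)-smoothed in time).

Single-trial SNR is deliberately low: with the default amplitudes the
planted class difference is far below the noise floor of one trial and only
becomes prominent after trial averaging, mirroring real scalp EEG.

The module also reproduces the paradigm's timing arithmetic (probe words,
jittered interstimulus intervals drawn from a 7-value grid averaging 2 s,
and rest breaks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import DEFAULT_MONTAGE_32, EpochedEEG, default_times_ms

__all__ = [
    "SimulationConfig",
    "ParadigmTiming",
    "generate_dataset",
    "sample_isi",
    "experiment_duration",
]


@dataclass
class SimulationConfig:
    """All generator knobs.

    Amplitudes are in arbitrary signal units; only their ratios matter
    because every trial is z-scored before entering a classifier.  The
    default ``noise_sd``/``effect_amplitude`` ratio is calibrated so that
    intersubject single-trial decoding accuracy falls in the 0.55-0.65
    range typical of scalp EEG animacy decoding.
    """

    n_subjects: int = 15
    n_categories: int = 23
    n_animate_categories: int = 10
    trials_per_category: int = 30
    n_channels: int = 32
    sampling_rate_hz: float = 100.0
    epoch_start_ms: float = -100.0
    n_times: int = 60
    channel_names: tuple[str, ...] = DEFAULT_MONTAGE_32
    effect_channels: tuple[str, ...] = ("O1", "O2", "P7", "P8")
    effect_window_ms: tuple[float, float] = (200.0, 330.0)
    effect_amplitude: float = 0.22
    subject_amplitude_sd: float = 0.25
    subject_latency_jitter_ms: float = 20.0
    noise_sd: float = 1.0
    common_erp_amplitude: float = 1.0
    ar1_coefficient: float = 0.0
    rng_seed: int = 0

    @property
    def n_trials(self) -> int:
        return self.n_categories * self.trials_per_category

    @property
    def n_animate_trials(self) -> int:
        return self.n_animate_categories * self.trials_per_category

    def validate(self) -> None:
        """Raise ValueError naming the offending field on invalid config."""
        if self.n_animate_categories >= self.n_categories:
            raise ValueError("n_animate_categories must be < n_categories")
        for name in ("n_subjects", "n_categories", "n_animate_categories",
                     "trials_per_category", "n_channels", "n_times"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_channels != len(self.channel_names):
            raise ValueError("n_channels does not match channel_names length")
        missing = set(self.effect_channels) - set(self.channel_names)
        if missing:
            raise ValueError(f"effect_channels not in montage: {sorted(missing)}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        times = self.times_ms()
        lo, hi = self.effect_window_ms
        if not (times[0] <= lo < hi):
            raise ValueError("effect_window_ms must be increasing and inside the epoch")
        if hi > times[-1] + 1000.0 / self.sampling_rate_hz:
            raise ValueError("effect_window_ms extends past the epoch window")
        if not -1.0 < self.ar1_coefficient < 1.0:
            raise ValueError("ar1_coefficient must be in (-1, 1)")

    def times_ms(self) -> np.ndarray:
        return default_times_ms(self.n_times, self.sampling_rate_hz,
                                self.epoch_start_ms)


@dataclass
class ParadigmTiming:
    """Stimulus-presentation timing of the paradigm."""

    probe_duration_s: float = 5.0
    stimulus_duration_s: float = 1.0
    isi_values_s: tuple[float, ...] = (1.85, 1.90, 1.95, 2.00, 2.05, 2.10, 2.15)
    n_breaks: int = 5
    break_duration_s: float = 35.0

    def __post_init__(self) -> None:
        if len(self.isi_values_s) == 0:
            raise ValueError("isi_values_s must be nonempty")


def sample_isi(timing: ParadigmTiming, n: int, seed: int | np.random.Generator = 0
               ) -> np.ndarray:
    """Draw ``n`` interstimulus intervals uniformly (with replacement) from the grid."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.choice(np.asarray(timing.isi_values_s, dtype=float), size=n, replace=True)


def experiment_duration(timing: ParadigmTiming, n_categories: int = 23,
                        trials_per_category: int = 30,
                        use_expected_isi: bool = True,
                        seed: int = 0) -> float:
    """Total experiment duration in seconds.

    With the expected ISI of the grid (2.0 s by default) the default
    paradigm lasts 23*5 + 23*30*(1 + 2) + 5*35 = 2360 s = 39.33 min.
    ``n_categories == 0`` degenerates to the breaks alone.
    """
    if n_categories < 0 or trials_per_category < 0:
        raise ValueError("counts must be nonnegative")
    n_trials = n_categories * trials_per_category
    if use_expected_isi:
        isi_total = n_trials * float(np.mean(timing.isi_values_s))
    else:
        isi_total = float(sample_isi(timing, n_trials, seed).sum())
    return (n_categories * timing.probe_duration_s
            + n_trials * timing.stimulus_duration_s
            + isi_total
            + timing.n_breaks * timing.break_duration_s)


# ---------------------------------------------------------------------------
# Evoked templates
# ---------------------------------------------------------------------------

#: (latency_ms, width_ms, relative amplitude) of the common evoked deflections.
_COMMON_COMPONENTS: tuple[tuple[float, float, float], ...] = (
    (90.0, 18.0, -1.0),    # early posterior negativity
    (140.0, 22.0, 1.2),    # P1/P2-like positivity
    (250.0, 35.0, 0.8),    # P3a-like
    (300.0, 40.0, 0.9),    # P3b-like
)


def _channel_profile(cfg: SimulationConfig) -> np.ndarray:
    """Per-channel gain of the common evoked response (posterior-dominant)."""
    gains = np.full(cfg.n_channels, 0.4)
    for i, name in enumerate(cfg.channel_names):
        if name.startswith(("O", "PO", "P")):
            gains[i] = 1.0
        elif name.startswith(("CP", "C", "T")):
            gains[i] = 0.7
    return gains


def common_template(cfg: SimulationConfig) -> np.ndarray:
    """Common evoked template, shape (n_channels, n_times); zero pre-stimulus."""
    t = cfg.times_ms()
    wave = np.zeros_like(t)
    for mu, sigma, amp in _COMMON_COMPONENTS:
        wave += amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2)
    wave[t < 0] = 0.0
    return cfg.common_erp_amplitude * np.outer(_channel_profile(cfg), wave)


def effect_template(cfg: SimulationConfig) -> np.ndarray:
    """Animate-minus-inanimate component, confined to the effect channels/window.

    Hann-windowed in time so the component vanishes exactly at (and outside)
    the window edges.
    """
    t = cfg.times_ms()
    lo, hi = cfg.effect_window_ms
    inside = (t >= lo) & (t <= hi)
    wave = np.zeros_like(t)
    span = hi - lo
    wave[inside] = np.sin(np.pi * (t[inside] - lo) / span) ** 2
    out = np.zeros((cfg.n_channels, cfg.n_times))
    ch_index = [cfg.channel_names.index(c) for c in cfg.effect_channels]
    out[ch_index] = cfg.effect_amplitude * wave
    return out


def _shift_template(template: np.ndarray, shift_samples: int) -> np.ndarray:
    """Shift along time, padding with zeros (positive shift = later latency)."""
    if shift_samples == 0:
        return template
    out = np.zeros_like(template)
    if shift_samples > 0:
        out[:, shift_samples:] = template[:, :-shift_samples]
    else:
        out[:, :shift_samples] = template[:, -shift_samples:]
    return out


def generate_dataset(cfg: SimulationConfig | None = None) -> EpochedEEG:
    """Generate a full epoched dataset; bitwise-reproducible from ``cfg.rng_seed``.

    Per subject, ``trials_per_category`` trials of each category are laid out
    in randomized category blocks (category order and within-category content
    are random per subject).  Categories ``1..n_animate_categories`` are
    animate (+1), the rest inanimate (-1).
    """
    cfg = cfg or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)

    base = common_template(cfg)
    effect = effect_template(cfg)
    dt_ms = 1000.0 / cfg.sampling_rate_hz

    n_s, n_tr = cfg.n_subjects, cfg.n_trials
    data = np.empty((n_s, n_tr, cfg.n_channels, cfg.n_times))
    category_labels = np.empty((n_s, n_tr), dtype=int)

    for s in range(n_s):
        gain = rng.lognormal(mean=0.0, sigma=cfg.subject_amplitude_sd)
        jitter_ms = rng.uniform(-cfg.subject_latency_jitter_ms,
                                cfg.subject_latency_jitter_ms)
        shift = int(round(jitter_ms / dt_ms))
        subj_base = gain * _shift_template(base, shift)
        subj_effect = gain * _shift_template(effect, shift)

        order = rng.permutation(cfg.n_categories) + 1  # randomized block order
        cats = np.repeat(order, cfg.trials_per_category)
        category_labels[s] = cats
        animate = cats <= cfg.n_animate_categories

        noise = rng.normal(0.0, cfg.noise_sd,
                           size=(n_tr, cfg.n_channels, cfg.n_times))
        if cfg.ar1_coefficient != 0.0:
            phi = cfg.ar1_coefficient
            # AR(1) along time with stationary marginal variance noise_sd**2
            for k in range(1, cfg.n_times):
                noise[:, :, k] = (phi * noise[:, :, k - 1]
                                  + np.sqrt(1 - phi ** 2) * noise[:, :, k])

        data[s] = subj_base[None] + noise
        data[s, animate] += subj_effect[None]

    animacy = np.where(category_labels <= cfg.n_animate_categories, 1, -1)
    return EpochedEEG(
        data=data,
        subject_ids=[f"S{s + 1:02d}" for s in range(n_s)],
        category_labels=category_labels,
        animacy_labels=animacy,
        channel_names=list(cfg.channel_names),
        times_ms=cfg.times_ms(),
        sampling_rate_hz=cfg.sampling_rate_hz,
    )
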