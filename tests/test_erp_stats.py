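import numpy as np
import pytest

from eegdecode import (EpochedEEG, SimulationConfig, compute_erps,
                       erp_difference_map, generate_dataset, paired_ttest_map)
from eegdecode.core_data import default_times_ms


def tiny_dataset(subject_blocks, animacy_per_trial, n_ch=2, n_t=3):
    """Hand-built dataset: subject_blocks[s][trial] is a (ch, t) array."""
    data = np.asarray(subject_blocks, dtype=float)
    n_s, n_tr = data.shape[:2]
    animacy = np.tile(animacy_per_trial, (n_s, 1))
    category = np.where(animacy == 1, 1, 2)
    return EpochedEEG(
        data=data,
        subject_ids=[f"s{i}" for i in range(n_s)],
        category_labels=category,
        animacy_labels=animacy,
        channel_names=[f"c{i}" for i in range(n_ch)],
        times_ms=default_times_ms(n_t),
        sampling_rate_hz=100.0,
    )


class TestComputeErps:
    def test_identical_animate_trials_reproduced_exactly(self):
        a = np.full((2, 3), 2.5)
        b = np.zeros((2, 3))
        d = tiny_dataset([[a, a, b, b]] * 4, [1, 1, -1, -1])
        erps = compute_erps(d)
        np.testing.assert_array_equal(erps.grand_animate, a)
        np.testing.assert_array_equal(erps.grand_inanimate, b)
        for s in range(4):
            np.testing.assert_array_equal(erps.subject_means[s, 0], a)

    def test_grand_average_weights_subjects_equally(self, small_dataset):
        erps = compute_erps(small_dataset)
        np.testing.assert_allclose(
            erps.grand_animate, erps.subject_means[:, 0].mean(axis=0),
            atol=1e-12)

    def test_linearity_in_data_scale(self, small_dataset):
        scaled = small_dataset.copy()
        scaled.data = 2.0 * scaled.data
        base = compute_erps(small_dataset)
        double = compute_erps(scaled)
        np.testing.assert_allclose(double.grand_animate,
                                   2.0 * base.grand_animate, atol=1e-12)

    def test_missing_class_raises(self):
        a = np.ones((2, 3))
        d = tiny_dataset([[a, a, a]] * 3, [1, 1, 1])
        with pytest.raises(ValueError, match="inanimate"):
            compute_erps(d)


class TestDifferenceMap:
    def test_identical_class_means_give_zero_map(self):
        a = np.ones((2, 3))
        d = tiny_dataset([[a, a]] * 3, [1, -1])
        dm = erp_difference_map(compute_erps(d))
        np.testing.assert_array_equal(dm.values, 0.0)

    def test_swapping_labels_negates_map(self, small_dataset):
        flipped = small_dataset.copy()
        flipped.animacy_labels = -flipped.animacy_labels
        base = erp_difference_map(compute_erps(small_dataset))
        neg = erp_difference_map(compute_erps(flipped))
        np.testing.assert_allclose(neg.values, -base.values, atol=1e-12)

    def test_planted_effect_peaks_inside_effect_region(self):
        cfg = SimulationConfig(n_subjects=8, trials_per_category=10,
                               effect_amplitude=1.0, rng_seed=5)
        d = generate_dataset(cfg)
        dm = erp_difference_map(compute_erps(d))
        ch, t = np.unravel_index(np.argmax(np.abs(dm.values)), dm.values.shape)
        assert cfg.channel_names[ch] in cfg.effect_channels
        lo, hi = cfg.effect_window_ms
        assert lo <= dm.times_ms[t] <= hi


class TestPairedTTestMap:
    def test_zero_difference_gives_zero_t(self):
        a = np.ones((2, 3))
        d = tiny_dataset([[a, a]] * 5, [1, -1])
        res = paired_ttest_map(compute_erps(d))
        np.testing.assert_array_equal(res.t_map.values, 0.0)
        assert not res.significant.any()

    def test_hand_paired_t(self):
        """Differences (2, 0, 1, -1, 3) in one cell -> t = 1 / sqrt(2.5/5)."""
        diffs = [2.0, 0.0, 1.0, -1.0, 3.0]
        blocks = []
        for dval in diffs:
            animate = np.full((1, 1), dval)
            inanimate = np.zeros((1, 1))
            blocks.append([animate, inanimate])
        d = tiny_dataset(blocks, [1, -1], n_ch=1, n_t=1)
        res = paired_ttest_map(compute_erps(d))
        assert res.t_map.values[0, 0] == pytest.approx(1.4142, abs=1e-4)

    def test_zero_variance_nonzero_mean_is_significant_infinite_t(self):
        blocks = []
        for _ in range(5):
            blocks.append([np.full((1, 1), 1.0), np.zeros((1, 1))])
        d = tiny_dataset(blocks, [1, -1], n_ch=1, n_t=1)
        res = paired_ttest_map(compute_erps(d))
        assert np.isposinf(res.t_map.values[0, 0])
        assert res.significant[0, 0]

    def test_correction_scope_counts(self, small_dataset):
        full = paired_ttest_map(compute_erps(small_dataset),
                                correction_scope="time_by_channel")
        assert full.n_comparisons == 32 * 60
        trace = paired_ttest_map(compute_erps(small_dataset),
                                 correction_scope="time_only")
        assert trace.n_comparisons == 60
        assert trace.t_map.values.shape == (1, 60)

    def test_invariant_to_subject_specific_common_waveform(self, small_dataset):
        shifted = small_dataset.copy()
        rng = np.random.default_rng(0)
        for s in range(shifted.n_subjects):
            shifted.data[s] += rng.normal(size=(1,) + shifted.data.shape[2:])
        base = paired_ttest_map(compute_erps(small_dataset))
        moved = paired_ttest_map(compute_erps(shifted))
        np.testing.assert_allclose(moved.t_map.values, base.t_map.values,
                                   atol=1e-7)

    def test_too_few_subjects_raises(self):
        a = np.ones((2, 3))
        d = tiny_dataset([[a, a]] * 2, [1, -1])
        with pytest.raises(ValueError):
            paired_ttest_map(compute_erps(d))
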