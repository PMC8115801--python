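"""ERP feature extraction: filtering, baselining, peaks, block rows."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mindwander import (GeneratorConfig, FeatureSpec, bandpass_filter,
                        baseline_correct, block_features, cohort_features,
                        extract_peak, generate_subject, iter_cohort,
                        normalize_features, select_preprobe_trials,
                        session_features)
from mindwander.features import FEATURE_NAMES, _batch_peaks, preprocess_epoch
from mindwander.simulate import Block, STANDARD, TARGET, ON_TASK

from conftest import make_epoch


class TestBandpassFilter:
    def test_zero_phase_preserves_pulse_latency(self):
        times = -1000 + np.arange(1536) / 512 * 1000
        pulse = np.exp(-0.5 * ((times - 400) / 50) ** 2)
        ep = make_epoch(pulse[None, :])
        out = bandpass_filter(ep, (1.0, 15.0))
        assert abs(np.argmax(out.data[0]) - np.argmax(pulse)) <= 1

    def test_30hz_sinusoid_attenuated_20db(self):
        times_s = np.arange(1536) / 512
        sine = np.sin(2 * np.pi * 30 * times_s)
        ep = make_epoch(sine[None, :])
        out = bandpass_filter(ep, (1.0, 15.0))
        # steady-state response: central half, clear of edge transients
        c = slice(384, 1152)
        rms_in = np.sqrt((sine[c] ** 2).mean())
        rms_out = np.sqrt((out.data[0][c] ** 2).mean())
        assert 20 * np.log10(rms_in / rms_out) >= 20.0

    def test_dc_offset_removed(self):
        ep = make_epoch(np.full((2, 1536), 3.0))
        out = bandpass_filter(ep, (1.0, 15.0))
        assert np.sqrt((out.data**2).mean()) < 3.0 / 100  # >= 40 dB down

    def test_band_outside_nyquist_rejected(self):
        ep = make_epoch(np.zeros((1, 1536)))
        with pytest.raises(ValueError):
            bandpass_filter(ep, (1.0, 300.0))
        with pytest.raises(ValueError):
            bandpass_filter(ep, (15.0, 1.0))


class TestBaselineCorrect:
    def test_constant_channel_becomes_zero(self):
        ep = make_epoch(np.full((1, 1536), 3.0))
        out = baseline_correct(ep, (-200.0, 0.0))
        assert np.allclose(out.data, 0.0)

    def test_every_sample_shifted_by_baseline_mean(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(3, 1536))
        ep = make_epoch(data)
        out = baseline_correct(ep, (-200.0, 0.0))
        mask = (ep.times_ms >= -200) & (ep.times_ms <= 0)
        shift = data[:, mask].mean(axis=1, keepdims=True)
        assert np.allclose(out.data, data - shift)
        assert np.abs(out.data[:, mask].mean(axis=1)).max() < 1e-10

    def test_window_outside_epoch_rejected(self):
        ep = make_epoch(np.zeros((1, 1536)))
        with pytest.raises(ValueError):
            baseline_correct(ep, (-2000.0, -1500.0))


class TestExtractPeak:
    def test_all_zero_epoch_gives_zero(self):
        ep = make_epoch(np.zeros((3, 1536)), channels=["FC1", "FCz", "FC2"])
        assert extract_peak(ep, ("FC1", "FCz"), (80.0, 120.0), -1) == 0.0

    def test_single_channel_bump_minimum(self):
        times = -1000 + np.arange(1536) / 512 * 1000
        bump = -5.0 * np.exp(-0.5 * ((times - 100) / 20) ** 2)
        ep = make_epoch(bump[None, :], channels=["FCz"])
        assert extract_peak(ep, ("FCz",), (80.0, 120.0), -1) == pytest.approx(
            -5.0, abs=0.01)  # sample grid does not hit 100 ms exactly

    def test_channel_average_before_peak(self):
        data = np.vstack([np.full(1536, 2.0), np.full(1536, 4.0)])
        ep = make_epoch(data, channels=["P1", "Pz"])
        assert extract_peak(ep, ("P1", "Pz"), (400.0, 600.0), +1) == pytest.approx(3.0)

    def test_missing_channel_raises(self):
        ep = make_epoch(np.zeros((1, 1536)), channels=["FCz"])
        with pytest.raises(KeyError):
            extract_peak(ep, ("Oz",), (80.0, 120.0), -1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(3, 256))
        ep = make_epoch(data, fs=512.0, t0=-100.0, channels=["a", "b", "c"])
        lo = float(rng.uniform(-90, 100))
        hi = lo + float(rng.uniform(10, 200))
        pol = -1 if rng.random() < 0.5 else 1
        got = extract_peak(ep, ("a", "c"), (lo, hi), pol)
        virtual = (data[0] + data[2]) / 2
        mask = (ep.times_ms >= lo) & (ep.times_ms <= hi)
        expected = virtual[mask].min() if pol < 0 else virtual[mask].max()
        assert got == expected


class TestSelectPreprobe:
    def _block(self, n, artifact_indices=()):
        trials = []
        for i in range(n):
            ep = make_epoch(np.zeros((1, 16)), artifact=i in artifact_indices)
            ep.trial_index = i
            trials.append(ep)
        return Block(trials, ON_TASK, 60.0)

    def test_last_ten_clean_trials(self):
        block = self._block(40)
        got = select_preprobe_trials(block, 10)
        assert [t.trial_index for t in got] == list(range(30, 40))

    def test_artifacts_skipped_counting_backwards(self):
        block = self._block(40, artifact_indices={37, 38, 39})
        got = select_preprobe_trials(block, 10)
        assert [t.trial_index for t in got] == list(range(27, 37))

    def test_fewer_than_ten_returns_all(self):
        block = self._block(6)
        assert len(select_preprobe_trials(block, 10)) == 6


class TestBlockFeatures:
    def test_batch_peaks_match_per_epoch_pipeline(self, noiseless_config):
        cfg = noiseless_config
        rng = np.random.default_rng(5)
        session = generate_subject(cfg.short_blocks(), "s", rng)
        spec = FeatureSpec()
        trials = select_preprobe_trials(session.blocks[0], 10)
        n1_batch, p3_batch = _batch_peaks(trials, spec)
        for i, trial in enumerate(trials):
            pre = preprocess_epoch(trial, spec)
            assert extract_peak(pre, spec.n1.channels, spec.n1.window_ms,
                                -1) == pytest.approx(n1_batch[i], abs=1e-10)
            assert extract_peak(pre, spec.p3.channels, spec.p3.window_ms,
                                +1) == pytest.approx(p3_batch[i], abs=1e-10)

    def test_identical_trials_give_zero_sd(self, noiseless_config):
        rng = np.random.default_rng(5)
        session = generate_subject(noiseless_config.short_blocks(), "s", rng)
        row = block_features(session.blocks[0], FeatureSpec(), "s", 0)
        assert row["n1_sd"] == pytest.approx(0.0, abs=1e-9)
        assert row["p3_sd"] == pytest.approx(0.0, abs=1e-9)

    def test_sample_sd_convention(self):
        # peaks {1, 2, 3} must give sd exactly 1 under the n-1 convention
        peaks = np.array([1.0, 2.0, 3.0])
        assert peaks.std(ddof=1) == pytest.approx(1.0)
        # and the feature row uses that convention on real per-trial peaks
        cfg = GeneratorConfig(noise_white_sd_uv=0.5, noise_pink_scale_uv=0.0,
                              trial_amplitude_jitter=0.0, subject_gain_sd=0.0,
                              artifact_probability=0.0, seed=2).short_blocks()
        session = generate_subject(cfg, "s", np.random.default_rng(2))
        spec = FeatureSpec()
        block = session.blocks[0]
        row = block_features(block, spec, "s", 0)
        selected = [t for t in select_preprobe_trials(block, 10)
                    if t.tone_type == STANDARD]
        n1, p3 = _batch_peaks(selected, spec)
        assert row["n1_sd"] == pytest.approx(n1.std(ddof=1))
        assert row["n1_mean"] == pytest.approx(n1.mean())

    def test_standard_only_counting(self, noiseless_config):
        rng = np.random.default_rng(8)
        session = generate_subject(noiseless_config, "s", rng)
        for b_idx, block in enumerate(session.blocks):
            row = block_features(block, FeatureSpec(), "s", b_idx)
            n_std = sum(1 for t in select_preprobe_trials(block, 10)
                        if t.tone_type == STANDARD)
            assert row["n_trials_used"] == n_std

    def test_too_few_trials_drops_block(self, noiseless_config):
        rng = np.random.default_rng(8)
        session = generate_subject(noiseless_config.short_blocks(), "s", rng)
        block = session.blocks[0]
        for trial in block.trials:
            trial.artifact = True
        assert block_features(block, FeatureSpec(), "s", 0) is None


class TestNormalize:
    def _table(self, on_task_vals, mw_vals):
        rows = []
        for i, v in enumerate(on_task_vals):
            rows.append({"subject_id": "s1", "block": i, "label": 0,
                         "n1_mean": v, "n1_sd": 0.0, "p3_mean": 0.0,
                         "p3_sd": 0.0, "n_trials_used": 10, "normalized": 0})
        for j, v in enumerate(mw_vals):
            rows.append({"subject_id": "s1", "block": len(on_task_vals) + j,
                         "label": 1, "n1_mean": v, "n1_sd": 0.0,
                         "p3_mean": 0.0, "p3_sd": 0.0, "n_trials_used": 10,
                         "normalized": 0})
        return pd.DataFrame(rows)

    def test_hand_computed_centering(self):
        out = normalize_features(self._table([1.0, 3.0], [4.0]))
        assert out["n1_mean"].tolist() == [-1.0, 1.0, 2.0]

    def test_identical_rows_become_zero(self):
        out = normalize_features(self._table([2.0, 2.0], [2.0]))
        assert (out[list(FEATURE_NAMES)] == 0).all().all()

    def test_on_task_mean_is_zero_after(self):
        rng = np.random.default_rng(3)
        table = self._table(rng.normal(size=8), rng.normal(size=10))
        out = normalize_features(table)
        on_task = out[out["label"] == 0]
        assert abs(on_task["n1_mean"].mean()) < 1e-12

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        table = self._table(rng.normal(size=8), rng.normal(size=10))
        once = normalize_features(table)
        twice = normalize_features(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_subject_without_on_task_blocks_rejected(self):
        table = self._table([], [1.0, 2.0])
        with pytest.raises(ValueError, match="s1"):
            normalize_features(table)


class TestEndToEnd:
    def test_noiseless_amplitude_recovery_within_filter_ripple(self, noiseless_config):
        import dataclasses
        table = cohort_features(iter_cohort(
            dataclasses.replace(noiseless_config, n_subjects=2)))
        assert abs(table["n1_mean"].mean() - (-5.0)) < 0.02 * 5.0
        assert abs(table["p3_mean"].mean() - 6.0) < 0.02 * 6.0
        assert table["n1_sd"].max() < 1e-6

    def test_artifact_free_default_yields_25_rows_per_subject(self, noiseless_config):
        session = generate_subject(noiseless_config.short_blocks(), "s",
                                   np.random.default_rng(1))
        table = session_features(session)
        assert len(table) == 25
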