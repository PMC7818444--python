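"""EEG cleaning chain: resampling, robust PCA, ocular regression, rejection."""

import numpy as np
import pytest

from srcflow.preprocess import (
    EEGRecording,
    build_ocular_regressors,
    default_frontal_sets,
    iterative_rejection,
    preprocess,
    regress_out,
    resample_and_highpass,
    robust_pca,
)


def _recording(data, rate=500.0):
    return EEGRecording(data=np.asarray(data, dtype=float), rate=rate)


class TestResampleAndHighpass:
    def test_output_length_and_rate(self):
        rec = _recording(np.random.default_rng(0).standard_normal((4, 5000)))
        out = resample_and_highpass(rec, 30.0, 1.0)
        assert out.rate == 30.0
        assert out.data.shape == (4, 300)

    def test_dc_offset_removed(self):
        """A pure 13 uV offset is suppressed by ~6 orders of magnitude."""
        rec = _recording(np.full((2, 5000), 13.0))
        out = resample_and_highpass(rec, 30.0, 1.0)
        interior = out.data[:, 30:-30]  # skip 1 s edges
        assert np.abs(interior).max() < 1e-4

    def test_passband_sinusoid_preserved(self):
        """A 5 Hz unit sinusoid survives 500 -> 30 Hz with ~unit amplitude."""
        t = np.arange(10_000) / 500.0
        rec = _recording(np.sin(2 * np.pi * 5.0 * t)[None, :])
        out = resample_and_highpass(rec, 30.0, 1.0)
        interior = out.data[0, 30:-30]
        amp = np.sqrt(2.0 * np.mean(interior**2))
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_upsampling_rejected(self):
        rec = _recording(np.zeros((2, 100)), rate=30.0)
        with pytest.raises(ValueError):
            resample_and_highpass(rec, 500.0, 1.0)


class TestRobustPCA:
    def test_clean_low_rank_gives_tiny_sparse(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((30, 2)) @ rng.standard_normal((2, 400))
        low, sparse = robust_pca(data, lam=1.0)
        assert np.linalg.norm(sparse) / np.linalg.norm(data) < 1e-4

    def test_spike_recovery(self):
        """Planted rank-3 + 1% +/-50 spikes: low-rank part recovered."""
        rng = np.random.default_rng(1)
        l0 = rng.standard_normal((48, 3)) @ rng.standard_normal((3, 600))
        s0 = np.zeros_like(l0)
        idx = rng.random(l0.shape) < 0.01
        s0[idx] = 50.0 * rng.choice([-1.0, 1.0], idx.sum())
        low, _ = robust_pca(l0 + s0, lam=1.0, scaling="max-dim")
        assert np.linalg.norm(low - l0) / np.linalg.norm(l0) < 1e-3

    def test_additivity(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((20, 100))
        low, sparse = robust_pca(data)
        assert np.allclose(low + sparse, data, atol=1e-6 * np.abs(data).max())
        assert np.linalg.matrix_rank(low) <= min(data.shape)

    def test_nonfinite_rejected(self):
        data = np.ones((4, 4))
        data[0, 0] = np.nan
        with pytest.raises(ValueError):
            robust_pca(data)


class TestOcularRegression:
    def test_signed_sums(self):
        data = np.arange(80.0).reshape(8, 10)
        rec = _recording(data, rate=30.0)
        regs = build_ocular_regressors(
            rec, [[(0, +1), (1, +1)], [(0, +1), (1, -1)],
                  [(2, +1), (3, +1)], [(4, +1), (5, -1)]])
        assert np.allclose(regs.signals[0], data[0] + data[1])
        assert np.allclose(regs.signals[1], data[0] - data[1])

    def test_invalid_channel_rejected(self):
        rec = _recording(np.zeros((8, 10)), rate=30.0)
        rec.valid_channels[1] = False
        with pytest.raises(ValueError):
            build_ocular_regressors(rec, [[(1, +1)]] * 4)

    def test_blink_regressor_captures_injected_blink(self):
        """Frontal virtual electrodes track the planted blink time course."""
        from srcflow.synth import generate_ground_truth, generate_eeg, \
            generate_stimulus

        truth = generate_ground_truth(n_channels=16, n_components=1, seed=0,
                                      noise_sd=0.5, artifact_rate=0.0,
                                      condition_gains={"c": 1.0},
                                      alpha_amplitude={"c": 0.0})
        raw = generate_stimulus(60.0, seed=1)
        eeg = generate_eeg(raw, truth, "c", seed=2, ocular_amplitude=30.0,
                           blink_rate_per_min=20.0)
        eeg_clean = generate_eeg(raw, truth, "c", seed=2, ocular_amplitude=0.0)
        blink = eeg.data[0] - eeg_clean.data[0]  # injected frontal time course
        regs = build_ocular_regressors(eeg)
        best = max(abs(np.corrcoef(r, blink)[0, 1]) for r in regs.signals)
        assert best > 0.9

    def test_projection_removes_matching_channel(self):
        rng = np.random.default_rng(0)
        reg_sig = rng.standard_normal((4, 200))
        data = np.vstack([reg_sig[0], rng.standard_normal(200)])
        rec = _recording(data, rate=30.0)
        from srcflow.preprocess import OcularRegressors

        regs = OcularRegressors(signals=reg_sig,
                                construction=[[(0, 1)]] * 4)
        out = regress_out(rec, regs)
        assert np.abs(out.data[0]).max() < 1e-9

    def test_orthogonal_channel_unchanged_and_idempotent(self):
        rng = np.random.default_rng(3)
        reg_sig = rng.standard_normal((4, 500))
        target = rng.standard_normal(500)
        # orthogonalize target against regressors and the intercept
        q, _ = np.linalg.qr(np.column_stack([np.ones(500), reg_sig.T]))
        target -= q @ (q.T @ target)
        rec = _recording(target[None, :], rate=30.0)
        from srcflow.preprocess import OcularRegressors

        regs = OcularRegressors(signals=reg_sig,
                                construction=[[(0, 1)]] * 4)
        once = regress_out(rec, regs)
        assert np.allclose(once.data[0], target, atol=1e-9)
        twice = regress_out(once, regs)
        assert np.allclose(twice.data, once.data, atol=1e-9)

    def test_mixture_residual_decorrelated(self):
        """channel = clean + 0.7 * blink -> residual nearly blink-free."""
        rng = np.random.default_rng(4)
        blink = rng.standard_normal(1000)
        clean = rng.standard_normal(1000)
        data = np.vstack([blink, (clean + 0.7 * blink)])
        rec = _recording(data, rate=30.0)
        from srcflow.preprocess import OcularRegressors

        regs = OcularRegressors(
            signals=np.vstack([blink, rng.standard_normal((3, 1000))]),
            construction=[[(0, 1)]] * 4)
        out = regress_out(rec, regs)
        assert abs(np.corrcoef(out.data[1], blink)[0, 1]) < 0.05


class TestIterativeRejection:
    def test_homogeneous_gaussian_keeps_all_channels(self):
        rng = np.random.default_rng(0)
        rec = _recording(rng.standard_normal((32, 3000)), rate=30.0)
        out = iterative_rejection(rec, n_sd=4.0, n_iter=3)
        assert out.valid_channels.all()

    def test_loud_channel_rejected_first_iteration(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((64, 2000))
        data[5] *= 10.0
        out = iterative_rejection(_recording(data, rate=30.0), n_iter=1)
        assert not out.valid_channels[5]
        assert out.valid_channels.sum() == 63

    def test_spike_and_neighbors_masked(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((4, 2000))
        data[2, 1000] = 500.0
        out = iterative_rejection(_recording(data, rate=30.0))
        assert not out.valid_samples[2, 999:1002].any()
        assert out.data[2, 999:1002].sum() == 0.0

    def test_masks_monotone(self):
        """Entries never flip back to valid across iterations."""
        rng = np.random.default_rng(3)
        data = rng.standard_normal((8, 1000))
        data[1, ::100] = 50.0
        rec = _recording(data, rate=30.0)
        prev = np.ones_like(rec.valid_samples)
        for n in (1, 2, 3):
            out = iterative_rejection(rec, n_iter=n)
            assert np.all(out.valid_samples <= prev)
            prev = out.valid_samples

    def test_all_rejected_raises(self):
        rec = _recording(np.zeros((2, 50)), rate=30.0)
        rec.valid_channels[:] = False
        with pytest.raises(ValueError):
            iterative_rejection(rec)


class TestTriggerIntervals:
    def test_aligned_recordings_pass(self):
        from srcflow.preprocess import check_trigger_intervals

        t = np.arange(0.0, 10.0, 0.5)
        ok, diff = check_trigger_intervals(t, t + 0.002)
        assert ok and diff < 1e-9  # constant offset cancels in intervals

    def test_misaligned_recordings_flagged(self):
        from srcflow.preprocess import check_trigger_intervals

        rng = np.random.default_rng(0)
        t = np.arange(0.0, 10.0, 0.5)
        drifted = t + np.cumsum(rng.uniform(0.0, 0.3, t.size))
        ok, diff = check_trigger_intervals(t, drifted)
        assert not ok and diff > 0.05

    def test_mismatched_lengths_rejected(self):
        from srcflow.preprocess import check_trigger_intervals

        with pytest.raises(ValueError):
            check_trigger_intervals(np.arange(3.0), np.arange(4.0))


class TestFullPreprocess:
    def test_clean_data_nearly_preserved(self):
        """Artifact-free data passes through with per-channel corr > 0.95."""
        from srcflow.synth import generate_ground_truth, generate_eeg, \
            generate_stimulus

        truth = generate_ground_truth(n_channels=16, n_components=2, seed=0,
                                      noise_sd=1.0, artifact_rate=0.0,
                                      condition_gains={"c": 1.0},
                                      alpha_amplitude={"c": 0.0})
        raw_stim = generate_stimulus(40.0, fs=500.0, seed=1, cutoff_hz=3.0)
        raw_eeg = generate_eeg(raw_stim, truth, "c", seed=2, fs=500.0)
        reference = resample_and_highpass(raw_eeg, 30.0, 1.0)
        cleaned = preprocess(raw_eeg, run_ocular=False)
        valid = np.flatnonzero(cleaned.valid_channels)
        assert valid.size >= 14  # at most a couple of false rejections
        sl = slice(30, -30)
        for c in valid:
            assert np.corrcoef(reference.data[c, sl],
                               cleaned.data[c, sl])[0, 1] > 0.95

    def test_preprocessing_raises_src_under_artifacts(self):
        """The artifact cocktail hurts SRC; cleaning recovers part of it."""
        from srcflow.model import StimulusResponseCCA
        from srcflow.synth import generate_ground_truth, generate_eeg, \
            generate_stimulus
        from srcflow.video import StimulusFeature

        truth = generate_ground_truth(n_channels=16, n_components=1, seed=5,
                                      noise_sd=1.0, artifact_rate=30.0,
                                      condition_gains={"c": 1.0},
                                      alpha_amplitude={"c": 1.0})
        raw_stim = generate_stimulus(120.0, fs=500.0, seed=6, cutoff_hz=3.0)
        raw_eeg = generate_eeg(raw_stim, truth, "c", seed=7, fs=500.0,
                               ocular_amplitude=40.0, blink_rate_per_min=15.0,
                               artifact_amplitude=200.0)
        from scipy.signal import resample_poly

        s30 = resample_poly(raw_stim, 3, 50)
        s30 = (s30 - s30.mean()) / s30.std()
        feat = StimulusFeature(values=s30, rate=30.0)

        naive = resample_and_highpass(raw_eeg, 30.0, 1.0)
        clean = preprocess(raw_eeg)
        n = min(feat.values.size, naive.n_samples, clean.n_samples)
        feat.values = feat.values[:n]
        naive.data = naive.data[:, :n]
        naive.valid_samples = naive.valid_samples[:, :n]
        clean.data = clean.data[:, :n]
        clean.valid_samples = clean.valid_samples[:, :n]
        src_naive = StimulusResponseCCA(feat, naive, n_lags=30,
                                        n_components=5).fit().total_src
        src_clean = StimulusResponseCCA(feat, clean, n_lags=30,
                                        n_components=5).fit().total_src
        assert src_clean > src_naive
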