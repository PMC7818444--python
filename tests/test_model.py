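"""Temporally embedded CCA: embedding, oracle equivalence, projections."""

import numpy as np
import pytest
import scipy.linalg

from srcflow.model import (
    SRCResult,
    StimulusResponseCCA,
    fit_cca,
    pool_and_fit,
    project,
    temporal_embed,
    total_src,
)
from srcflow.preprocess import EEGRecording
from srcflow.video import StimulusFeature

from conftest import make_session


class TestTemporalEmbed:
    def test_zero_padded_construction(self):
        out = temporal_embed(np.array([1.0, 2.0, 3.0]), 2)
        assert np.array_equal(out, [[1, 0], [2, 1], [3, 2]])

    def test_single_lag_is_identity(self):
        s = np.arange(5.0)
        assert np.array_equal(temporal_embed(s, 1).ravel(), s)

    def test_filter_application_is_convolution(self):
        """Embedded s times [1, -1] equals the (zero-padded) first difference."""
        rng = np.random.default_rng(0)
        s = rng.standard_normal(50)
        diff = temporal_embed(s, 2) @ np.array([1.0, -1.0])
        expected = np.concatenate([[s[0]], np.diff(s)])
        assert np.allclose(diff, expected)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            temporal_embed(np.ones(3), 5)


def brute_force_cca(s_emb, data, k):
    """Generalized-eigenproblem CCA oracle (no masks, plain covariance)."""
    sc = s_emb - s_emb.mean(axis=0)
    rc = (data - data.mean(axis=1, keepdims=True)).T
    T = sc.shape[0]
    css = sc.T @ sc / T
    crr = rc.T @ rc / T
    csr = sc.T @ rc / T
    vals, vecs = np.linalg.eigh(crr)
    order = np.argsort(vals)[::-1][:k]
    basis = vecs[:, order]
    crr_p = basis.T @ crr @ basis
    csr_p = csr @ basis
    m = csr_p @ np.linalg.solve(crr_p, csr_p.T)
    eigvals = scipy.linalg.eigvals(np.linalg.solve(css, m))
    rho2 = np.sort(np.real(eigvals))[::-1]
    return np.sqrt(np.clip(rho2, 0.0, 1.0))


class TestFitCCAOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_generalized_eigenproblem(self, seed):
        """Canonical correlations equal the brute-force solve to 1e-8."""
        rng = np.random.default_rng(seed)
        d = rng.integers(4, 9)
        L = rng.integers(2, 5)
        k = int(min(L, d))
        s = rng.standard_normal(500)
        s_emb = temporal_embed(s, L)
        data = rng.standard_normal((d, 500))
        eeg = EEGRecording(data=data, rate=30.0)
        res = fit_cca(s_emb, eeg, k_components=k)
        oracle = brute_force_cca(s_emb, data, k)
        assert np.allclose(res.rho, oracle[: res.rho.size], atol=1e-8)

    def test_component_invariants(self):
        """rho non-increasing; corr(u_j, v_j) = rho_j; u_j decorrelated."""
        rng = np.random.default_rng(3)
        s = rng.standard_normal(800)
        data = rng.standard_normal((6, 800))
        data[0] += 0.5 * np.concatenate([[0, 0], s[:-2]])
        res = fit_cca(temporal_embed(s, 4), EEGRecording(data=data, rate=30.0),
                      k_components=4)
        assert np.all(np.diff(res.rho) <= 1e-12)
        for j in range(res.k_components):
            assert np.corrcoef(res.u[:, j], res.v[:, j])[0, 1] == \
                pytest.approx(res.rho[j], abs=1e-6)
        cu = np.corrcoef(res.u.T)
        assert np.abs(cu - np.eye(res.k_components)).max() < 1e-6

    @pytest.mark.parametrize("c_stim,c_chan", [(3.0, 1.0), (1.0, 0.25),
                                               (10.0, 5.0)])
    def test_scale_invariance(self, c_stim, c_chan):
        """rho is invariant to positive rescaling of stimulus or channels
        (untruncated CCA; the eigenvalue truncation is itself scale-aware)."""
        rng = np.random.default_rng(1)
        s = rng.standard_normal(400)
        data = rng.standard_normal((5, 400))
        base = fit_cca(temporal_embed(s, 6),
                       EEGRecording(data=data, rate=30.0), k_components=5)
        scaled_data = data.copy()
        scaled_data[2] *= c_chan
        scaled = fit_cca(temporal_embed(c_stim * s, 6),
                         EEGRecording(data=scaled_data, rate=30.0),
                         k_components=5)
        assert np.allclose(base.rho, scaled.rho, atol=1e-9)

    def test_k_exceeding_dims_rejected(self):
        rng = np.random.default_rng(2)
        eeg = EEGRecording(data=rng.standard_normal((3, 100)), rate=30.0)
        with pytest.raises(ValueError):
            fit_cca(temporal_embed(rng.standard_normal(100), 2), eeg,
                    k_components=5)

    def test_sign_convention(self):
        """Each temporal filter's largest-magnitude coefficient is positive."""
        stim, eeg, _ = make_session(n_channels=12, n_components=2,
                                    duration_s=60.0, noise_sd=1.0, seed=8)
        res = StimulusResponseCCA(stim, eeg, n_lags=20, n_components=6).fit()
        for h in res.temporal_filters:
            assert h[np.argmax(np.abs(h))] > 0


class TestTotalSRC:
    def test_sum(self):
        assert total_src(np.array([0.3, 0.2, 0.1])).total_src == \
            pytest.approx(0.6)

    def test_single_component(self):
        assert total_src(np.array([0.42])).total_src == pytest.approx(0.42)

    def test_exact_sum_of_components(self):
        res = SRCResult(per_component=np.array([0.25, 0.15, 0.05]))
        assert res.total_src == float(res.per_component.sum())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            total_src(np.array([]))


class TestProject:
    def test_training_projection_reproduces_rho(self):
        stim, eeg, _ = make_session(n_channels=10, n_components=2,
                                    duration_s=60.0, noise_sd=1.0, seed=4)
        res = StimulusResponseCCA(stim, eeg, n_lags=15, n_components=5).fit()
        proj = project(res, stim, eeg)
        assert np.allclose(proj.per_component, res.rho, atol=1e-9)

    def test_channel_mismatch_rejected(self):
        stim, eeg, _ = make_session(n_channels=10, duration_s=40.0, seed=4)
        res = StimulusResponseCCA(stim, eeg, n_lags=10, n_components=3).fit()
        other = EEGRecording(data=np.zeros((8, eeg.n_samples)), rate=30.0)
        with pytest.raises(ValueError):
            res.project(stim, other)

    def test_gain_raises_projected_src(self):
        """Condition with gain 1.25 projects to higher total SRC than 1.0."""
        wins = 0
        for seed in range(5):
            stim, eeg_hi, truth = make_session(
                n_channels=16, n_components=2, duration_s=120.0,
                noise_sd=3.2, gain=1.25, seed=100 + seed)
            _, eeg_lo, _ = make_session(
                n_channels=16, n_components=2, duration_s=120.0,
                noise_sd=3.2, gain=1.0, seed=100 + seed)
            res = StimulusResponseCCA([stim, stim], [eeg_hi, eeg_lo],
                                      n_lags=30, n_components=11).fit()
            hi = res.project(stim, eeg_hi).total_src
            lo = res.project(stim, eeg_lo).total_src
            wins += hi > lo
        assert wins >= 4

    def test_shuffled_eeg_within_null(self):
        """Stimulus-independent EEG projects within the circular-shift null."""
        rng = np.random.default_rng(11)
        stim, eeg, _ = make_session(n_channels=12, n_components=1,
                                    duration_s=120.0, noise_sd=1.0, seed=12)
        res = StimulusResponseCCA(stim, eeg, n_lags=20, n_components=5).fit()
        # destroy the stimulus-EEG pairing by a large circular shift
        shifted = EEGRecording(data=np.roll(eeg.data, eeg.n_samples // 2,
                                            axis=1), rate=30.0)
        obs = res.project(stim, shifted).total_src
        null = []
        for _ in range(50):
            k = rng.integers(300, eeg.n_samples - 300)
            null.append(res.project(
                stim, EEGRecording(data=np.roll(eeg.data, int(k), axis=1),
                                   rate=30.0)).total_src)
        assert obs < np.quantile(null, 0.99) + 0.05


class TestPoolAndFit:
    def test_duplicated_trial_preserves_filters(self):
        stim, eeg, _ = make_session(n_channels=8, duration_s=40.0,
                                    noise_sd=1.0, seed=6)

        class Sess:
            stimulus = [stim, stim]
            eeg_trials = [eeg, eeg]

        single = StimulusResponseCCA(stim, eeg, n_lags=10,
                                     n_components=4).fit()
        double = StimulusResponseCCA([stim, stim], [eeg, eeg], n_lags=10,
                                     n_components=4).fit()
        assert np.allclose(single.rho, double.rho, atol=1e-9)
        assert np.allclose(single.temporal_filters, double.temporal_filters,
                           atol=1e-7)

    def test_lag_rows_restart_at_trial_boundaries(self):
        s1 = np.arange(1.0, 41.0)
        s2 = np.arange(100.0, 140.0)
        model = StimulusResponseCCA(
            [StimulusFeature(values=s1, rate=30.0),
             StimulusFeature(values=s2, rate=30.0)],
            [EEGRecording(data=np.zeros((2, 40)) + np.arange(40), rate=30.0),
             EEGRecording(data=np.zeros((2, 40)) + np.arange(40), rate=30.0)],
            n_lags=3, n_components=2)
        # first row of the second trial must be zero-padded, not carry s1
        row = model.s_emb[40]
        assert np.array_equal(row, [100.0, 0.0, 0.0])

    def test_inconsistent_rates_rejected(self):
        stim, eeg, _ = make_session(n_channels=4, duration_s=20.0, seed=1)
        bad = EEGRecording(data=eeg.data, rate=60.0)
        with pytest.raises(ValueError):
            StimulusResponseCCA([stim, stim], [eeg, bad], n_lags=5,
                                n_components=2)

    def test_pooling_scopes(self):
        from srcflow.synth import generate_cohort

        sessions = generate_cohort(n_subjects=2, duration_s=20.0,
                                   n_channels=8, noise_sd=1.0, seed=9)
        per_subject = pool_and_fit(sessions, pooling="subject",
                                   n_lags=10, n_components=4)
        assert len(per_subject) == 2
        group = pool_and_fit(sessions, pooling="all", n_lags=10,
                             n_components=4)
        assert group.rho.size >= 1
        with pytest.raises(ValueError):
            pool_and_fit(sessions, pooling="nope")


def test_total_src_monotone_in_k():
    """On training projections, total SRC at K=11 >= total SRC at K=1."""
    stim, eeg, _ = make_session(n_channels=16, n_components=2,
                                duration_s=80.0, noise_sd=2.0, seed=13)
    lo = StimulusResponseCCA(stim, eeg, n_lags=20, n_components=1).fit()
    hi = StimulusResponseCCA(stim, eeg, n_lags=20, n_components=11).fit()
    assert hi.total_src >= lo.total_src - 1e-9


def test_summary_reports_key_quantities():
    stim, eeg, _ = make_session(n_channels=8, duration_s=30.0, seed=2)
    res = StimulusResponseCCA(stim, eeg, n_lags=10, n_components=3).fit()
    text = res.summary()
    assert "Total SRC" in text and "rho" in text
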