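"""Shared fixtures: small simulated sessions and helpers."""

from __future__ import annotations

import numpy as np
import pytest

from srcflow.synth import (
    GroundTruth,
    generate_eeg,
    generate_ground_truth,
    generate_stimulus,
)
from srcflow.video import StimulusFeature


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_session(
    n_channels: int = 16,
    n_components: int = 1,
    duration_s: float = 60.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    gain: float = 1.0,
    alpha: float = 0.0,
    **eeg_kwargs,
):
    """One (stimulus, eeg, truth) triple at the analysis rate."""
    truth = generate_ground_truth(
        n_channels=n_channels, n_components=n_components, n_lags=30,
        seed=seed + 1, noise_sd=noise_sd, artifact_rate=0.0,
        condition_gains={"c": gain}, alpha_amplitude={"c": alpha},
    )
    raw = generate_stimulus(duration_s, fs=30.0, seed=seed)
    eeg = generate_eeg(raw, truth, "c", seed=seed + 2, **eeg_kwargs)
    z = (raw - raw.mean()) / raw.std()
    stim = StimulusFeature(values=z, rate=30.0)
    return stim, eeg, truth


@pytest.fixture
def noiseless_session():
    return make_session()


@pytest.fixture
def noisy_session():
    return make_session(n_components=3, n_channels=32, noise_sd=2.0,
                        duration_s=120.0, seed=7)
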