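"""Synthetic stimuli and EEG with known ground truth.

The generative model mirrors the analysis model: a nonnegative, slowly varying
"flow-like" stimulus feature s(t) drives K neural components, each the causal
convolution of s(t) with a unit-norm temporal filter h_j, projected onto the
scalp through a spatial map a_j.  On top of the evoked part sit spatially
correlated 1/f background noise, a condition-dependent 10 Hz alpha oscillation
on central channels, sparse high-amplitude spike artifacts, and a blink-like
ocular component on frontal channels.  Every generator is deterministic given
its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .preprocess import EEGRecording
from .video import FrameSequence, StimulusFeature

__all__ = [
    "GroundTruth",
    "SimulatedSession",
    "generate_stimulus",
    "generate_ground_truth",
    "generate_eeg",
    "generate_cohort",
    "generate_translating_frames",
    "stimulus_lag_autocovariance",
    "central_channels",
    "frontal_channels",
]

#: number of frontal-most channel indices carrying the ocular component
N_FRONTAL = 8


def frontal_channels(n_channels: int) -> np.ndarray:
    """Indices of the frontal channels (ocular projection)."""
    return np.arange(min(N_FRONTAL, n_channels))


def central_channels(n_channels: int) -> np.ndarray:
    """Indices of the designated central channels (alpha/mu injection).

    A contiguous block around the middle of the channel axis, about a tenth
    of the montage (at least 2 channels).
    """
    half_width = max(1, n_channels // 20)
    mid = n_channels // 2
    lo = max(0, mid - half_width)
    hi = min(n_channels, mid + half_width)
    return np.arange(lo, hi)


@dataclass
class GroundTruth:
    """Generative parameters of a simulated subject.

    Attributes
    ----------
    true_temporal_filters : (K, L) array
        Per-component lag profiles at the analysis rate, each unit Euclidean
        norm.
    true_spatial_maps : (K, D) array
        Per-component channel weights (arbitrary units), linearly independent.
    condition_gains : dict
        Condition name -> multiplicative response gain (unitless, > 0).
    alpha_amplitude : dict
        Condition name -> amplitude (uV) of the 10 Hz oscillation injected on
        the central channels.
    noise_sd : float
        Channel noise scale (uV).
    artifact_rate : float
        Expected sparse-artifact events per minute.
    seed : int
        RNG seed the truth was drawn with.
    """

    true_temporal_filters: np.ndarray
    true_spatial_maps: np.ndarray
    condition_gains: dict[str, float] = field(
        default_factory=lambda: {"active": 1.25, "sham": 1.25, "passive": 1.0}
    )
    alpha_amplitude: dict[str, float] = field(
        default_factory=lambda: {"active": 1.0, "sham": 1.0, "passive": 2.0}
    )
    noise_sd: float = 3.2
    artifact_rate: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_temporal_filters = np.atleast_2d(
            np.asarray(self.true_temporal_filters, dtype=float)
        )
        self.true_spatial_maps = np.atleast_2d(
            np.asarray(self.true_spatial_maps, dtype=float)
        )
        if self.true_temporal_filters.shape[0] != self.true_spatial_maps.shape[0]:
            raise ValueError("filters and maps must agree on component count")
        if any(g <= 0 for g in self.condition_gains.values()):
            raise ValueError("all condition gains must be > 0")

    @property
    def n_components(self) -> int:
        return self.true_temporal_filters.shape[0]

    @property
    def n_channels(self) -> int:
        return self.true_spatial_maps.shape[1]

    @property
    def n_lags(self) -> int:
        return self.true_temporal_filters.shape[1]


@dataclass
class SimulatedSession:
    """All trials of one simulated subject.

    Parallel lists: ``stimulus[i]`` and ``eeg[i]`` are the feature series and
    EEG of trial i, recorded under condition ``condition[i]``.
    """

    stimulus: list[StimulusFeature]
    eeg: list[EEGRecording]
    condition: list[str]
    ground_truth: GroundTruth
    subject: str = "sim"

    def __post_init__(self) -> None:
        if not (len(self.stimulus) == len(self.eeg) == len(self.condition)):
            raise ValueError("per-trial lists must have equal length")
        for s, e in zip(self.stimulus, self.eeg):
            if s.values.shape[0] != e.data.shape[1]:
                raise ValueError("stimulus and EEG of a trial must share duration")
            if s.rate != e.rate:
                raise ValueError("stimulus and EEG must share the analysis rate")

    def trials(self, condition: str | None = None):
        """Iterate (stimulus, eeg) pairs, optionally restricted to one condition."""
        for s, e, c in zip(self.stimulus, self.eeg, self.condition):
            if condition is None or c == condition:
                yield s, e


def generate_stimulus(
    duration_s: float,
    fs: float = 30.0,
    seed: int = 0,
    cutoff_hz: float = 3.0,
) -> np.ndarray:
    """Generate a raw nonnegative, slowly varying flow-like feature series.

    Gaussian white noise is low-passed at ``cutoff_hz / 2`` (zero-phase
    Butterworth) and squared.  Squaring doubles the bandwidth, so the result
    is nonnegative with spectral content confined below ``cutoff_hz`` --
    emulating the slow, skewed optic-flow magnitude of natural gameplay video.

    Returns the raw (not z-scored) series of length ``round(duration_s * fs)``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if not (0 < cutoff_hz < fs / 2):
        raise ValueError("cutoff_hz must lie in (0, fs/2)")
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    # pad to soak up filter transients, then crop
    pad = int(4 * fs / cutoff_hz)
    white = rng.standard_normal(n + 2 * pad)
    sos = signal.butter(4, cutoff_hz / 2.0, btype="low", fs=fs, output="sos")
    slow = signal.sosfiltfilt(sos, white)
    return np.square(slow[pad : pad + n])


def _bump(n_lags: int, peak: float, width: float) -> np.ndarray:
    lags = np.arange(n_lags, dtype=float)
    return np.exp(-0.5 * ((lags - peak) / width) ** 2)


_STIM_AUTOCOV_CACHE: dict[tuple, np.ndarray] = {}


def stimulus_lag_autocovariance(
    n_lags: int = 30,
    fs: float = 30.0,
    cutoff_hz: float = 3.0,
) -> np.ndarray:
    """Reference lag autocovariance of the standardized stimulus process.

    Estimated once from a long (20 min) realization with a fixed internal
    seed; the stimulus generator's spectrum is stationary, so this Toeplitz
    matrix characterizes the process, not any particular trial.
    """
    key = (n_lags, fs, cutoff_hz)
    if key not in _STIM_AUTOCOV_CACHE:
        from scipy.linalg import toeplitz

        ref = generate_stimulus(1200.0, fs=fs, seed=1234567,
                                cutoff_hz=cutoff_hz)
        z = (ref - ref.mean()) / ref.std()
        ac = np.array([np.dot(z[: z.size - k], z[k:]) / z.size
                       for k in range(n_lags)])
        _STIM_AUTOCOV_CACHE[key] = toeplitz(ac)
    return _STIM_AUTOCOV_CACHE[key]


def generate_ground_truth(
    n_channels: int = 96,
    n_components: int = 3,
    n_lags: int = 30,
    seed: int = 0,
    peak_lags: tuple[float, ...] | None = None,
    strength_decay: float = 0.65,
    filter_subspace_dim: int = 5,
    stim_fs: float = 30.0,
    stim_cutoff_hz: float = 3.0,
    **truth_kwargs,
) -> GroundTruth:
    """Draw a GroundTruth with smooth unimodal lag profiles and random maps.

    Default peak latencies are lags 6 and 12 (200 ms and 400 ms at 30 Hz)
    for the first two components, then evenly spaced later peaks.  The lag
    profiles are built from smooth bumps with a small biphasic undershoot,
    confined to the ``filter_subspace_dim`` dominant principal directions of
    the stimulus-process lag covariance, and symmetrically (Loewdin)
    orthogonalized under that covariance so the component drives h_j * s
    are mutually uncorrelated — the same uncorrelatedness the analysis-side
    decomposition imposes, and the condition under which the planted
    components are identifiable at all.  Filters are unit Euclidean norm.

    Spatial maps are smooth random channel profiles, orthogonalized and
    scaled by ``strength_decay**j`` so component strengths decrease — as
    empirical component spectra do — which makes the component order
    well defined.
    """
    if n_components > min(n_channels, n_lags):
        raise ValueError("n_components must be <= min(n_channels, n_lags)")
    rng = np.random.default_rng(seed)
    if peak_lags is None:
        # bump centers chosen so the delivered (subspace-projected,
        # orthogonalized) profiles peak at lags 6 and 12 (200/400 ms at
        # 30 Hz) for components 1 and 2
        peak_lags = tuple([7.0, 12.5] + [18.5 + 6.0 * j
                                         for j in range(n_components)])[:n_components]
    css = stimulus_lag_autocovariance(n_lags, stim_fs, stim_cutoff_hz)
    vals, vecs = np.linalg.eigh(css)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    m = min(max(filter_subspace_dim, n_components + 2), n_lags)
    proj = vecs[:, :m] @ vecs[:, :m].T

    raw_filters = np.empty((n_components, n_lags))
    for j in range(n_components):
        h = _bump(n_lags, peak_lags[j], width=1.5 + 0.5 * j)
        # slight biphasic undershoot after the peak for realism
        h -= 0.3 * _bump(n_lags, peak_lags[j] + 4.0, width=2.0 + 0.5 * j)
        raw_filters[j] = proj @ h
    gram = raw_filters @ css @ raw_filters.T
    gvals, gvecs = np.linalg.eigh(gram)
    inv_sqrt = (gvecs / np.sqrt(np.maximum(gvals, 1e-12))) @ gvecs.T
    filters = (raw_filters.T @ inv_sqrt).T
    filters /= np.linalg.norm(filters, axis=1, keepdims=True)
    for j in range(n_components):
        if filters[j, np.argmax(np.abs(filters[j]))] < 0:
            filters[j] *= -1.0

    # smooth random maps: moving-average of white noise along the channel
    # axis, orthogonalized, with geometrically decaying strengths
    raw = rng.standard_normal((n_components, n_channels + 8))
    kernel = np.hanning(9)
    maps = np.array([np.convolve(r, kernel, mode="valid") for r in raw])
    q, _ = np.linalg.qr(maps.T)
    maps = q.T[:n_components]
    for j in range(n_components):
        if maps[j, np.argmax(np.abs(maps[j]))] < 0:
            maps[j] *= -1.0
    maps *= (strength_decay ** np.arange(n_components))[:, None]
    return GroundTruth(
        true_temporal_filters=filters,
        true_spatial_maps=maps,
        seed=seed,
        **truth_kwargs,
    )


def _colored_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                   fs: float) -> np.ndarray:
    """Spatially correlated 1/f-shaped noise, unit variance per channel."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    # 1/f amplitude profile, flattened below 0.5 Hz to keep variance finite
    amp = 1.0 / np.sqrt(np.maximum(freqs, 0.5))
    spec = (
        rng.standard_normal((n_channels, freqs.size))
        + 1j * rng.standard_normal((n_channels, freqs.size))
    ) * amp
    noise = np.fft.irfft(spec, n=n_samples, axis=1)
    # short-range channel correlation: smooth across the channel axis
    kernel = np.array([0.25, 0.5, 1.0, 0.5, 0.25])
    pad = len(kernel) // 2
    padded = np.pad(noise, ((pad, pad), (0, 0)), mode="edge")
    mixed = np.stack(
        [np.tensordot(kernel, padded[i : i + len(kernel)], axes=1)
         for i in range(n_channels)]
    )
    mixed /= mixed.std(axis=1, keepdims=True)
    return mixed


def _blink_pulse(fs: float) -> np.ndarray:
    """200 ms biphasic blink-like transient, peak amplitude 1."""
    n = max(int(round(0.2 * fs)), 4)
    t = np.linspace(0, 1, n)
    pulse = np.sin(np.pi * t) - 0.4 * np.sin(2 * np.pi * t)
    return pulse / np.abs(pulse).max()


def generate_eeg(
    stimulus: np.ndarray,
    truth: GroundTruth,
    condition: str,
    seed: int = 0,
    fs: float = 30.0,
    blink_rate_per_min: float = 10.0,
    ocular_amplitude: float = 0.0,
    artifact_amplitude: float = 50.0,
) -> EEGRecording:
    """Simulate one trial of EEG evoked by ``stimulus`` under ``condition``.

    data = gain * sum_j a_j (h_j * s)(t) + colored noise + alpha sinusoid
    + sparse spikes + ocular blinks.  The convolution is causal with zero
    initial conditions, matching the analysis-side lag embedding.

    The stimulus is standardized (z-scored) before convolution so that the
    evoked amplitude is controlled by the spatial-map scale and gain alone.
    """
    if condition not in truth.condition_gains:
        raise ValueError(f"unknown condition {condition!r}")
    s = np.asarray(stimulus, dtype=float)
    if s.std() > 0:
        s = (s - s.mean()) / s.std()
    n = s.size
    rng = np.random.default_rng(seed)
    gain = truth.condition_gains[condition]

    data = np.zeros((truth.n_channels, n))
    for h, a in zip(truth.true_temporal_filters, truth.true_spatial_maps):
        driven = signal.fftconvolve(s, h)[:n]
        data += gain * np.outer(a, driven)

    if truth.noise_sd > 0:
        data += truth.noise_sd * _colored_noise(rng, truth.n_channels, n, fs)

    alpha_amp = truth.alpha_amplitude.get(condition, 0.0)
    if alpha_amp > 0:
        t = np.arange(n) / fs
        central = central_channels(truth.n_channels)
        for ch in central:
            phase = rng.uniform(0, 2 * np.pi)
            data[ch] += alpha_amp * np.sin(2 * np.pi * 10.0 * t + phase)

    if truth.artifact_rate > 0:
        # ~60 ms triangular transients (electrode pops, muscle bursts)
        half = max(1, int(round(0.03 * fs)))
        pulse = 1.0 - np.abs(np.arange(-half, half + 1)) / (half + 1)
        n_events = rng.poisson(truth.artifact_rate * n / fs / 60.0)
        for _ in range(n_events):
            ch = rng.integers(truth.n_channels)
            k = rng.integers(half, n - half - 1)
            amp = artifact_amplitude * rng.choice([-1.0, 1.0])
            data[ch, k - half : k + half + 1] += amp * pulse

    if ocular_amplitude > 0:
        pulse = ocular_amplitude * _blink_pulse(fs)
        frontal = frontal_channels(truth.n_channels)
        weights = np.linspace(1.0, 0.5, frontal.size)
        n_blinks = rng.poisson(blink_rate_per_min * n / fs / 60.0)
        for _ in range(n_blinks):
            k = rng.integers(0, max(n - pulse.size, 1))
            data[np.ix_(frontal, np.arange(k, k + pulse.size))] += (
                np.outer(weights, pulse)
            )

    labels = [f"ch{i:03d}" for i in range(truth.n_channels)]
    return EEGRecording(data=data, rate=fs, channel_labels=labels)


def generate_cohort(
    n_subjects: int = 18,
    conditions: list[tuple[str, float, float]] | None = None,
    trials_per_condition: int = 2,
    seed: int = 0,
    duration_s: float = 176.0,
    fs: float = 30.0,
    n_channels: int = 96,
    n_components: int = 3,
    n_lags: int = 30,
    noise_sd: float = 3.2,
    artifact_rate: float = 0.0,
    subject_map_sd: float = 0.2,
    stimulus_sharing: str = "all",
    **eeg_kwargs,
) -> list[SimulatedSession]:
    """Simulate a multi-subject study.

    ``conditions`` is a list of (label, gain, alpha_amplitude) triples;
    default emulates the three-condition design (active/sham engaged at gain
    1.25, passive at 1.0, with stronger alpha during passive viewing).

    Subjects share the temporal filter shapes; their spatial maps are the
    group maps plus per-subject Gaussian perturbations (sd ``subject_map_sd``
    relative to the unit-norm map), renormalized.

    ``stimulus_sharing`` controls how stimuli are reused:

    * ``"all"`` (default): trial t shows the same stimulus in every
      condition and for every subject, so the condition manipulation is
      purely the planted gain/alpha effect.  This is the exchangeable-null
      design: with equal gains, paired condition contrasts are calibrated.
    * ``"per-condition"``: each condition has its own fixed stimuli, reused
      across subjects — the playback design of deception studies, which
      confounds condition with stimulus content.
    * ``"none"``: every trial of every subject gets an independent stimulus.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if conditions is None:
        conditions = [("active", 1.25, 1.0), ("sham", 1.25, 1.0),
                      ("passive", 1.0, 2.0)]
    if not conditions:
        raise ValueError("conditions must be nonempty")

    master = np.random.default_rng(seed)
    group_truth = generate_ground_truth(
        n_channels=n_channels, n_components=n_components, n_lags=n_lags,
        seed=int(master.integers(2**31)),
    )
    gains = {label: g for label, g, _ in conditions}
    alphas = {label: a for label, _, a in conditions}

    if stimulus_sharing not in {"all", "per-condition", "none"}:
        raise ValueError("stimulus_sharing must be 'all', 'per-condition' "
                         "or 'none'")
    trial_seeds = {t: int(master.integers(2**31))
                   for t in range(trials_per_condition)}
    stim_seeds = {
        (label, t): (trial_seeds[t] if stimulus_sharing == "all"
                     else int(master.integers(2**31)))
        for label, _, _ in conditions
        for t in range(trials_per_condition)
    }

    sessions = []
    for subj in range(n_subjects):
        sub_rng = np.random.default_rng(int(master.integers(2**31)))
        maps = group_truth.true_spatial_maps.copy()
        maps += subject_map_sd * sub_rng.standard_normal(maps.shape)
        maps /= np.linalg.norm(maps, axis=1, keepdims=True)
        truth = GroundTruth(
            true_temporal_filters=group_truth.true_temporal_filters.copy(),
            true_spatial_maps=maps,
            condition_gains=dict(gains),
            alpha_amplitude=dict(alphas),
            noise_sd=noise_sd,
            artifact_rate=artifact_rate,
            seed=seed,
        )
        stims, eegs, labels = [], [], []
        for label, _, _ in conditions:
            for t in range(trials_per_condition):
                s_seed = (int(sub_rng.integers(2**31))
                          if stimulus_sharing == "none"
                          else stim_seeds[(label, t)])
                raw = generate_stimulus(duration_s, fs=fs, seed=s_seed)
                z = (raw - raw.mean()) / raw.std()
                stims.append(StimulusFeature(values=z, rate=fs,
                                             feature_name="optic_flow"))
                eegs.append(generate_eeg(
                    raw, truth, label, seed=int(sub_rng.integers(2**31)),
                    fs=fs, **eeg_kwargs,
                ))
                labels.append(label)
        sessions.append(SimulatedSession(
            stimulus=stims, eeg=eegs, condition=labels,
            ground_truth=truth, subject=f"S{subj:02d}",
        ))
    return sessions


def generate_translating_frames(
    height: int = 64,
    width: int = 64,
    n_frames: int = 10,
    speed: float = 1.0,
    seed: int = 0,
    frame_rate: float = 60.0,
    smooth_px: float = 3.0,
) -> FrameSequence:
    """Smooth random texture translated horizontally with periodic wrap.

    The texture is Gaussian-smoothed white noise (scale ``smooth_px`` pixels,
    wrap-around boundary); each successive frame shifts it by ``speed`` pixels
    along the width axis (sub-pixel shifts via the Fourier shift theorem).
    The known displacement makes this the ground-truth fixture for optic-flow
    validation.
    """
    if speed < 0:
        raise ValueError("speed must be >= 0")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    texture = ndimage.gaussian_filter(
        rng.standard_normal((height, width)), sigma=smooth_px, mode="wrap"
    )
    # 8-bit video intensity scale; keeps gradient magnitudes in the regime
    # the Horn-Schunck regularizer defaults expect
    texture = 255.0 * (texture - texture.min()) / (texture.max() - texture.min())
    frames = np.empty((n_frames, height, width))
    spec = np.fft.fft(texture, axis=1)
    freqs = np.fft.fftfreq(width)
    for t in range(n_frames):
        shift = speed * t
        if float(shift).is_integer():
            frames[t] = np.roll(texture, int(shift), axis=1)
        else:
            phase = np.exp(-2j * np.pi * freqs * shift)
            frames[t] = np.real(np.fft.ifft(spec * phase, axis=1))
    return FrameSequence(frames=frames, frame_rate=frame_rate)
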