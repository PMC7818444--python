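"""Video stimulus features: optic-flow magnitude and temporal contrast.

Frames are reduced to 320x180 grayscale, dense optic flow is estimated with
the classic Horn-Schunck method, and the spatial mean of the flow magnitude
(or of the absolute frame difference) forms a scalar time series that is
resampled to the EEG analysis rate and z-scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "FrameSequence",
    "FlowField",
    "StimulusFeature",
    "preprocess_frames",
    "horn_schunck_flow",
    "frame_feature",
    "feature_to_eeg_rate",
    "zscore",
]

#: ITU-R BT.601 luma weights (R, G, B)
BT601 = np.array([0.299, 0.587, 0.114])


class DegenerateInputError(ValueError):
    """Raised when an operation receives input it cannot meaningfully process
    (e.g. z-scoring a constant series)."""


@dataclass
class FrameSequence:
    """A stack of grayscale frames with its frame rate.

    frames : (T, H, W) array of finite intensities (0-1 or 0-255; the scale
    is whatever the source used and is carried through unchanged).
    """

    frames: np.ndarray
    frame_rate: float = 60.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")
        if self.frames.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class FlowField:
    """Dense per-pixel displacement (px/frame) for each consecutive frame pair."""

    u_x: np.ndarray
    u_y: np.ndarray

    def __post_init__(self) -> None:
        self.u_x = np.asarray(self.u_x, dtype=float)
        self.u_y = np.asarray(self.u_y, dtype=float)
        if self.u_x.shape != self.u_y.shape or self.u_x.ndim != 3:
            raise ValueError("u_x and u_y must be matching (T-1, H, W) stacks")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u_x, self.u_y)


@dataclass
class StimulusFeature:
    """Z-scored scalar stimulus time series at the analysis rate."""

    values: np.ndarray
    rate: float
    feature_name: str = "optic_flow"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.rate <= 0:
            raise ValueError("rate must be positive")


def zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if x.size < 2 or sd == 0:
        raise DegenerateInputError("cannot z-score a constant or scalar series")
    return (x - x.mean()) / sd


def preprocess_frames(
    raw_frames: np.ndarray,
    target_h: int = 180,
    target_w: int = 320,
) -> FrameSequence:
    """Convert color frames to grayscale and resize by area averaging.

    ``raw_frames`` is (T, H, W, 3) RGB or (T, H, W) already-gray.  Luminance
    uses the BT.601 weights.  When the source dimensions are integer
    multiples of the target, the resize is an exact block mean; otherwise a
    smoothed interpolating resize (skimage) is used.
    """
    raw = np.asarray(raw_frames, dtype=float)
    if raw.ndim == 4:
        if raw.shape[-1] != 3:
            raise ValueError("color frames must have 3 channels")
        gray = raw @ BT601
    elif raw.ndim == 3:
        gray = raw
    else:
        raise ValueError("expected (T, H, W[, 3]) frame stack")
    if gray.shape[0] < 1:
        raise ValueError("empty frame stack")
    if target_h < 2 or target_w < 2:
        raise ValueError("target dimensions must be >= 2x2")

    T, H, W = gray.shape
    if H % target_h == 0 and W % target_w == 0:
        fh, fw = H // target_h, W // target_w
        out = gray.reshape(T, target_h, fh, target_w, fw).mean(axis=(2, 4))
    elif (H, W) == (target_h, target_w):
        out = gray
    else:
        from skimage.transform import resize

        out = np.stack([
            resize(f, (target_h, target_w), anti_aliasing=True,
                   preserve_range=True)
            for f in gray
        ])
    frame_rate = 60.0
    if isinstance(raw_frames, FrameSequence):  # pragma: no cover - convenience
        frame_rate = raw_frames.frame_rate
    return FrameSequence(frames=out, frame_rate=frame_rate)


# Horn-Schunck finite-difference stencils: gradients averaged over the
# 2x2x2 cube spanning the two frames, per the original formulation.
_KX = np.array([[-1.0, 1.0], [-1.0, 1.0]]) / 4.0
_KY = np.array([[-1.0, -1.0], [1.0, 1.0]]) / 4.0
_KT = np.array([[1.0, 1.0], [1.0, 1.0]]) / 4.0
# local-average kernel for the Jacobi update
_AVG = np.array([
    [1 / 12, 1 / 6, 1 / 12],
    [1 / 6, 0.0, 1 / 6],
    [1 / 12, 1 / 6, 1 / 12],
])


def _hs_pair(i0: np.ndarray, i1: np.ndarray, alpha2: float,
             n_iter: int) -> tuple[np.ndarray, np.ndarray]:
    ex = ndimage.convolve(i0, _KX, mode="nearest") + ndimage.convolve(
        i1, _KX, mode="nearest")
    ey = ndimage.convolve(i0, _KY, mode="nearest") + ndimage.convolve(
        i1, _KY, mode="nearest")
    et = ndimage.convolve(i1, _KT, mode="nearest") - ndimage.convolve(
        i0, _KT, mode="nearest")
    u = np.zeros_like(i0)
    v = np.zeros_like(i0)
    denom = alpha2 + ex**2 + ey**2
    for _ in range(n_iter):
        ubar = ndimage.convolve(u, _AVG, mode="nearest")
        vbar = ndimage.convolve(v, _AVG, mode="nearest")
        rate = (ex * ubar + ey * vbar + et) / denom
        u = ubar - ex * rate
        v = vbar - ey * rate
    return u, v


def horn_schunck_flow(
    frames: FrameSequence,
    smoothness: float = 1.0,
    n_iter: int = 10,
) -> FlowField:
    """Dense optic flow by the iterative Horn-Schunck method.

    For each consecutive frame pair, spatial and temporal intensity gradients
    are estimated with the standard 2x2x2 finite-difference stencils, then
    ``n_iter`` Jacobi iterations refine the flow from a zero initialization,
    trading brightness-constancy error against a smoothness penalty weighted
    by ``smoothness`` (the Horn-Schunck alpha^2 regularizer uses its square).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if smoothness <= 0:
        raise ValueError("smoothness must be > 0")
    f = frames.frames
    if f.shape[0] < 2:
        raise ValueError("need at least 2 frames for flow")
    alpha2 = smoothness**2
    us, vs = [], []
    for t in range(f.shape[0] - 1):
        u, v = _hs_pair(f[t], f[t + 1], alpha2, n_iter)
        us.append(u)
        vs.append(v)
    return FlowField(u_x=np.stack(us), u_y=np.stack(vs))


def frame_feature(
    frames: FrameSequence,
    flow: FlowField | None = None,
    feature_name: str = "optic_flow",
    rectify: bool = True,
) -> np.ndarray:
    """Scalar per-frame-pair feature: mean flow magnitude or temporal contrast.

    ``rectify`` controls whether the frame difference is taken in absolute
    value before spatial averaging (only relevant for temporal_contrast).
    Output length is T - 1.
    """
    if feature_name == "optic_flow":
        if flow is None:
            raise ValueError("optic_flow feature requires a FlowField")
        return flow.magnitude.mean(axis=(1, 2))
    if feature_name == "temporal_contrast":
        diff = np.diff(frames.frames, axis=0)
        if rectify:
            diff = np.abs(diff)
        return diff.mean(axis=(1, 2))
    raise ValueError(f"unknown feature {feature_name!r}")


def feature_to_eeg_rate(
    series: np.ndarray,
    frame_rate: float,
    eeg_rate: float = 30.0,
    feature_name: str = "optic_flow",
) -> StimulusFeature:
    """Resample a per-frame series to the EEG analysis rate and z-score it.

    When the frame rate is an integer multiple of the EEG rate the resample
    is an anti-aliasing mean over consecutive frame groups (60 -> 30 Hz:
    mean of adjacent pairs); otherwise polyphase resampling is used.
    Constant input raises :class:`DegenerateInputError`.
    """
    x = np.asarray(series, dtype=float).ravel()
    if frame_rate < eeg_rate:
        raise ValueError("frame_rate must be >= eeg_rate")
    ratio = frame_rate / eeg_rate
    if abs(ratio - round(ratio)) < 1e-9:
        k = int(round(ratio))
        n_out = x.size // k
        if n_out == 0:
            raise ValueError("series too short for the requested rate")
        y = x[: n_out * k].reshape(n_out, k).mean(axis=1)
    else:
        frac = Fraction(eeg_rate / frame_rate).limit_denominator(1000)
        y = signal.resample_poly(x, frac.numerator, frac.denominator,
                                 padtype="line")
        if y.size == 0:
            raise ValueError("series too short for the requested rate")
    return StimulusFeature(values=zscore(y), rate=eeg_rate,
                           feature_name=feature_name)
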