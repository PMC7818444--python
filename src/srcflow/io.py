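"""Readers and writers for the pipeline's data formats.

EEG: BrainVision (.vhdr) and EDF via mne, plus an internal HDF5 array
container used for simulated/cleaned data.  Stimulus features: 2-column
delimited text (time_s, value).  Video: a directory of ordered PNG frames,
or any container imageio can open (mp4/avi need an ffmpeg backend).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .preprocess import EEGRecording
from .video import FrameSequence, StimulusFeature

__all__ = [
    "save_eeg_h5",
    "load_eeg_h5",
    "read_raw_eeg",
    "write_feature_tsv",
    "read_feature_tsv",
    "read_video",
    "save_ground_truth_json",
]


def save_eeg_h5(path: str | Path, eeg: EEGRecording, **attrs) -> None:
    """Write an EEGRecording (uV) to the internal HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("data", data=eeg.data)
        d.attrs["rate"] = eeg.rate
        d.attrs["unit"] = "uV"
        for k, v in attrs.items():
            d.attrs[k] = v
        f.create_dataset("channel_labels",
                         data=np.array(eeg.channel_labels, dtype="S"))
        f.create_dataset("valid_channels", data=eeg.valid_channels)
        f.create_dataset("valid_samples", data=eeg.valid_samples)


def load_eeg_h5(path: str | Path) -> EEGRecording:
    import h5py

    with h5py.File(path, "r") as f:
        for key in ("data", "channel_labels", "valid_channels",
                    "valid_samples"):
            if key not in f:
                raise ValueError(f"malformed EEG container: missing '{key}'")
        d = f["data"]
        if "rate" not in d.attrs:
            raise ValueError("malformed EEG container: missing 'rate' attr")
        return EEGRecording(
            data=d[...],
            rate=float(d.attrs["rate"]),
            channel_labels=[s.decode() for s in f["channel_labels"][...]],
            valid_channels=f["valid_channels"][...],
            valid_samples=f["valid_samples"][...],
        )


def read_raw_eeg(path: str | Path) -> EEGRecording:
    """Read BrainVision/EDF (via mne, converted to uV) or the HDF5 container."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".h5", ".hdf5"}:
        return load_eeg_h5(path)
    import mne

    if suffix == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif suffix == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unrecognized EEG format: {path.name}")
    data_uv = raw.get_data() * 1e6  # mne uses volts internally
    return EEGRecording(data=data_uv, rate=float(raw.info["sfreq"]),
                        channel_labels=list(raw.ch_names))


def write_feature_tsv(path: str | Path, feature: StimulusFeature) -> None:
    """Write a stimulus feature as 2-column delimited text (time_s, value)."""
    t = np.arange(feature.values.size) / feature.rate
    header = f"time_s\t{feature.feature_name}"
    np.savetxt(path, np.column_stack([t, feature.values]), delimiter="\t",
               header=header, comments="")


def read_feature_tsv(path: str | Path,
                     feature_name: str = "optic_flow") -> StimulusFeature:
    arr = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    if arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("feature file must have 2 columns and >= 2 rows")
    t, v = arr[:, 0], arr[:, 1]
    dt = np.diff(t)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("feature time axis must be uniformly increasing")
    return StimulusFeature(values=v, rate=1.0 / dt[0],
                           feature_name=feature_name)


def read_video(path: str | Path) -> np.ndarray:
    """Load video frames as a (T, H, W[, 3]) array.

    ``path`` may be a directory of ordered PNG frames (always supported) or
    a container file readable by imageio (mp4/avi require an ffmpeg
    backend; a clear error is raised if none is available).
    """
    import imageio.v3 as iio

    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in {".png", ".jpg", ".jpeg",
                                               ".tif", ".tiff"})
        if not files:
            raise ValueError(f"no image frames found in {path}")
        frames = [iio.imread(f) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ValueError("frame sizes differ within the directory")
        return np.stack(frames)
    try:
        return iio.imread(path, index=None)
    except Exception as exc:  # noqa: BLE001 - plugin availability varies
        raise ValueError(
            f"could not read video container {path.name}: {exc}; "
            "install an imageio ffmpeg backend or supply a PNG directory"
        ) from exc


def save_ground_truth_json(path: str | Path, truth) -> None:
    """Ground-truth sidecar for simulated sessions."""
    payload = {
        "true_temporal_filters": truth.true_temporal_filters.tolist(),
        "true_spatial_maps": truth.true_spatial_maps.tolist(),
        "condition_gains": truth.condition_gains,
        "alpha_amplitude": truth.alpha_amplitude,
        "noise_sd": truth.noise_sd,
        "artifact_rate": truth.artifact_rate,
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
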