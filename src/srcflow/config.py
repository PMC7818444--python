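"""Pipeline configuration: one dataclass, YAML round-trip, study defaults."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["SimulationConfig", "PipelineConfig"]


@dataclass
class SimulationConfig:
    """Simulated-study block: the default three-condition paired design."""

    n_subjects: int = 18
    trials_per_condition: int = 2
    duration_s: float = 176.0
    n_channels: int = 96
    n_components: int = 3
    noise_sd: float = 1.0
    artifact_rate: float = 0.0
    subject_map_sd: float = 0.2
    # (label, evoked gain, alpha amplitude on central channels in uV)
    conditions: list = field(default_factory=lambda: [
        ["active", 1.25, 1.0],
        ["sham", 1.25, 1.0],
        ["passive", 1.0, 2.0],
    ])


@dataclass
class PipelineConfig:
    """All analysis settings; the defaults pin the standard operating point.

    analysis_rate 30 Hz, L = 30 lags, K = 11 EEG dimensions (or a variance
    fraction), robust-PCA lambda 0.5, 4-SD rejection over 3 iterations,
    8-12 Hz 4th-order alpha band-pass, 1,000 permutations, FDR q = 0.05.
    """

    analysis_rate: float = 30.0
    n_lags: int = 30
    k_components: int = 11
    var_frac: float | None = None
    rpca_lam: float = 0.5
    hp_cutoff: float = 1.0
    rejection_n_sd: float = 4.0
    rejection_n_iter: int = 3
    alpha_band: tuple = (8.0, 12.0)
    alpha_filter_order: int = 4
    n_perm: int = 1000
    q: float = 0.05
    n_response_components: int = 3
    seed: int = 0
    run_preprocess: bool = False
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**{k: v for k, v in raw.items()
                     if k in cls.__dataclass_fields__})
        if sim:
            cfg.simulation = SimulationConfig(
                **{k: v for k, v in sim.items()
                   if k in SimulationConfig.__dataclass_fields__})
        if isinstance(cfg.alpha_band, list):
            cfg.alpha_band = tuple(cfg.alpha_band)
        return cfg
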