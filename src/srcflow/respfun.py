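"""Condition-specific spatial and temporal response functions.

With a common set of CCA filters fitted on condition-pooled data, the
condition-wise response structure is recovered by ordinary regression:

* spatial: regress the filtered stimulus components u_1..u_3 (plus
  intercept) onto each EEG channel of one condition -> per-channel weights
  a_j, the condition's spatial response function;
* temporal: spatially filter the condition EEG with w_1..w_3 and regress
  each virtual electrode v_j on the lag-embedded stimulus -> lag weights
  h_j(tau), the condition's temporal response function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import SRCResults, temporal_embed
from .preprocess import EEGRecording
from .video import StimulusFeature

__all__ = [
    "ResponseFunctionSet",
    "spatial_response_by_condition",
    "temporal_response_by_condition",
    "condition_response_functions",
    "group_average",
]


@dataclass
class ResponseFunctionSet:
    """Per-condition spatial (n_comp x D) and temporal (n_comp x L) weights."""

    spatial: dict[str, np.ndarray] = field(default_factory=dict)
    temporal: dict[str, np.ndarray] = field(default_factory=dict)
    subject: str = "group-average"


def _lstsq_masked(design: np.ndarray, targets: np.ndarray,
                  valid: np.ndarray | None = None) -> np.ndarray:
    """Least squares of each target row on the design (T x p); returns p x n."""
    if valid is not None:
        design = design[valid]
        targets = targets[:, valid]
    coef, *_ = np.linalg.lstsq(design, targets.T, rcond=None)
    return coef


def spatial_response_by_condition(
    u_components: np.ndarray,
    eeg_cond: EEGRecording,
) -> np.ndarray:
    """Regress filtered-stimulus components onto each channel of one condition.

    ``u_components`` is (T, n_comp) from the pooled fit applied to this
    condition's stimulus.  Returns (n_comp, D) regression weights (intercept
    fitted, not returned).  Samples invalid on any valid channel are
    excluded.
    """
    u = np.atleast_2d(np.asarray(u_components, dtype=float))
    if u.shape[0] != eeg_cond.n_samples:
        raise ValueError("component length must match the EEG")
    valid = np.all(eeg_cond.valid_samples[eeg_cond.valid_channels], axis=0)
    design = np.column_stack([np.ones(u.shape[0]), u])
    coef = _lstsq_masked(design, eeg_cond.data, valid)
    weights = coef[1:]                       # drop intercept -> n_comp x D
    weights[:, ~eeg_cond.valid_channels] = 0.0
    return weights


def temporal_response_by_condition(
    s: StimulusFeature | np.ndarray,
    v_components: np.ndarray,
    n_lags: int = 30,
) -> np.ndarray:
    """Regress spatially filtered condition EEG on the lag-embedded stimulus.

    ``v_components`` is (T, n_comp): the condition EEG passed through the
    pooled-fit spatial filters.  Returns (n_comp, L) lag weights — the
    condition's temporal response functions.  The full least-squares solve
    (not a naive cross-correlation) deconvolves the stimulus
    autocorrelation.
    """
    v = np.atleast_2d(np.asarray(v_components, dtype=float))
    if v.ndim != 2:
        raise ValueError("v_components must be (T, n_comp)")
    s_emb = temporal_embed(s, n_lags)
    if v.shape[0] != s_emb.shape[0]:
        raise ValueError("component length must match the stimulus")
    if v.shape[0] < 10 * n_lags:
        import warnings

        warnings.warn("fewer than 10*L samples for the temporal regression",
                      RuntimeWarning, stacklevel=2)
    design = np.column_stack([np.ones(s_emb.shape[0]), s_emb])
    coef = _lstsq_masked(design, v.T)
    return coef[1:].T                        # n_comp x L


def condition_response_functions(
    decomp: SRCResults,
    session,
    n_components: int = 3,
    n_lags: int | None = None,
) -> ResponseFunctionSet:
    """Build the per-condition response-function set for one subject.

    For every condition in ``session`` (a SimulatedSession-like object),
    concatenates that condition's trials, forms u_j from the pooled-fit
    temporal filters and v_j from the pooled-fit spatial filters, and runs
    the two regressions.
    """
    if n_lags is None:
        n_lags = decomp.temporal_filters.shape[1]
    n_comp = min(n_components, decomp.k_components)
    h = decomp.temporal_filters[:n_comp]
    w = decomp.spatial_filters[:n_comp]
    out = ResponseFunctionSet(subject=getattr(session, "subject", "subject"))
    for cond in dict.fromkeys(session.condition):
        s_parts, u_parts, v_parts, eeg_parts = [], [], [], []
        for s, e in session.trials(cond):
            emb = temporal_embed(s, n_lags)
            u_parts.append(emb @ h.T)
            v_parts.append((w @ np.where(e.valid_samples, e.data, 0.0)).T)
            s_parts.append(np.asarray(s.values))
            eeg_parts.append(e)
        u = np.vstack(u_parts)
        v = np.vstack(v_parts)
        data = np.hstack([e.data for e in eeg_parts])
        eeg_cat = EEGRecording(
            data=data, rate=eeg_parts[0].rate,
            channel_labels=list(eeg_parts[0].channel_labels),
            valid_channels=np.logical_and.reduce(
                [e.valid_channels for e in eeg_parts]),
            valid_samples=np.hstack([e.valid_samples for e in eeg_parts]),
        )
        out.spatial[cond] = spatial_response_by_condition(u, eeg_cat)
        # embed per trial so lags do not cross trial edges
        temp = np.zeros((n_comp, n_lags))
        design_rows = np.vstack([temporal_embed(sp, n_lags) for sp in s_parts])
        design = np.column_stack([np.ones(design_rows.shape[0]), design_rows])
        coef = _lstsq_masked(design, v.T)
        temp[:] = coef[1:].T
        out.temporal[cond] = temp
    return out


def group_average(sets: list[ResponseFunctionSet]) -> ResponseFunctionSet:
    """Elementwise mean of response functions across subjects, per condition."""
    if not sets:
        raise ValueError("need at least one subject")
    conds = list(sets[0].spatial)
    out = ResponseFunctionSet(subject="group-average")
    for cond in conds:
        out.spatial[cond] = np.mean([s.spatial[cond] for s in sets], axis=0)
        out.temporal[cond] = np.mean([s.temporal[cond] for s in sets], axis=0)
    return out
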