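"""Stimulus-response correlation via temporally embedded CCA.

The model: a scalar stimulus feature s(t) is temporally filtered,
u(t) = sum_tau h(tau) s(t - tau), and the D-channel neural response r_i(t)
is spatially filtered, v(t) = sum_i w_i r_i(t); canonical correlation
analysis finds the filter pairs (h_j, w_j) maximizing the Pearson
correlation rho_j = corr(u_j, v_j), with successive components mutually
uncorrelated.  The EEG side is regularized by truncating the eigenvalue
spectrum of its covariance to K dimensions (default 11, or the smallest K
explaining a configured variance fraction).  The dependent measure is the
total SRC, the sum of the canonical correlations.  Each component's forward
model a_j = C_rr w_j / (w_j' C_rr w_j) gives the scalp pattern ("spatial
response function") through which the component is expressed.

Organized statsmodels-style: :class:`StimulusResponseCCA` is built from
data and ``fit()`` returns :class:`SRCResults`, which carries estimates,
diagnostics, ``project()`` for out-of-sample SRC, and ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import EEGRecording
from .video import StimulusFeature

__all__ = [
    "TemporalFilter",
    "SpatialFilter",
    "SRCResult",
    "SRCResults",
    "ComponentDecomposition",
    "StimulusResponseCCA",
    "temporal_embed",
    "fit_cca",
    "total_src",
    "project",
    "pool_and_fit",
]


@dataclass
class TemporalFilter:
    """Lag-indexed filter h(tau), tau = 0..L-1 samples at the analysis rate."""

    coefficients: np.ndarray

    @property
    def n_lags(self) -> int:
        return self.coefficients.size


@dataclass
class SpatialFilter:
    """Per-channel weights w_i, i = 1..D."""

    weights: np.ndarray


@dataclass
class SRCResult:
    """Per-component and total SRC for one projection of data."""

    per_component: np.ndarray
    condition: str | None = None
    subject: str | None = None
    n_samples_used: int = 0

    @property
    def total_src(self) -> float:
        return float(np.sum(self.per_component))


def temporal_embed(s: np.ndarray | StimulusFeature, n_lags: int) -> np.ndarray:
    """Causal lag matrix: row t is [s(t), s(t-1), ..., s(t-L+1)], zero-padded.

    EEG lags the stimulus, so only nonnegative delays enter the model.
    """
    if isinstance(s, StimulusFeature):
        s = s.values
    s = np.asarray(s, dtype=float).ravel()
    if n_lags < 1:
        raise ValueError("n_lags must be >= 1")
    if s.size < n_lags:
        raise ValueError("series shorter than the number of lags")
    out = np.zeros((s.size, n_lags))
    for tau in range(n_lags):
        out[tau:, tau] = s[: s.size - tau]
    return out


def _masked_center(x: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Center each row over its valid samples and zero invalid entries."""
    counts = np.maximum(mask.sum(axis=1, keepdims=True), 1)
    means = (x * mask).sum(axis=1, keepdims=True) / counts
    return np.where(mask, x - means, 0.0)


def _pairwise_cov(xc: np.ndarray, mx: np.ndarray,
                  yc: np.ndarray, my: np.ndarray) -> np.ndarray:
    """Covariance between rows of xc and yc, pairwise over shared valid samples.

    Inputs are already centered over their own valid samples and zeroed at
    invalid entries.
    """
    counts = mx.astype(float) @ my.T.astype(float)
    return (xc @ yc.T) / np.maximum(counts, 1.0)


def _inv_sqrt_psd(c: np.ndarray, rtol: float = 1e-10) -> tuple[np.ndarray, int]:
    """Symmetric pseudo-inverse square root of a PSD matrix; returns rank."""
    c = 0.5 * (c + c.T)
    vals, vecs = np.linalg.eigh(c)
    floor = rtol * max(vals.max(), 0.0)
    keep = vals > floor
    rank = int(keep.sum())
    inv_sqrt = (vecs[:, keep] / np.sqrt(vals[keep])) @ vecs[:, keep].T
    return inv_sqrt, rank


class SRCResults:
    """Fitted CCA decomposition: filters, forward models, correlations.

    Attributes
    ----------
    rho : (K_cca,) array
        Canonical correlations, non-increasing, in [0, 1].
    temporal_filters : (K_cca, L) array of h_j.
    spatial_filters : (K_cca, D) array of w_j (zeros at invalid channels).
    forward_models : (K_cca, D) array of a_j.
    u, v : (T, K_cca) arrays
        Stimulus and response components on the training data.
    pca_eigvecs, pca_eigvals : retained EEG principal directions/variances.
    """

    def __init__(self, model: "StimulusResponseCCA", rho, temporal_filters,
                 spatial_filters, forward_models, u, v,
                 pca_eigvecs, pca_eigvals, n_samples_used: int):
        self.model = model
        self.rho = np.asarray(rho, dtype=float)
        self.temporal_filters = np.asarray(temporal_filters, dtype=float)
        self.spatial_filters = np.asarray(spatial_filters, dtype=float)
        self.forward_models = np.asarray(forward_models, dtype=float)
        self.u = u
        self.v = v
        self.pca_eigvecs = pca_eigvecs
        self.pca_eigvals = pca_eigvals
        self.n_samples_used = n_samples_used

    @property
    def k_components(self) -> int:
        return self.rho.size

    @property
    def total_src(self) -> float:
        """Total SRC: the exact sum of the canonical correlations."""
        return float(np.sum(self.rho))

    def temporal_filter(self, j: int) -> TemporalFilter:
        return TemporalFilter(coefficients=self.temporal_filters[j])

    def spatial_filter(self, j: int) -> SpatialFilter:
        return SpatialFilter(weights=self.spatial_filters[j])

    def src_result(self, condition: str | None = None,
                   subject: str | None = None) -> SRCResult:
        return SRCResult(per_component=self.rho.copy(), condition=condition,
                         subject=subject, n_samples_used=self.n_samples_used)

    def project(self, s: StimulusFeature | np.ndarray, eeg: EEGRecording,
                condition: str | None = None,
                subject: str | None = None) -> SRCResult:
        """Apply the fitted filters to new data; no refitting.

        h_j filters the new stimulus, w_j the new EEG; per-component Pearson
        correlations over valid samples are summed into a total SRC.
        """
        if eeg.n_channels != self.spatial_filters.shape[1]:
            raise ValueError("channel count does not match the fitted filters")
        s_emb = temporal_embed(s, self.temporal_filters.shape[1])
        u = s_emb @ self.temporal_filters.T
        v = self.spatial_filters @ np.where(eeg.valid_samples, eeg.data, 0.0)
        used = eeg.valid_channels & (np.abs(self.spatial_filters).sum(0) > 0)
        valid = np.all(eeg.valid_samples[used], axis=0) if used.any() else (
            np.ones(eeg.n_samples, dtype=bool))
        rhos = np.empty(self.k_components)
        for j in range(self.k_components):
            uj = u[valid, j]
            vj = v[j, valid]
            su, sv = uj.std(), vj.std()
            rhos[j] = (
                0.0 if su == 0 or sv == 0
                else float(np.corrcoef(uj, vj)[0, 1])
            )
        return SRCResult(per_component=rhos, condition=condition,
                         subject=subject, n_samples_used=int(valid.sum()))

    def project_pooled(self, stimuli, eegs, condition: str | None = None,
                       subject: str | None = None) -> SRCResult:
        """Project several trials and correlate over their pooled samples.

        Each trial is lag-embedded independently (zero padding restarts at
        trial edges), the filtered components are concatenated, and a single
        Pearson correlation per component is computed over the pooled valid
        samples.  This is the concatenation scheme for per-condition SRC.
        """
        us, vs, valids = [], [], []
        L = self.temporal_filters.shape[1]
        for s, eeg in zip(stimuli, eegs):
            if eeg.n_channels != self.spatial_filters.shape[1]:
                raise ValueError("channel count does not match the fit")
            s_emb = temporal_embed(s, L)
            us.append(s_emb @ self.temporal_filters.T)
            vs.append(
                (self.spatial_filters
                 @ np.where(eeg.valid_samples, eeg.data, 0.0)).T)
            used = eeg.valid_channels
            valids.append(np.all(eeg.valid_samples[used], axis=0)
                          if used.any() else np.ones(eeg.n_samples, bool))
        u = np.vstack(us)
        v = np.vstack(vs)
        valid = np.concatenate(valids)
        rhos = np.empty(self.k_components)
        for j in range(self.k_components):
            uj, vj = u[valid, j], v[valid, j]
            rhos[j] = (0.0 if uj.std() == 0 or vj.std() == 0
                       else float(np.corrcoef(uj, vj)[0, 1]))
        return SRCResult(per_component=rhos, condition=condition,
                         subject=subject, n_samples_used=int(valid.sum()))

    def summary(self) -> str:
        lines = [
            "Stimulus-Response CCA Results",
            "=" * 46,
            f"{'Components':<28}{self.k_components:>18d}",
            f"{'Lags (L)':<28}{self.temporal_filters.shape[1]:>18d}",
            f"{'Channels (D)':<28}{self.spatial_filters.shape[1]:>18d}",
            f"{'Samples used':<28}{self.n_samples_used:>18d}",
            f"{'Total SRC':<28}{self.total_src:>18.4f}",
            "-" * 46,
            f"{'component':<12}{'rho':>12}{'peak lag':>12}",
        ]
        for j in range(self.k_components):
            peak = int(np.argmax(np.abs(self.temporal_filters[j])))
            lines.append(f"{j + 1:<12d}{self.rho[j]:>12.4f}{peak:>12d}")
        lines.append("=" * 46)
        return "\n".join(lines)


#: alias emphasizing what the results object is: the fitted decomposition
ComponentDecomposition = SRCResults


class StimulusResponseCCA:
    """Covariance-truncated CCA between an embedded stimulus and EEG.

    Parameters
    ----------
    stimulus : StimulusFeature / array, or list of them (one per trial)
    eeg : EEGRecording or list of them (one per trial)
    n_lags : filter length L (default 30 ~ 0-967 ms at 30 Hz)
    n_components : EEG covariance truncation K (default 11)
    var_frac : if given, choose K as the smallest number of principal
        directions explaining this variance fraction instead.
    stim_rtol : conditioning floor for the stimulus side: lag-covariance
        eigendirections with variance below ``stim_rtol`` times the dominant
        one are truncated before whitening (default 0.05).  For broadband
        stimuli this never triggers; for narrowband (slow) stimuli it
        confines the temporal filters to the subspace the data can actually
        constrain, the same spectral-truncation regularization applied to
        the EEG side.

    Trials are embedded independently (lags never span trial boundaries;
    zero padding restarts per trial) and their samples pooled.
    """

    def __init__(self, stimulus, eeg, n_lags: int = 30,
                 n_components: int = 11, var_frac: float | None = None,
                 stim_rtol: float = 0.05):
        stim_list = stimulus if isinstance(stimulus, (list, tuple)) else [stimulus]
        eeg_list = eeg if isinstance(eeg, (list, tuple)) else [eeg]
        if len(stim_list) != len(eeg_list) or not stim_list:
            raise ValueError("need matching, nonempty stimulus and EEG lists")
        rates = {e.rate for e in eeg_list}
        if len(rates) != 1:
            raise ValueError("all trials must share the sampling rate")
        d = {e.n_channels for e in eeg_list}
        if len(d) != 1:
            raise ValueError("all trials must share the channel count")
        self.n_lags = int(n_lags)
        self.n_components = int(n_components)
        self.var_frac = var_frac
        self.stim_rtol = float(stim_rtol)
        self.boundaries = np.cumsum(
            [0] + [e.n_samples for e in eeg_list])  # trial edges in pooled time
        self.s_emb = np.vstack([temporal_embed(s, self.n_lags)
                                for s in stim_list])
        self.eeg_data = np.hstack([e.data for e in eeg_list])
        self.valid_channels = np.logical_and.reduce(
            [e.valid_channels for e in eeg_list])
        self.valid_samples = np.hstack([e.valid_samples for e in eeg_list])

    def fit(self) -> SRCResults:
        L = self.n_lags
        d_valid = np.flatnonzero(self.valid_channels)
        D = self.valid_channels.size
        if self.var_frac is None and self.n_components > min(L, d_valid.size):
            raise ValueError("k_components must be <= min(L, D)")
        r = self.eeg_data[d_valid]
        m_r = self.valid_samples[d_valid]
        m_s = np.ones_like(self.s_emb.T, dtype=bool)

        sc = _masked_center(self.s_emb.T, m_s)      # L x T
        rc = _masked_center(r, m_r)                  # D_eff x T

        css = _pairwise_cov(sc, m_s, sc, m_s)
        crr = _pairwise_cov(rc, m_r, rc, m_r)
        csr = _pairwise_cov(sc, m_s, rc, m_r)

        # EEG covariance truncation (regularization)
        vals, vecs = np.linalg.eigh(0.5 * (crr + crr.T))
        order = np.argsort(vals)[::-1]
        vals, vecs = np.maximum(vals[order], 0.0), vecs[:, order]
        if self.var_frac is not None:
            csum = np.cumsum(vals) / max(vals.sum(), 1e-30)
            k = int(np.searchsorted(csum, self.var_frac) + 1)
        else:
            k = self.n_components
        k = min(k, int((vals > 1e-12 * max(vals[0], 1e-30)).sum()))
        if k < 1:
            raise ValueError("EEG has no variance on the valid channels")
        basis = vecs[:, :k]
        crr_p = basis.T @ crr @ basis
        csr_p = csr @ basis

        _, exact_rank = _inv_sqrt_psd(css)
        if exact_rank < L:
            warnings.warn("stimulus embedding is rank deficient; "
                          f"effective lag rank {exact_rank}", RuntimeWarning,
                          stacklevel=2)
        ws, rank_s = _inv_sqrt_psd(css, rtol=self.stim_rtol)
        wr, _ = _inv_sqrt_psd(crr_p)
        m = ws @ csr_p @ wr
        p, sing, qt = np.linalg.svd(m)
        k_cca = min(rank_s, k)
        rho = np.clip(sing[:k_cca], 0.0, 1.0)

        n_valid = int(self.valid_samples[d_valid].all(axis=0).sum())
        if n_valid < 10 * (L + k):
            warnings.warn("few valid samples relative to model dimension",
                          RuntimeWarning, stacklevel=2)

        h = (ws @ p[:, :k_cca]).T                       # k_cca x L
        w_p = (wr @ qt.T[:, :k_cca])                    # k x k_cca
        w_eff = basis @ w_p                             # D_eff x k_cca
        denom = np.einsum("ij,jk,ki->i", w_eff.T, crr, w_eff)
        a_eff = (crr @ w_eff) / np.maximum(denom, 1e-30)

        w_full = np.zeros((k_cca, D))
        a_full = np.zeros((k_cca, D))
        w_full[:, d_valid] = w_eff.T
        a_full[:, d_valid] = a_eff.T

        # sign convention: largest-magnitude coefficient of h_j positive;
        # flip (h, u) and (w, a, v) together so rho is unchanged
        signs = np.sign(h[np.arange(k_cca), np.argmax(np.abs(h), axis=1)])
        signs[signs == 0] = 1.0
        h *= signs[:, None]
        w_full *= signs[:, None]
        a_full *= signs[:, None]

        u = sc.T @ h.T
        v = (w_full[:, d_valid] @ rc).T

        return SRCResults(
            model=self, rho=rho, temporal_filters=h, spatial_filters=w_full,
            forward_models=a_full, u=u, v=v,
            pca_eigvecs=basis, pca_eigvals=vals[:k],
            n_samples_used=n_valid,
        )


# ---------------------------------------------------------------------------
# functional surface


def fit_cca(s_emb: np.ndarray, eeg: EEGRecording,
            k_components: int = 11,
            var_frac: float | None = None,
            stim_rtol: float = 0.05) -> SRCResults:
    """Fit the truncated CCA from a pre-built lag matrix and one recording."""
    s_emb = np.asarray(s_emb, dtype=float)
    if s_emb.shape[0] != eeg.n_samples:
        raise ValueError("lag matrix and EEG must have equal sample counts")
    model = StimulusResponseCCA.__new__(StimulusResponseCCA)
    model.n_lags = s_emb.shape[1]
    model.n_components = int(k_components)
    model.var_frac = var_frac
    model.stim_rtol = float(stim_rtol)
    model.boundaries = np.array([0, eeg.n_samples])
    model.s_emb = s_emb
    model.eeg_data = eeg.data
    model.valid_channels = eeg.valid_channels
    model.valid_samples = eeg.valid_samples
    return model.fit()


def total_src(decomp: SRCResults | SRCResult | np.ndarray) -> SRCResult:
    """Total SRC = sum over components of rho_j."""
    if isinstance(decomp, SRCResults):
        return decomp.src_result()
    if isinstance(decomp, SRCResult):
        return decomp
    rho = np.asarray(decomp, dtype=float)
    if rho.size == 0:
        raise ValueError("need at least one component")
    return SRCResult(per_component=rho)


def project(decomp: SRCResults, s: StimulusFeature | np.ndarray,
            eeg: EEGRecording, **kwargs) -> SRCResult:
    """Apply fitted filters to new data (see :meth:`SRCResults.project`)."""
    return decomp.project(s, eeg, **kwargs)


def pool_and_fit(sessions, pooling: str = "subject",
                 n_lags: int = 30, n_components: int = 11,
                 var_frac: float | None = None,
                 stim_rtol: float = 0.05):
    """Fit CCA on data pooled across conditions (and optionally subjects).

    ``sessions`` is a list of SimulatedSession-like objects (with per-trial
    ``stimulus`` / ``eeg`` lists).  With ``pooling='subject'`` (default, the
    common-basis-per-subject scheme) returns one SRCResults per session;
    with ``pooling='all'`` returns a single SRCResults over every trial of
    every session.  Trials are embedded independently so lags never span
    trial boundaries.
    """
    if not sessions:
        raise ValueError("need at least one session")
    if pooling == "all":
        stims = [s for sess in sessions for s in sess.stimulus]
        eegs = [e for sess in sessions for e in sess.eeg]
        return StimulusResponseCCA(stims, eegs, n_lags=n_lags,
                                   n_components=n_components,
                                   var_frac=var_frac,
                                   stim_rtol=stim_rtol).fit()
    if pooling == "subject":
        return [
            StimulusResponseCCA(sess.stimulus, sess.eeg, n_lags=n_lags,
                                n_components=n_components,
                                var_frac=var_frac,
                                stim_rtol=stim_rtol).fit()
            for sess in sessions
        ]
    raise ValueError("pooling must be 'subject' or 'all'")
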