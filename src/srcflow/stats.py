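"""Alpha-band power maps and the nonparametric statistical battery.

* alpha_power: zero-phase 4th-order Butterworth band-pass (8-12 Hz) per
  channel, then the temporal mean square — one power value per electrode.
* wilcoxon_signed_rank: paired test on per-subject values; exact null
  distribution (by convolution over the rank generating function) for small
  tie-free samples, normal approximation with tie and continuity corrections
  otherwise.  The z statistic is always reported from the approximation.
* rank_sum: Mann-Whitney/rank-sum for independent subgroups.
* permutation_condition_test: paired label-swap (sign-flip) permutation null
  for group-average difference maps over electrodes or lags, with
  Benjamini-Hochberg FDR across map entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats as sps

from .preprocess import EEGRecording

__all__ = [
    "AlphaPowerMap",
    "PermutationTestResult",
    "alpha_power",
    "wilcoxon_signed_rank",
    "rank_sum",
    "permutation_condition_test",
    "fdr_bh",
]


@dataclass
class AlphaPowerMap:
    """Per-channel band power (uV^2) for one subject x condition."""

    power: np.ndarray
    band: tuple[float, float] = (8.0, 12.0)
    condition: str | None = None
    subject: str | None = None

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float).ravel()
        if np.any(self.power < -1e-12):
            raise ValueError("band power must be nonnegative")


@dataclass
class PermutationTestResult:
    """Observed difference map, its permutation null, p-values, FDR mask."""

    observed: np.ndarray
    null: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    n_perm: int
    q: float


def alpha_power(
    eeg: EEGRecording,
    band: tuple[float, float] = (8.0, 12.0),
    order: int = 4,
    condition: str | None = None,
    subject: str | None = None,
) -> AlphaPowerMap:
    """Band-limited power per channel: mean square of the band-passed signal.

    Power is computed over each channel's valid samples; fully rejected
    channels get power 0.
    """
    lo, hi = band
    if not (0 < lo < hi < eeg.rate / 2):
        raise ValueError("band must lie strictly inside (0, Nyquist)")
    sos = signal.butter(order, [lo, hi], btype="band", fs=eeg.rate,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, eeg.data, axis=1)
    power = np.zeros(eeg.n_channels)
    for c in range(eeg.n_channels):
        if not eeg.valid_channels[c]:
            continue
        m = eeg.valid_samples[c]
        if m.any():
            power[c] = float(np.mean(filtered[c, m] ** 2))
    return AlphaPowerMap(power=power, band=band, condition=condition,
                         subject=subject)


def _signed_rank_exact_sf(n: int, w: float) -> tuple[float, float]:
    """P(W+ <= w) and P(W+ >= w) under the exact tie-free null for n pairs."""
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    total = counts.sum()
    wi = int(round(w))
    return counts[: wi + 1].sum() / total, counts[wi:].sum() / total


def wilcoxon_signed_rank(
    x: np.ndarray,
    y: np.ndarray,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test; returns (z, p).

    Zero differences are excluded, ties get mid-ranks.  For n <= 25 with no
    tied absolute differences the p-value is exact (enumeration of sign
    patterns via the rank generating function); otherwise a normal
    approximation with tie and continuity corrections is used.  The z
    statistic always comes from the approximation.  ``alternative`` is
    'two-sided' or 'greater' / 'less' (x vs y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-d samples")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero; test undefined")
    if n < 5:
        raise ValueError("need at least 5 nonzero differences")
    absd = np.abs(d)
    ranks = sps.rankdata(absd)
    w_plus = float(ranks[d > 0].sum())

    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(absd, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    sd = np.sqrt(var)
    cc = 0.5 * np.sign(w_plus - mean)
    z = (w_plus - mean - cc) / sd if sd > 0 else 0.0

    has_ties = np.any(tie_counts > 1)
    if n <= 25 and not has_ties:
        cdf, sf = _signed_rank_exact_sf(n, w_plus)
        if alternative == "greater":
            p = sf
        elif alternative == "less":
            p = cdf
        else:
            p = min(1.0, 2.0 * min(cdf, sf))
    else:
        if alternative == "greater":
            p = float(sps.norm.sf((w_plus - mean - 0.5) / sd))
        elif alternative == "less":
            p = float(sps.norm.cdf((w_plus - mean + 0.5) / sd))
        else:
            p = float(2.0 * sps.norm.sf(abs(z)))
        p = min(1.0, p)
    return float(z), float(p)


def _rank_sum_exact_sf(n1: int, n2: int, u: float) -> tuple[float, float]:
    """P(U <= u), P(U >= u) for the exact Mann-Whitney null (no ties)."""
    max_u = n1 * n2
    # DP: number of subsets of size n1 from ranks {1..N} with a given rank
    # sum; U = (rank sum of group A) - n1(n1+1)/2
    N = n1 + n2
    min_s = n1 * (n1 + 1) // 2
    max_s = min_s + max_u
    table = np.zeros((n1 + 1, max_s + 1))
    table[0, 0] = 1.0
    for r in range(1, N + 1):
        for k in range(min(n1, r), 0, -1):
            table[k, r:] += table[k - 1, :-r] if r > 0 else table[k - 1]
    dist = table[n1, min_s : max_s + 1]
    total = dist.sum()
    ui = int(round(u))
    return dist[: ui + 1].sum() / total, dist[ui:].sum() / total


def rank_sum(
    x: np.ndarray,
    y: np.ndarray,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Wilcoxon rank-sum (Mann-Whitney) test; returns (U statistic, p).

    Exact p (rank-sum distribution by dynamic programming) for tie-free
    samples with n1 + n2 <= 25, normal approximation with tie and continuity
    corrections otherwise.  ``alternative``: 'two-sided', 'greater' or
    'less' (x vs y).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    r1 = float(ranks[:n1].sum())
    u = r1 - n1 * (n1 + 1) / 2.0          # Mann-Whitney U for x

    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = np.any(tie_counts > 1)
    if (n1 + n2) <= 25 and not has_ties:
        cdf, sf = _rank_sum_exact_sf(n1, n2, u)
        if alternative == "greater":
            p = sf
        elif alternative == "less":
            p = cdf
        else:
            p = min(1.0, 2.0 * min(cdf, sf))
    else:
        mean = n1 * n2 / 2.0
        N = n1 + n2
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (N * (N - 1))
        var = n1 * n2 / 12.0 * (N + 1 - tie_term)
        sd = np.sqrt(var)
        if alternative == "greater":
            p = float(sps.norm.sf((u - mean - 0.5) / sd))
        elif alternative == "less":
            p = float(sps.norm.cdf((u - mean + 0.5) / sd))
        else:
            cc = 0.5 * np.sign(u - mean)
            p = float(2.0 * sps.norm.sf(abs((u - mean - cc) / sd)))
        p = min(1.0, p)
    return float(u), float(p)


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up: boolean mask of discoveries at level q."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def permutation_condition_test(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    n_perm: int = 1000,
    q: float = 0.05,
    seed: int = 0,
) -> PermutationTestResult:
    """Paired permutation test on group-average difference maps.

    ``maps_a`` / ``maps_b`` are (n_subjects, n_entries) paired maps
    (electrodes or lags).  The observed statistic is mean(a) - mean(b); the
    null swaps each subject's condition labels independently with
    probability 1/2 (sign flips of the paired differences), ``n_perm``
    times.  Two-sided p per entry = (1 + #{|null| >= |obs|}) / (n_perm + 1),
    floored at 1/(n_perm+1); BH-FDR across entries at level ``q``.
    """
    a = np.atleast_2d(np.asarray(maps_a, dtype=float))
    b = np.atleast_2d(np.asarray(maps_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("paired maps must have equal shape")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n_subj = a.shape[0]
    diffs = a - b
    observed = diffs.mean(axis=0)
    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
    null = (flips @ diffs) / n_subj
    exceed = (np.abs(null) >= np.abs(observed)[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (n_perm + 1.0)
    significant = fdr_bh(p, q=q)
    return PermutationTestResult(observed=observed, null=null, p_values=p,
                                 significant=significant, n_perm=n_perm, q=q)
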