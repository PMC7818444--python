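"""End-to-end orchestration: simulate (or load) -> pooled CCA fit ->
per-condition SRC -> response functions -> alpha power -> statistics.

``run_pipeline`` executes the full analysis from a :class:`PipelineConfig`
and writes tidy CSV tables plus a JSON run manifest.  Identical config and
seed reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .model import pool_and_fit
from .respfun import condition_response_functions, group_average
from .stats import alpha_power, fdr_bh, permutation_condition_test, \
    wilcoxon_signed_rank
from .synth import generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "run_pipeline"]


@dataclass
class RunManifest:
    """What a pipeline run did: config, versions, outputs, timings."""

    config: dict
    version: str = __version__
    outputs: dict = field(default_factory=dict)   # path -> sha256 digest
    timings_s: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 sessions=None) -> RunManifest:
    """Run the full analysis and write outputs under ``out_dir``.

    If ``sessions`` is None, a cohort is simulated from the config's
    simulation block; otherwise the given list of sessions (each with
    per-trial ``stimulus`` / ``eeg`` / ``condition`` lists) is analyzed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config))
    t0 = time.perf_counter()

    if sessions is None:
        sim = config.simulation
        sessions = generate_cohort(
            n_subjects=sim.n_subjects,
            conditions=[tuple(c) for c in sim.conditions],
            trials_per_condition=sim.trials_per_condition,
            seed=config.seed,
            duration_s=sim.duration_s,
            fs=config.analysis_rate,
            n_channels=sim.n_channels,
            n_components=sim.n_components,
            noise_sd=sim.noise_sd,
            artifact_rate=sim.artifact_rate,
            subject_map_sd=sim.subject_map_sd,
        )
        logger.info("simulated %d subjects", len(sessions))
    manifest.timings_s["simulate_or_load"] = time.perf_counter() - t0
    conditions = list(dict.fromkeys(sessions[0].condition))

    # pooled CCA fit per subject (common basis across conditions)
    t0 = time.perf_counter()
    decomps = pool_and_fit(sessions, pooling="subject",
                           n_lags=config.n_lags,
                           n_components=config.k_components,
                           var_frac=config.var_frac)
    manifest.timings_s["cca_fit"] = time.perf_counter() - t0

    # per-condition SRC by projection onto the common basis
    t0 = time.perf_counter()
    rows = []
    for sess, dec in zip(sessions, decomps):
        for cond in conditions:
            stims = [s for s, c in zip(sess.stimulus, sess.condition)
                     if c == cond]
            eegs = [e for e, c in zip(sess.eeg, sess.condition) if c == cond]
            res = dec.project_pooled(stims, eegs, condition=cond,
                                     subject=sess.subject)
            for j, r in enumerate(res.per_component):
                rows.append({"subject": sess.subject, "condition": cond,
                             "component": j + 1, "rho": r,
                             "total_src": res.total_src})
    src_df = pd.DataFrame(rows)
    src_path = out / "src_by_condition.csv"
    src_df.to_csv(src_path, index=False)
    manifest.timings_s["src_projection"] = time.perf_counter() - t0

    # SRC contrasts (paired Wilcoxon on total SRC)
    totals = src_df.drop_duplicates(["subject", "condition"]).pivot(
        index="subject", columns="condition", values="total_src")
    contrast_rows = []
    for i, c1 in enumerate(conditions):
        for c2 in conditions[i + 1:]:
            z, p = wilcoxon_signed_rank(totals[c1].values, totals[c2].values)
            contrast_rows.append({"measure": "total_src", "a": c1, "b": c2,
                                  "z": z, "p": p})

    # response functions per condition + permutation tests
    t0 = time.perf_counter()
    rf_sets = [condition_response_functions(dec, sess,
                                            config.n_response_components,
                                            config.n_lags)
               for dec, sess in zip(decomps, sessions)]
    group_rf = group_average(rf_sets)
    rf_rows = []
    for cond in conditions:
        for j in range(group_rf.spatial[cond].shape[0]):
            for ch, wgt in enumerate(group_rf.spatial[cond][j]):
                rf_rows.append({"condition": cond, "component": j + 1,
                                "kind": "spatial", "index": ch,
                                "weight": wgt})
            for lag, wgt in enumerate(group_rf.temporal[cond][j]):
                rf_rows.append({"condition": cond, "component": j + 1,
                                "kind": "temporal", "index": lag,
                                "weight": wgt})
    rf_path = out / "response_functions_group.csv"
    pd.DataFrame(rf_rows).to_csv(rf_path, index=False)

    perm_rows = []
    if len(conditions) >= 2 and len(sessions) >= 2:
        c1, c2 = conditions[0], conditions[-1]
        for kind in ("spatial", "temporal"):
            for j in range(config.n_response_components):
                maps_a = np.stack([getattr(s, kind)[c1][j] for s in rf_sets])
                maps_b = np.stack([getattr(s, kind)[c2][j] for s in rf_sets])
                res = permutation_condition_test(
                    maps_a, maps_b, n_perm=config.n_perm, q=config.q,
                    seed=config.seed + 1000 + j)
                for idx in range(res.observed.size):
                    perm_rows.append({
                        "kind": kind, "component": j + 1, "index": idx,
                        "a": c1, "b": c2,
                        "difference": res.observed[idx],
                        "p": res.p_values[idx],
                        "significant": bool(res.significant[idx]),
                    })
    perm_path = out / "response_function_contrasts.csv"
    pd.DataFrame(perm_rows).to_csv(perm_path, index=False)
    manifest.timings_s["response_functions"] = time.perf_counter() - t0

    # alpha power maps + channel-wise Wilcoxon with FDR
    t0 = time.perf_counter()
    alpha_rows = []
    alpha_maps: dict[str, list[np.ndarray]] = {c: [] for c in conditions}
    for sess in sessions:
        for cond in conditions:
            powers = [alpha_power(e, band=tuple(config.alpha_band),
                                  order=config.alpha_filter_order).power
                      for e, c in zip(sess.eeg, sess.condition) if c == cond]
            mean_map = np.mean(powers, axis=0)
            alpha_maps[cond].append(mean_map)
            for ch, val in enumerate(mean_map):
                alpha_rows.append({"subject": sess.subject,
                                   "condition": cond, "channel": ch,
                                   "alpha_power": val})
    alpha_path = out / "alpha_power.csv"
    pd.DataFrame(alpha_rows).to_csv(alpha_path, index=False)

    alpha_sig_rows = []
    for i, c1 in enumerate(conditions):
        for c2 in conditions[i + 1:]:
            a = np.stack(alpha_maps[c1])
            b = np.stack(alpha_maps[c2])
            ps, zs = [], []
            for ch in range(a.shape[1]):
                z, p = wilcoxon_signed_rank(a[:, ch], b[:, ch])
                zs.append(z)
                ps.append(p)
            sig = fdr_bh(np.array(ps), q=config.q)
            for ch in range(a.shape[1]):
                alpha_sig_rows.append({
                    "a": c1, "b": c2, "channel": ch,
                    "difference": a[:, ch].mean() - b[:, ch].mean(),
                    "z": zs[ch], "p": ps[ch],
                    "significant": bool(sig[ch]),
                })
    alpha_sig_path = out / "alpha_contrasts.csv"
    pd.DataFrame(alpha_sig_rows).to_csv(alpha_sig_path, index=False)
    contrast_path = out / "src_contrasts.csv"
    pd.DataFrame(contrast_rows).to_csv(contrast_path, index=False)
    manifest.timings_s["alpha_and_stats"] = time.perf_counter() - t0

    for p in (src_path, contrast_path, rf_path, perm_path, alpha_path,
              alpha_sig_path):
        manifest.outputs[p.name] = _digest(p)
    manifest.save(out / "manifest.json")
    manifest.outputs["manifest.json"] = "self"
    return manifest
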