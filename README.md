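# srcflow

Stimulus–response correlation (SRC) analysis for continuous visual stimuli
and multichannel EEG.

When people watch dynamic natural stimuli — video, gameplay, movies — the
EEG contains a continuous evoked response that tracks low-level stimulus
features such as the overall optic flow. `srcflow` measures the strength of
that response as the temporal correlation between a scalar stimulus feature
and the multichannel neural signal, and provides everything around that
measurement: stimulus feature extraction from video, EEG preprocessing,
condition-wise response functions, alpha-band power maps, and the
nonparametric statistics used to compare experimental conditions. A
first-class synthetic-data module simulates whole multi-subject studies
with known ground truth, so the entire analysis chain is testable without
access to human recordings.

It is written for EEG/neural-signal researchers working with naturalistic,
continuous stimuli (passive viewing, video games, brain–computer-interface
style paradigms) who want a tested, reproducible SRC pipeline.

## The model

Let s(t) be a z-scored scalar stimulus feature (e.g. mean optic-flow
magnitude per frame) and r_i(t), i = 1..D the EEG channels. The stimulus is
temporally filtered and the response spatially filtered,

    u(t) = Σ_τ h(τ) s(t − τ),        v(t) = Σ_i w_i r_i(t),

and canonical correlation analysis finds the filter pairs (h_j, w_j),
j = 1..K, that maximize the Pearson correlation ρ_j = corr(u_j, v_j), with
successive component pairs mutually uncorrelated. Only causal lags
τ = 0..L−1 enter (the EEG lags the stimulus); L = 30 samples at the 30 Hz
analysis rate spans 0–967 ms. The EEG side is regularized by truncating the
eigenvalue spectrum of its covariance (default K = 11 dimensions, or a
configured variance fraction). The dependent measure is the **total SRC**

    SRC = Σ_{j=1..K} ρ_j ,

and each component's forward model a_j = C_rr w_j / (w_jᵀ C_rr w_j) gives
the scalp pattern ("spatial response function") through which the component
is expressed; h_j(τ) is its temporal response function, the analog of an
event-related potential for a continuous stimulus.

Condition comparisons use paired two-tailed Wilcoxon signed-rank tests on
per-subject total SRC and alpha-band (8–12 Hz) power, and a paired
label-swap permutation test with Benjamini–Hochberg FDR control across
electrodes or lags for response-function maps.

## Worked example

Simulate one trial with three planted response components and recover them:

```python
import numpy as np
from srcflow.synth import generate_stimulus, generate_ground_truth, generate_eeg
from srcflow.model import StimulusResponseCCA
from srcflow.video import StimulusFeature

truth = generate_ground_truth(n_channels=96, n_components=3, seed=1)
raw = generate_stimulus(176.0, fs=30.0, seed=2)       # flow-like feature
eeg = generate_eeg(raw, truth, "passive", seed=3)      # 96-channel EEG
stim = StimulusFeature(values=(raw - raw.mean()) / raw.std(), rate=30.0)

res = StimulusResponseCCA(stim, eeg, n_lags=30, n_components=11).fit()
print(res.summary())
```

```
Stimulus-Response CCA Results
==============================================
Components                                   6
Lags (L)                                    30
Channels (D)                                96
Samples used                              5280
Total SRC                               0.8750
----------------------------------------------
component            rho    peak lag
1                 0.3313           6
2                 0.2051          11
3                 0.1519          17
4                 0.0818          28
5                 0.0602           0
6                 0.0446          29
==============================================
```

The three planted components are recovered as the three leading canonical
pairs: ρ₁ = 0.33 with its temporal response peaking at lag 6 (200 ms at
30 Hz), the second at ~400 ms, the third later and weaker — matching the
planted peak latencies and the 0.65-per-component strength decay of the
generator. Components beyond the third carry only chance-level correlation.
`res.project(stim, other_eeg)` applies the same filters to held-out data
(e.g. other experimental conditions over a common basis), and
`res.forward_models` holds the per-channel scalp patterns.

The same analysis runs end-to-end from the shell:

```bash
srcflow run-all --seed 1 --out results/run1/   # simulate + full analysis
srcflow features --video frames_dir/ --feature optic_flow --out feat.tsv
srcflow src --features feat.tsv --eeg clean.h5 --out src.csv
```

`run-all` writes per-subject, per-condition SRC tables, group response
functions, alpha-power maps, all condition contrasts, and a JSON manifest.

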