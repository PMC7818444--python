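# Methods

This note documents the models, numerical choices, and simulation design
behind `srcflow`, in the spirit of a methods appendix: what is computed,
under which assumptions, and what the synthetic-data validation does and
does not establish.

## Stimulus–response correlation via temporally embedded CCA

The core computation correlates a scalar stimulus feature s(t) with a
D-channel EEG recording r(t). The stimulus is lag-embedded into a T × L
matrix whose row t is [s(t), s(t−1), …, s(t−L+1)] (causal lags only — the
brain responds after the stimulus — with zero padding at trial starts, and
embedding restarted at every trial boundary so lags never span trials).
Canonical correlation analysis between the lag matrix and the EEG yields
filter pairs (h_j, w_j) with correlations ρ₁ ≥ ρ₂ ≥ … ≥ ρ_K; the total SRC
is their sum. The solver:

1. estimates C_ss (L × L), C_rr (D × D) and C_sr from samples, pairwise
   over the validity masks (invalid samples are zeroed and excluded from
   each covariance entry's numerator and denominator);
2. truncates the eigenvalue spectrum of C_rr to K dimensions (default
   K = 11, or the smallest K reaching a configured variance fraction) —
   the EEG-side regularization;
3. whitens both sides and reads the canonical pairs off the SVD of the
   whitened cross-covariance;
4. maps spatial filters back to channel space and forms forward models
   a_j = C_rr w_j / (w_jᵀ C_rr w_j).

Component signs are fixed so each temporal filter's largest-magnitude
coefficient is positive. `project()` applies fitted filters to new data
without refitting, which is how per-condition SRCs are computed over a
common basis (filters fitted on data pooled across conditions, by default
per subject).

### Stimulus-side conditioning (`stim_rtol`)

For broadband stimuli the L-lag covariance is well conditioned and CCA
needs no stimulus-side regularization. For narrowband stimuli — and slow,
nonnegative optic-flow traces are strongly low-pass — C_ss is nearly
singular: many filter coefficient vectors produce indistinguishable
filtered stimuli, so the coefficient estimate is dominated by noise in the
near-null directions even when the filtered component u_j(t) itself is
estimated almost perfectly. The whitening therefore truncates stimulus
eigendirections whose variance is below `stim_rtol` (default 0.05) times
the dominant one — the same spectral-truncation regularization applied to
the EEG side. For white or broadband stimuli this floor never triggers
(all eigenvalues are within a factor of a few), so solver-vs-oracle
agreement on generic instances is unaffected. The temporal response
functions reported for slow stimuli are consequently the projections of the
underlying responses onto the stimulus's estimable subspace; structure
outside that subspace is not recoverable from such a stimulus by any
estimator, only suppressed rather than hallucinated here.

## Preprocessing chain

Order: resample → high-pass → robust PCA → ocular regression → iterative
rejection.

* **Resampling**: zero-phase 8th-order Butterworth anti-alias low-pass at
  0.9× the target Nyquist, rational polyphase resampling (500→30 Hz is
  3/50) with linear-extrapolation padding, then a zero-phase 4th-order
  Butterworth high-pass at 1 Hz (channels demeaned first to suppress edge
  transients on offset-dominated channels).
* **Robust PCA** (principal component pursuit, inexact augmented Lagrange
  multipliers): data = L + S with L low-rank (kept) and S sparse
  (discarded); sparse scalp activity is physiologically implausible under
  volume conduction, so S is treated as artifact. The sparsity weight is
  λ/√D by default (λ = 0.5), the convention of the reference inexact-ALM
  implementation for channels × samples input. The classical λ/√max(D,T)
  weight is available (`scaling="max-dim"`) and is the right choice for
  exact low-rank + sparse separation problems, but on long noisy EEG
  matrices it sends the entire recording into S. Convergence:
  ‖data − L − S‖_F / ‖data‖_F < 1e−7 or 500 iterations (warned).
* **Ocular regression**: four virtual electrodes (two summed frontal pairs
  as blink proxies, two differenced lateral pairs as saccade proxies;
  channel sets configurable since montages vary), regressed out of every
  channel by least squares with an intercept. Linearly dependent
  regressors are dropped with a warning. The operation is a projection and
  hence idempotent.
* **Iterative rejection** (defaults: 4 SD, 3 iterations): per iteration,
  channels whose mean power exceeds the across-channel mean by 4 SD are
  invalidated, then within each channel samples whose |amplitude| exceeds
  the mean absolute amplitude by 4 SD are invalidated together with their
  immediate neighbors. Statistics are recomputed from surviving entries
  each iteration; masks only ever shrink. Rejected entries are zeroed and
  the masks are honored by all covariance estimators downstream. Note the
  mean + 4 SD channel rule requires a reasonably large montage: a single
  ×10-power outlier among ~16 channels inflates the SD enough to mask
  itself, while at ≥64 channels it is flagged reliably.

## Stimulus features from video

Frames are converted to luminance (ITU-R BT.601 weights) and resized to
320 × 180 by exact block averaging when the source is an integer multiple,
else by anti-aliased interpolation. Dense optic flow uses the classic
Horn–Schunck formulation: gradients from the original 2×2×2
finite-difference stencils, then Jacobi iterations (default 10) of the
local-average update with smoothness weight α (default 1). Defaults match
common toolbox settings and assume 8-bit-scale intensities; on weak-contrast
imagery (gradients ≪ α) the flow is underestimated and more iterations or a
smaller α are needed. The 2×2 stencils are not exactly rotation-symmetric,
so flow magnitude under 90° frame rotation is preserved only to a few
percent. The scalar features are the per-frame-pair spatial means of the
flow magnitude and of the absolute frame difference (temporal contrast;
rectification is the default because a signed mean cancels on
pan-dominated content, and is switchable). Features are averaged over
adjacent frame groups to reach the EEG analysis rate (60→30 Hz: pairwise
mean) and z-scored; constant series raise a degenerate-input error rather
than silently becoming zeros.

## Statistics

* **Alpha power**: zero-phase 4th-order Butterworth band-pass (8–12 Hz at
  the 30 Hz analysis rate), then the temporal mean square per channel over
  valid samples; per-subject values average the subject's trials within a
  condition.
* **Wilcoxon signed-rank** (paired, two-tailed by default): zero
  differences excluded, mid-ranks for ties; exact p by the rank generating
  function for n ≤ 25 without ties, otherwise a normal approximation with
  tie and continuity corrections. The z statistic is always reported from
  the approximation. **Rank-sum** follows the same pattern (exact by
  dynamic programming for n₁+n₂ ≤ 25 tie-free).
* **Permutation test for paired maps**: observed statistic is the
  group-mean condition difference per entry; the null swaps each subject's
  condition labels independently with probability ½ (sign flips of paired
  differences — the exchangeable null for a paired design); two-sided
  p = (1 + #{|null| ≥ |obs|})/(n_perm + 1), floored at 1/(n_perm+1);
  Benjamini–Hochberg across entries at q = 0.05.

A discreteness limit worth knowing: with n_perm = 1,000 the smallest
attainable p is 1/1001 ≈ 1e−3, which exceeds the k = 1 step-up threshold
q/m for m = 96 electrodes (5.2e−4). A solitary effect at one electrode
therefore cannot survive FDR at this permutation count regardless of its
size; over m = 30 lags (threshold 1.7e−3) it can, and effects spanning
several electrodes raise the step-up threshold enough to be detectable.
The planted-effect validation uses the 30-entry lag maps for this reason.

## The synthetic study

The generator emulates a within-subject visual-engagement experiment:
n = 18 subjects, conditions with 2 trials each, ~176 s trials at 30 Hz,
96 channels.

* **Stimulus**: squared low-pass-filtered Gaussian noise — nonnegative,
  skewed, and slowly varying like the optic flow of gameplay video. The
  pre-squaring filter cutoff is half the nominal cutoff (default 3 Hz) so
  that squaring, which doubles bandwidth, leaves the feature band-limited
  below the nominal cutoff.
* **Evoked structure**: K response components, each the causal convolution
  of the standardized stimulus with a unit-norm temporal filter h_j,
  projected through a spatial map a_j. Default peak latencies deliver lags
  6 and 12 (200/400 ms) for the two leading components. The default
  filters are confined to the 5 dominant principal directions of the
  stimulus-process lag covariance and symmetrically (Löwdin)
  orthogonalized under that covariance, so the planted component drives
  are mutually uncorrelated — the uncorrelatedness CCA imposes, and the
  condition under which planted filters are identifiable at all. Spatial
  maps are smooth random channel profiles, orthogonalized, with strengths
  decaying 0.65 per component so the component order is well defined, as
  in empirical component spectra.
* **Noise**: 1/f-shaped temporally colored noise with short-range channel
  correlation; the default scale (noise_sd = 3.2 µV against unit-scale
  maps) puts ρ₁ near 0.3 at the study's trial length — the total-SRC
  operating range reported for real recordings of this kind.
* **Condition effects**: a multiplicative response gain (engaged
  conditions 1.25 vs passive 1.0) and a 10 Hz alpha sinusoid of
  condition-dependent amplitude (stronger in passive viewing: 2 vs 1 µV)
  with random phase on a central channel block — the
  motor-engagement/alpha-desynchronization signature.
* **Artifacts**: ~60 ms triangular high-amplitude transients at a
  configurable rate (long enough to survive the 500→30 Hz anti-alias
  chain, like real electrode/muscle artifacts), and a 200 ms biphasic
  blink-like pulse projected onto the 8 frontal channels.
* **Subjects** share temporal filter shapes; their spatial maps are the
  group maps plus Gaussian perturbations (SD 0.2, renormalized),
  providing the between-subject variability group statistics need.
* **Stimulus sharing**: by default every condition reuses the same
  per-trial stimuli, so the condition manipulation is purely the planted
  gain/alpha effect and the equal-gain null is exchangeable (paired tests
  calibrate at nominal level). The playback design of real deception
  studies — fixed but different stimuli per condition — is available as
  `stimulus_sharing="per-condition"`; note it confounds stimulus content
  with condition and inflates the paired-test rejection rate under the
  null, in simulation as in reality.

### What passing tests show, and what they do not

The simulation shares the analysis model's structure (linear
convolution-plus-map responses, additive noise), so recovery results
validate the estimator and the statistical machinery — not the linear
model's adequacy for real cortex. Real EEG departures not emulated here:
nonstationary noise and drifting impedances, eye movements beyond discrete
blinks, somatosensory/motor potentials in active play, non-Gaussian and
spatially structured artifact topographies, and stimulus features whose
spectra differ from the squared low-pass process. Calibration results
(type-I rates, FDR behavior) depend only on the exchangeability structure
and transfer more directly.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use these sizes, chosen
to exercise the study conditions that matter while staying desk-scale:
solver-oracle agreement on 50 instances (D = 4–8, L = 2–4, T = 500);
noiseless and noisy (20 seeds) recovery at the full D = 96, 176 s trial;
condition-contrast power and type-I over 50 simulated cohorts each
(n = 18 paired, 2 trials/condition, D = 24 — the contrast operates on
per-subject totals, so the montage size is not the load-bearing factor);
permutation/FDR calibration over 100 null repetitions at 96 entries with
n_perm = 500, planted-effect detection over 20 runs at 30 entries with
n_perm = 1,000; alpha-topography replication over 20 cohorts (D = 32,
60 s trials). The pipeline smoke tests run a 6-subject, 30 s, 12-channel
study end to end.

## Known limitations

* Temporal filter coefficients for narrowband stimuli are identified only
  within the stimulus's estimable subspace (see stimulus-side
  conditioning above).
* The Horn–Schunck implementation is the classic single-scale algorithm:
  it underestimates large displacements (> a few px/frame) and
  low-contrast motion; no pyramid scheme is provided.
* Robust PCA assumes the artifact term is sparse in the channel × time
  matrix; spatially broad, sustained artifacts (e.g. sweating drifts) are
  not separated and must be handled by the high-pass and rejection stages.
* The mean + 4 SD channel-rejection rule self-masks single extreme
  outliers on small montages (≲ 32 channels).
* Exact Wilcoxon/rank-sum modes require tie-free data; with ties the
  normal approximation (tie-corrected) is used at any n.
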