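# Methods

This note documents the models, parameter choices, and numerical decisions
behind `grcbasis`, and states what the synthetic-data generator does and
does not emulate.

## The scientific setting

Mice grasp a robotic manipulandum and self-initiate ~8 mm forward pushes;
a water reward follows the end of a successful (>7 mm) reach after a fixed
delay of 1, 1.1, or 2 s, withheld on a random 20% of trials.  Two-photon
imaging records granule-cell (GrC) somatic fluorescence and Purkinje-cell
dendritic fluorescence — the latter reporting complex spikes and hence
climbing-fiber (CF) input — at 30 or 22.5 Hz, alongside 200 Hz behavioral
streams.  In expert animals many GrCs carry "anticipatory" activity that
spans the delay with heterogeneous kinetics, and reward triggers
time-locked CF spiking.  The package's core computation asks whether
classical CF-gated plasticity, applied to that basis, grades GrC→PkC
synapses by each GrC's anticipatory timing and thereby supports
delay-tracking Purkinje-cell output.

## Plasticity model

For each included CF j (those whose trial-averaged rate over [0, 0.25] s
after reward exceeds the [−0.3, −0.025] s pre-reward average) and each of
its reward-evoked spikes (spike time within [0, 0.25] s of a delivery), the
LTD event magnitude for GrC i is

    m_ij(t_spike) = 1 / (1 + exp(−F / s_i)),
    F = mean z-scored activity of GrC i over [t_spike − 0.150, t_spike − 0.025] s,

with F rectified at zero by default (only activity above baseline drives
depression) and s_i the 95th percentile of GrC i's full-session z-scored
trace.  Event magnitudes are averaged over all (trial, spike) events pooled
— the alternative per-trial-then-across-trial average differs only when
spike counts vary across trials, and is not exposed separately.  Each
per-CF weight vector is normalized to unit sum (a stand-in for homeostatic
maintenance of total synaptic drive), mean-subtracted (a stand-in for the
interneuron network; a strictly positive weighted sum would just resemble
the population average), averaged across CFs, and negated for the sign of
depression.  Mean subtraction and cross-CF averaging commute; the order
used is subtract-then-average.  Omission trials deliver no reward and
therefore contribute no teaching events.

Degenerate GrCs whose logistic scale is non-positive are assigned the
neutral magnitude 0.5 (the no-activity floor) with a logged warning, so
weight vectors always have one entry per GrC and the normalization
invariants hold unconditionally.

**LTP variant.**  Potentiation opposes depression at timepoints where a
CF's firing rate is lowest.  Because smoothed CF rates are exactly zero at
most frames, "the bottom 0.5% of timepoints by rate" is implemented as a
count — the 0.5% of within-trial timepoints with the lowest rate, ties
broken by a seeded shuffle — rather than a threshold, which would select
every zero-rate frame.  LTP magnitudes use the same eligibility window and
logistic bound; the net per-(CF, GrC) effect is the LTD sum minus the LTP
sum, followed by the same normalization chain, so a CF with no selected
low-rate timepoints reduces exactly to pure LTD.  CFs whose net depression
sum is non-positive (background-only CFs with few reward-window spikes)
are skipped with a logged warning.

**Controls.**  `time_shuffled` permutes each GrC's frames independently
within every trial span before rerunning the full LTD pipeline (each cell
keeps its per-trial value distribution, loses its timing);  `reordered`
permutes the true session vector across GrCs (the weight multiset is
preserved);  `uniform` is the simple GrC average — its session vector is
identically zero after mean subtraction, so its readout uses the
pre-subtraction uniform weights.

## Readout and decoding

A readout is `r(t) = w · z(t)` per frame and trial.  Timing quality is the
pooled Pearson correlation between the readout and the frame time across
all (trial, frame) samples, and timing accuracy is its square over a stated
window; the pooled (not per-trial-averaged) form is used throughout.  For
display, the trial-averaged readout is affinely mapped onto the delay time
range, oriented by the correlation sign.

Time decoding is 10-fold cross-validated ordinary least squares with
intercept: trials are concatenated along the time axis into an
(n_trials × T, n_cells) design matrix with the relative time axis
(−delay → 0 s) as target.  Folds partition **trials**, never frames, to
avoid temporal leakage; held-out predictions exist for every (trial,
frame) exactly once, and R²/MAE are computed on the pooled held-out
predictions.  OLS is refused when cells outnumber training samples (a
ridge fallback is available by flag).  The post-reward control decodes
[1, 2] s after reward — beyond the consumption epoch, which carries its own
stereotyped signals and is treated separately.

## Signal conditioning

The chain is bleach correction → detrending → noise z-scoring.

* **Bleach**: `c + a1·exp(−t/τ1) + a2·exp(−t/τ2)` is fit to the
  frame-averaged fluorescence (non-negative bounds, data-derived initial
  values); every trace is divided by the fit.
* **Detrend**: a moving windowed 10th percentile (GrCs: 10 s window, CF
  dendrites: 5 s) is subtracted.
* **Noise z-score**: a slow moving median (2 min / 1 min), computed
  excluding samples above the cell's 99th percentile, centers the noise on
  zero; a slow moving standard deviation of the remaining sub-zero samples
  estimates the lower half-normal width, and the full noise σ follows from
  σ = sd_subzero / √(1 − 2/π).  Dividing by the corrected σ is the default;
  dividing by the raw half-width is available by flag.  All moving
  statistics use centered windows, truncated at the edges, evaluated at
  anchor points (stride = window/8) and linearly interpolated — these are
  slow baselines, for which anchored interpolation is numerically
  equivalent to exact rolling statistics.

**Spike inference.**  The inverse first-order kernel
`d[t] = f[t] − f[t−1]·exp(−Δt/τ)` (τ = 150 ms) is thresholded at 1.9 times
the standard deviation of `d`, with consecutive-frame crossings merged into
one event.  The s.d. is deliberately the *plain* standard deviation of the
deconvolved signal, transients included: with the fixed 1.9 multiplier, a
noise-only (robust/MAD) calibration would fix the false-positive rate at
Q(1.9) ≈ 2.9% per frame — 0.7–0.9 spurious events per second at these frame
rates, swamping a ~1 Hz spike train regardless of SNR.  Including the
transients lets the threshold adapt upward with signal content, which is
what makes the fixed multiplier workable; the MAD estimator remains
available as an option.  Rates are event trains convolved with a unit-area
Gaussian of 200 ms FWHM (kernel mass is clipped only at trace boundaries),
so the integral of rate × dt equals the event count.

## Behavior

Reach end is the first time the y-position comes within 0.5 mm of its
maximum; mid is the first crossing of 4 mm; start is the latest time before
mid at which the 100-ms-boxcar-smoothed speed (central-difference velocity)
falls below 15 mm/s.  Only reaches exceeding 7 mm count as trials.  Trials
are invalid for lick analysis if the sensor is high for more than 90% of
any continuous 1.5 s block within the trial span.  Lick rates smooth sensor
0→1 transitions with a 150 ms FWHM Gaussian (the rate-signal smoothing
parameter is otherwise unconstrained).  Lick preference is
(late − early)/(late + early) over [−0.2, 0] vs [−0.8, −0.6] s before
reward; the lick off-time is the last time (≤ 2 s) the rate exceeds 70% of
its peak over [−0.25, 0.5] s, defined as 0 when the rate never falls below
50% of that peak — the 50% rule takes precedence when the rate dips between
the two thresholds.

## Classification

Anticipatory GrCs: trial-average activity over [−0.3, −0.03] s before
reward exceeds both the early flank [−1.3, −1] s and the post-reward flank
[0.3, 0.5] s by more than 0.1 z-scores.  Reward CFs: standardized rate over
[0, 0.2] s exceeds 0.1 and the pre-reward [−0.3, −0.03] s rate by 0.1; CF
rates are standardized per cell against their whole-session mean and s.d.
(rates are non-negative, so the sub-zero normalization does not apply, and
a within-delay baseline would misclassify delay-suppressed CFs).  General
modulation uses a two-sided paired Wilcoxon signed-rank test on per-trial
window means at p < 0.05 combined with a |mean difference| > 0.2 z-score
magnitude rule.  The anticipatory center time is the rectified
activity-weighted centroid of the trial average within the delay window
(an elevated-timepoint variant is exposed by flag); elevated duration uses
a 0.1 z-score margin above the pre-movement baseline, mirroring the
anticipatory threshold.  The CF onset-time threshold (20th percentile of
the reward response in [0, 0.2] s) is defined on rewarded trials and
applied as a fixed threshold to omission-trial traces.

## Synthetic sessions

The generator emulates the statistical structure the analysis assumes, at
the recorded scale (defaults: 143 GrCs, 55 CFs, 110 trials, 1.1 s delay,
20% omissions, 30 Hz imaging, 200 Hz behavior, 34% anticipatory GrCs, 50%
reward CFs on a 1 Hz background, τ = 150 ms indicator).

* **Anticipatory basis** (experts): piecewise-linear profiles in delay
  coordinates.  A 35%/65% mixture of early-peaking cells that ramp down
  across the delay and later-peaking cells that ramp up (peaks uniform up
  to 0.3 s past nominal reward, i.e. still rising when reward truncates
  them).  After its peak each cell decays to a sustained absolute residual
  level `0.08 + 0.5·(peak/delay)` z-scores held until reward — the
  generative form of the empirical observation that near-reward activity is
  a snapshot of a cell's earlier profile, which is precisely what makes the
  basis plasticity-readable.  Amplitudes (U[1,3] zsc) are rescaled so each
  cell's within-trial activity integral is independent of its timing; this
  keeps the time-shuffled plasticity control unbiased by construction.
  Profiles terminate ~0.2 s after reward (jittered, sd 0.1 s) and are
  prolonged by a per-cell U[0.2, 0.6] s on omission trials.  Trial-to-trial
  lognormal gain variability (sd 0.4) is applied.  Because individual cells
  ramp both up and down, the population mean rises across the delay as a
  population-scale property: successive delay-third means increase at
  realistic population sizes, not frame-by-frame.
* **Novices**: brief movement-locked transients with large per-trial timing
  (sd 0.25 s) and amplitude variability — novice responses are unreliable,
  which is what delay-time decoding improves upon with learning.
* **Other GrC classes**: movement transients (15%), consummatory reward
  transients (10%; causal alpha functions with trial-varying latency
  sd 0.25 s — acausal shapes would leak pre-reward information), and
  otherwise-silent cells; every cell additionally emits spontaneous
  background transients (0.05 Hz).
* **CFs**: Poisson background at 1 Hz (15% of cells thinned during the
  delay, emulating anticipatory suppression), reward spikes with per-cell
  probability U[0.65, 0.95] within [0.02, 0.18] s of delivery, replaced on
  omission trials by a late spike near the anticipation off-time, and
  movement-locked spikes in 20% of cells.
* **Noise and nuisance**: per-frame noise is an equal-power sum of white
  (shot-noise-like) and AR(1)-correlated (τ = 0.3 s, neuropil/motion-like)
  components with total s.d. `noise_sigma`; slow drift is a two-sinusoid
  sum at 0.3 × noise s.d.; raw fluorescence is
  `(baseline + gain·signal) × (1 + a1·e^(−t/τ1) + a2·e^(−t/τ2))`.
* **Licking**: inhomogeneous Poisson lick onsets from per-expertise rate
  templates (novice: early-delay licking; expert: quadratic ramp toward
  reward, consummatory burst, truncation after omission), 40 ms contacts.

**What passing tests do and do not show.**  The generator realizes the
structure the analysis assumes — in particular, the timing-ordered residual
is put in by construction, so recovery tests demonstrate that the pipeline
*measures* that structure correctly at realistic SNR, not that real GrCs
have it.  Features of real data not emulated: movie-level artifacts (the
pipeline starts from traces), eye/whisker/body movement covariates,
cross-cell noise correlations beyond the shared bleach/drift processes,
non-Poisson lick dynamics, and session-to-session learning trajectories
(expertise is a discrete switch).

## Problem sizes and numerics

Tests and the acceptance script run sessions of 150 GrCs × 20 CFs ×
90–100 trials (single sessions in a few seconds; the 20-seed
control-separation study in about two minutes), which matches the recorded
per-session scale.  Windowed statistics use anchored interpolation as
described above; eligibility windows with no frame (possible only at
session edges) drop that event; nearest-frame sampling is used for trial
alignment; reach matching tolerates ±0.3 s between expected and delivered
reward; all random draws flow from explicit integer seeds through
`numpy.random.Generator`, making every pipeline run bit-reproducible.

## Known limitations

* The LTD/LTP rule is phenomenological: magnitudes live in (0, 1) via the
  logistic bound, with no saturation dynamics, metaplasticity, or
  interaction between successive spikes.
* All-to-all GrC→PkC connectivity is assumed (a connection-probability
  option exists but defaults off), and each imaged CF stands in for its
  PkC.
* The half-normal noise estimator biases σ upward when transients occupy a
  large fraction of frames (tails leak below the moving median); it is
  accurate at the contamination levels it is specified for (~10% of
  frames).
* Pooled correlation metrics treat frames as exchangeable samples;
  autocorrelation within trials means their nominal p-values (not used for
  inference here) would be anticonservative.
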