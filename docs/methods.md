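# Methods

This document states the generative model behind `afmeg.synthgen`, the
statistical procedures implemented in the analysis modules, the default
parameters with their rationale, and the package's numerical choices and
limitations.

## 1. The simulated paradigm

`SimulationConfig` + `generate_performance` produce a keystroke event
table for a sequenced-performance experiment:

- Each subject plays blocks of short trials; within a trial one pitch
  pattern (4–5 notes) is cycled continuously at the nominal tempo.
- **Position classes**: the first and last ordinal positions of the
  pattern are "boundary" (Bo), all others "within" (In).
- **Altered feedback (AF)**: the heard pitch of a correct keystroke is
  replaced by a different pattern pitch. AF events are spaced uniformly
  8–10 keystrokes apart, with the targeted position class alternating
  (random phase) so Bo and In receive comparable event counts.
  Designated trials per block are perturbation-free.
- **Timing**: IOIs are the nominal interval (60000/tempo ms) plus i.i.d.
  Gaussian noise; after each AF event the *next* IOI is lengthened by
  `slowing_effect[class]` ms (the planted post-feedback slowing).
- **Errors**: each keystroke is a pitch error with probability
  `baseline_error_prob`; within the `error_horizon` keystrokes after an
  AF event the per-keystroke probability is raised by
  `error_boost[class] / error_horizon`, so `error_boost` approximates the
  *window-level* increment in the probability of at least one error — the
  same quantity the windowed error-rate statistic estimates.
- **MEG recordings** (`generate_recording`): trials are laid out
  sequentially with performance-free gaps (the pre-trial gaps provide
  baseline segments for noise-covariance estimation). Sensors are planar
  pairs (horizontal/vertical channel per position). Noise is AR(1) per
  channel; condition-locked effects deposit a Hanning-windowed template
  on a named sensor group in a fixed post-keystroke window. Triggers lag
  keystrokes by the MIDI delay.
- **Forward model** (`generate_forward`): a smooth toy leadfield over a
  random 3-D grid below the sensor plane. The h/v channels of a pair
  respond to the x/y displacement of a source weighted by a Gaussian
  distance falloff (planar-gradient-like sensitivity); columns are
  optionally smoothed across neighbouring grid points. Grid points are
  partitioned into 2/4/8 coordinate-octant regions.

### What the generator emulates, and what it does not

Emulated: the event structure of the paradigm (spacing rule,
perturbation-free trials, position classes), planted and recoverable
timing/error/ERF effects per condition, planar sensor geometry with
spatial adjacency, AR(1)-correlated sensor noise, baseline intervals,
trigger latency, and a linear forward mapping with regional structure.

Not emulated: real neural dynamics or component morphology (effects are
Hanning templates, not fERN/P3a waveforms), realistic head geometry or
physical units in the leadfield, learning dynamics across trials
(timing is stationary unless planted), motor variability structure
beyond i.i.d. IOI noise, eye/cardiac artifacts, and between-subject
amplitude variability beyond the noise model.

## 2. Parameters (defaults and rationale)

| Parameter | Default | Unit | Why |
|---|---|---|---|
| `n_subjects` | 20 | — | group size of the emulated study design |
| `tempo` | 200 | bpm | nominal IOI 300 ms |
| `trial_duration` | 23 | s | trial length of the emulated design |
| `trials_per_block` | 15 | — | block length of the emulated design |
| `af_spacing` | (8, 10) | keystrokes | AF between every 8th–10th note |
| `af_free_trials` | {1, 6, 10} | — | perturbation-free trials per block |
| `ioi_noise_sd` | 70 | ms | gives cvIOI ≈ 0.23, ordinary skilled-performance variability at this tempo |
| `min_ioi` | 1 | ms | keeps onsets strictly monotonic under noise |
| `baseline_error_prob` | 0.001 | — | rare spontaneous errors so planted boosts dominate the statistic |
| `error_horizon` | 5 | keystrokes | window of the error-rate statistic |
| `midi_trigger_delay` | 22.5 | ms | midpoint of the 20–25 ms trigger-latency range; corrected at epoching |
| `sfreq` | 1000 | Hz | sampling rate |
| `noise_ar1`, `noise_sd` | 0.9, 1.0 | —, a.u. | strongly low-pass sensor noise, typical of band-limited MEG |
| `velocity_mean/sd` | 64 / 8 | MIDI | mid-range key velocity |

Analysis constants (`pipeline.RunConfig`): 5000 rearrangements for
scalar permutation tests, 1000 cluster iterations, q = 0.05 (two-stage
FDR), FWE 0.025 per tail, cluster window 0.15–0.37 s, sanity window
−0.2–0.15 s, epochs −1..1 s, baseline −0.2..−0.1 s, inverse SNR 3,
band-pass 1–100 Hz. Neural problem sizes (`sensor_pairs`, `n_grid`,
`neural_blocks`) are package choices scaled for desk hardware.

## 3. Statistical procedures

- **Paired permutation test**: sign flips of the paired differences;
  `T = mean(x) − mean(y)`; two-sided `p = Pr(|T*| ≥ |T_obs|)` over
  Monte-Carlo flips (exhaustive enumeration of all 2ⁿ patterns for
  n ≤ 20 on request). No +1 correction by default, so p can reach 0 at
  the Monte-Carlo floor; the acceptance tests verify calibration.
- **PS_dep**: `Pr(yᵢ > xᵢ)` over pairs, ties counted 0.5.
- **2×2 factorial**: orthogonal contrasts (main A, main B, interaction)
  of the per-subject cell means, each tested by independent sign-flip
  permutation of its per-subject contrast values (synchronized across
  all points when vectorized).
- **Two-stage adaptive FDR** (linear step-up): stage 1 at
  q′ = q/(1+q) estimates m₀ = m − r₁; stage 2 re-runs the step-up at
  q′·m/m₀. Reported as `p_thr` = largest rejected p, 0 if none.
- **Cluster test**: paired t at every (position, time) point of the
  window; suprathreshold points (|t| > t₍0.975,n−1₎) grouped into
  connected components of the spatial-adjacency × consecutive-samples
  graph, signs never mixing; cluster mass = summed t; the max-mass null
  per sign from per-subject condition swaps; significant when
  p < 0.025 per tail.
- **Minimum-norm inverse**: `M = Lᵀ(LLᵀ + λ²C)⁻¹`, identity source
  covariance, `λ² = tr(LLᵀ)/(n_sensors·SNR²)`, C estimated from
  demeaned baseline segments with diagonal loading `ε·tr(C)/n`
  (ε = 10⁻³). Sources summarized in four 55-ms segments (S1–S4) tiling
  0.15–0.37 s; per-segment grid-point sign-flip tests + two-stage FDR;
  regions reported when their maximal per-segment area of significant
  activation is **equal or larger than** 10%.

## 4. Numerical choices

- **Band-pass filter**: linear-phase FIR designed by least squares
  (`scipy.signal.firls`), odd length ≈ 3.3·sfreq/transition taps,
  applied in a *single centered pass* via overlap-add convolution
  (`mode="same"`). A symmetric FIR with centered alignment is exactly
  zero-phase, and one pass is feasible on long continuous recordings
  where a forward-backward double pass is not. DC is removed first.
- **Vectorized permutation nulls**: sign flips realized as a
  {−1, +1} flip matrix multiplied onto the difference matrix; for
  permuted t-maps, Σd² is invariant under sign flips, so only the
  permuted mean is recomputed per iteration.
- **Matched-control selection**: greedy nearest-neighbour without
  replacement on pooled-z-scored covariates (preceding IOI, velocity);
  tested to be within 10% of the optimal assignment cost on random
  instances. A warning is emitted when post-matching covariate
  imbalance exceeds 0.25 pooled sd.
- **Inverse conditioning**: `λ = 0` with a rank-deficient `LLᵀ` falls
  back to the pseudoinverse (exactly the minimum-norm solution).
- **Reproducibility**: every stochastic stage draws from a
  `numpy.random.Generator`; the pipeline derives independent per-stage
  generators from one seed via `SeedSequence.spawn`, so stage results
  are invariant to the presence of other stages.

## 5. Limitations

- The minimum-norm estimate is depth-biased: peaks migrate toward
  superficial grid points. Localization is therefore validated laterally
  (and, in the acceptance test, on an equal-depth grid); the region
  reports inherit this bias in z.
- The error-rate factorial at n = 20 with realistic error counts is
  low-powered by construction (events with ≥1 error are rare); the
  planted-effect recovery criterion is therefore asserted on the ΔIOI
  interaction, while the error-rate factorial is still computed and
  reported.
- The forward model is a toy: no physical units, no realistic
  conductor geometry, and its regions are coordinate octants, not
  anatomy.
- Monte-Carlo p-values are discrete (granularity 1/n_rearrangements);
  comparisons near the floor should use the exhaustive mode where
  feasible (n ≤ 20).
- The greedy covariate matching is order-dependent and not globally
  optimal; the test suite bounds its suboptimality on random instances
  but pathological pools can do worse.
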