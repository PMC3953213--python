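# Methods

## The pure drift-diffusion model

Evidence is a Wiener process `dX = v dt + s dW` starting at `z` between
absorbing boundaries at 0 and `a`; the decision is the boundary reached,
the decision time is the first-passage time, and the observed RT adds a
non-decision time `t0` for perceptual and motor latencies.  The diffusion
coefficient is fixed at `s = 0.1` (the conventional scaling that makes the
remaining parameters identifiable).  An unbiased starting point is
`z = a/2`.  No across-trial variability parameters are modelled: drift,
boundary separation, starting point and non-decision time are constants
within a condition (the "pure" DDM).

Closed forms: `P(upper) = (1 − e^{−2vz/s²}) / (1 − e^{−2va/s²})` with the
`z/a` limit at `v = 0`, and `E[T] = (a·P(upper) − z)/v` with the
`z(a−z)/s²` limit.  The first-passage density uses the dimensionless
transformation (space scaled by `a`, time by `a²/s²`) and evaluates either
the small-time image expansion or the large-time eigenfunction expansion,
whichever needs fewer terms, truncating when terms drop below 1e−10.  The
defective CDF integrates the large-time series term by term, choosing the
term count so the tail at the smallest requested time is below 1e−12.

### Simulation

Trials are simulated by Euler–Maruyama, vectorized across trials, with
`dt = 0.1 ms` by default (any `dt ≤ 1 ms` is accepted).  Because a
discretely sampled path can cross and re-enter between grid points, raw
Euler first-passage times are biased late by O(√dt); both boundaries are
therefore moved inward by `0.5826·s·√dt` (the standard diffusion
continuity correction), which removes the leading-order bias.  The
correction can be disabled.  A 30 s cap guards non-termination; capped
trials are dropped with a warning and counted in the table's metadata.
Halving or doubling `dt` leaves simulated accuracy and mean RT within
Monte-Carlo error of the closed forms (the seeded 3-standard-error suite
in `tests/test_ddm.py` is the convergence check).

### Fitting

The observed RT distribution of each condition × choice cell is summarized
by its 0.1/0.3/0.5/0.7/0.9 quantiles; counts between successive quantiles
form a multinomial whose probabilities come from the defective CDF.  Cells
with fewer than 10 trials collapse to a single bin carrying that choice's
total probability, which keeps near-empty error cells well-defined at high
drift.  The objective is minimized by Nelder–Mead from 10 starts: the
first is a method-of-moments (EZ-style) estimate — with the starting point
solved from the observed upper-choice fraction — and the rest perturb it
log-normally (sd 0.15) under the caller's seed.  The best final
log-likelihood wins; ties go to the smaller parameter-vector norm.
Invalid regions (a ≤ 0, z outside (0, a), t0 < 0, zero-probability bins)
are rejected by penalty.  Parameter sharing across conditions is declared
per field ("shared" or "free"), and designs are compared by
`BIC = k·ln(n) − 2·logLik`.

At the published group-mean parameter sets, re-fitting 50,000 simulated
trials per condition recovers drift, boundary, and non-decision time to
within a few percent and the starting point to within ~1%
(`analysis/02_parameter_recovery.py`).  One caveat found during
development: in the non-integration (very high drift) condition virtually
every trial hits the correct boundary, so boundary separation and starting
point are jointly unidentified there; drift remains well recovered (its
seed-to-seed spread is ~2%), which is the only parameter reported for that
condition.

## The three-layer network

Units are firing-rate (population) variables; time is in seconds and
integration is Euler with 1 ms steps.

* **Accumulators** `a_i`:
  `τ_a·da_i = (I_i − k·a_i − w·a_j − reset) dt + σ_a·√(dt·τ_a)` noise,
  rectified at zero.  With leak balanced by lateral inhibition
  (`k = w = 3`), the difference `a_0 − a_1` drifts at
  `coherence_drive / τ_a` with constant diffusion — the DDM
  correspondence.  Input is `0.5 ± coherence_drive/2` per side while the
  stimulus is on; the stimulus switches off once the trial's response is
  registered.
* **Switch (threshold) units** `u_i`:
  `τ_u·du_i = (−λ·u_i + α·S(u_i) + W_f·a_i + b_i − reset) dt` with
  `S(u) = 1/(1+e^{−β(u−θ)})`, `λ = α = 1`, `β = 10`, `θ = 0.5`.  This unit
  is bistable for inputs in (−0.181, +0.181): stable states ≈ 0.007 and
  0.993 at zero input, with the low state annihilated in a saddle-node at
  the tipping input 0.181 (`switch_equilibria` solves the fixed-point
  equation by sign scan plus root polishing; `threshold_tipping_input` is
  analytic).  The feedforward weight `W_f = 1.6` keeps the common-mode
  accumulator input subthreshold while letting the winning side cross the
  fold.  The bias input `b` raises the low state toward the fold without
  crossing it — the model's response-bias signal.
* **Response units** `r_i` are switch units (offset 0.4) that are bistable
  at zero input, so once driven past their unstable point by the detector
  signal (a steep sigmoid of `u_i` centred at 0.9) they latch and complete
  their rise autonomously.  The response is registered at `r > 0.5` (the
  midpoint of the off/on states).  Reset inhibition is the near-binary
  response output (steep sigmoid at 0.35, just above the unstable point)
  times `reset_strength = 3`, applied to the accumulation and threshold
  layers; a slow adaptation variable (gain 0.8, τ = 0.3 s) then shuts the
  response unit off so the network returns to baseline well within a
  1-second inter-trial interval.

Because the reset engages while the response unit is still rising, the
threshold-layer difference peaks tens of milliseconds *before* the
registered response.  Stronger input (higher drift) pushes the winning
unit past its zero-input high state (overshoot), holds the detector on
longer and speeds the response unit's final leg — which is exactly why the
simulated LRP peak moves toward the response as drift grows.  With the
defaults, peaks sit at ≈ −95/−84/−52 ms for drives 0.025/0.06/0.4, the
area between low- and high-drive curves in the −250…−150 ms window is
positive, and baseline-to-peak height falls monotonically over bias levels
0 → 0.16 (`analysis/03_network_predictions.py` reproduces all three and is
also the tuning record for the default constants).  Only a qualitative
mapping from activation to microvolts is intended, so waveform comparisons
(`rmsd_layer_fit`) first scale each candidate trace to the target's peak
height; ties split 0.5/0.5, and only grid points whose mean simulated RT
falls inside a configurable plausibility window are counted.

## The LRP pipeline

The LRP is the trial-averaged, hand-signed central difference: C4 − C3 for
left-hand responses, C3 − C4 for right-hand.  Only correct trials enter.
Epochs are re-cut around the stimulus (−200…+1500 ms, baselined to the
200 ms before stimulus onset) or the response (−600…+200 ms, baselined to
400–600 ms pre-response); millisecond-to-sample mapping rounds half away
from zero, and window portions no trial covers are trimmed.  A flag
orients the waveform so the pre-response deflection is positive.

Artifact rejection runs on the unfiltered data (low-pass filtering would
wash out the variance and kurtosis signatures): a 100 ms running average
of the eye channel above 100 µV, any EEG channel beyond 70 µV, per-channel
variance above 80 or below 0.1 µV² (the thresholds are read as µV²), or
Pearson kurtosis above 5.  A large transient necessarily inflates kurtosis
as well, so each rejected trial is attributed to the first rule that flags
it (blink, amplitude, variance-high, variance-low, kurtosis) and the
report also lists every rule each trial matched.

Filtering is a 4th-order Butterworth applied forward–backward (zero
phase).  The conventional display cutoff is 4 Hz; the scalar-measure
analyses here use 20 Hz, because the zero-phase smearing of a 4 Hz filter
displaces the peak of an asymmetric wave by tens of milliseconds while at
20 Hz the displacement is below one sample at 250 Hz.  Measures are robust
to this choice in sign and ordering; only the sample-level recovery checks
need the wider band.

Onset uses the one-degree-of-freedom piecewise regression: a slope-zero
segment at the initial mean and a least-squares line through the rise, the
breakpoint chosen by total SSE (ties → earliest) and the onset reported as
the *intersection* of the two lines.  The rising line is fitted only up to
60% of the window maximum: beyond that the wave saturates toward its peak,
and a line through the shoulder systematically misplaces the intersection.
On noiseless flat-then-ramp input the estimator is exact; at SNR 10 it is
median-unbiased within one sample.  Peak measures follow the locking:
stimulus-locked, the first local maximum before the median RT with height
measured from the waveform at its onset; response-locked, the last local
maximum before the response with height from the preceding trough.  Local
maxima with prominence under 15% of the waveform's range are ignored — the
automated stand-in for the visual verification such measures traditionally
get.  The LRP-based non-decision time is the stimulus-locked onset plus
the (absolute) response-locked peak latency.

## Synthetic data

Behavior comes from the DDM simulator; in biased blocks the motion
direction is drawn with the preferred-direction probability and the
generating process keeps its starting-point bias toward the preferred
boundary while the drift sign follows the true direction.

EEG fixtures are built at 250 Hz (configurable) with three ingredients:

* **Template.**  The lateralized wave is the network's threshold-layer
  difference.  Two embedding geometries exist.  The *delay geometry* warps
  a canonical rise/decay pair so the wave departs at stimulus + d1 and
  peaks at response − d2; it grounds the recovery of d1, d2 and their sum
  (the neural non-decision time).  For it, the rise keeps only the
  ballistic segment above 50% of the switch transition (the subthreshold
  crawl would leave no crisp departure to detect) and both limbs get a
  quarter-sine taper so the peak has zero slope on each side and its
  location survives zero-phase filtering; the decay spans 250 ms.  The
  *response-locked geometry* instead embeds per-condition trial-averaged
  network waveforms rigidly at each response
  (`network_condition_templates`), which is the right fixture for
  condition-shape questions such as the area between coherence conditions
  — under the delay geometry a slow condition's long rise leaks into the
  pre-response baseline window and distorts exactly the comparison being
  tested.
* **Noise.**  Per channel, white (sd 5 µV) plus 1/f (sd 2.5 µV), and a
  common-mode 1/f term (sd 4 µV) shared by the EEG channels that the C3/C4
  difference cancels; the EOG channel carries only its own noise.  These
  levels keep clean trials comfortably inside every rejection threshold
  (per-channel variance ≈ 40–65 µV² against the 80 µV² rule).
* **Artifacts.**  Scripted contaminations each trip exactly one rule: a
  ~100 ms, 120 µV eye-channel bump (wide enough to survive the running
  average); a narrow 90 µV spike (amplitude rule — it would also trip
  kurtosis, which is why attribution order matters); added 12 µV white
  noise (variance-high, with peak amplitudes still under 70 µV); channel
  replacement by 0.01 µV noise (variance-low); and paired 40 µV two-sample
  spikes (kurtosis ≈ 12 with amplitude under 70 µV).

Bit-identical determinism under a fixed seed is tested for both
generators.

### What the fixtures do and do not show

The generator reproduces the statistical skeleton of the recordings —
RT/accuracy structure, a lateralized component with realistic (~3 µV)
amplitude riding on 1/f-plus-white noise, blink-like and amplitude
artifacts — but not volume conduction, electrode covariance beyond a
single common mode, drifting impedances, or any systematic relation
between RT and artifact rate.  Passing the round-trip therefore shows the
*pipeline* is correct and unbiased at realistic SNR; it does not certify
performance against every real-world failure mode.  Delay-recovery checks
use a high-drift (non-integration-style) condition: its tight RT
distribution is what makes a sample-level onset criterion meaningful,
since RT jitter smears the stimulus-locked average in slow conditions for
any estimator.  Recovery runs use 250 trials per session, below the
600–1300 per condition of the motivating studies.

## Study sizes and statistical checks

Simulation-versus-closed-form agreement is asserted at 3 standard errors
with fixed seeds: 20 random parameter sets × 10,000 trials in the unit
suite, plus the published sets at 20,000.  Parameter recovery at the
published sets uses 50,000 trials per condition.  The pipeline round trip
asserts medians over 100 seeds within ±2 samples at 250 Hz.  The
cross-subject script simulates a small cohort (default 8 subjects) with
between-subject spread set to the published standard errors scaled back to
individual scale; at that size the bias analyses are reliably significant
while the area-versus-drift regression is underpowered at single-subject
EEG noise and is reported without a significance claim.

## Known limitations

* The network's constants are one tuned instance of the qualitative
  regime, not a fit to data; all claims about it are ordinal
  (positive area, ordering of peaks and heights).
* Boundary separation and starting point are not identifiable from a
  single condition in which one response is (nearly) never given.
* The quantile-likelihood engine assumes enough trials per condition for
  stable quantiles (≥ 50 recommended); with fewer, cells collapse and
  precision degrades gracefully but is not guaranteed.
* The 1DF onset estimator is biased toward early onsets when baseline
  noise is high relative to the rise — the familiar property that makes
  LRP-based non-decision times underestimate behavioral ones.
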