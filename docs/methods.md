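# Methods

## The task being simulated

A participant holds a skin-stretch device mounted on a haptic arm and makes
vertical probing movements into a virtual elastic force field.  With
penetration `y ≤ 0` (metres below the field boundary) the device renders

    LF(t)       = -k · y(t)          load force, N   (k in N/m)
    y_tactor(t) = -g · y(t)          skin stretch, mm (g in mm/m)

and both are zero out of contact.  The standard field has k = 85 N/m and is
augmented with one of four stretch gains (0, 33, 66, 100 mm/m); the
comparison field is purely kinesthetic with k in 40–130 N/m.  On a
*stretch-catch* probe the load force is delivered but the stretch is
omitted, so the grip-force trace contains only the predictive
(feedforward) component.

## Trial schedules

* **Structured probing (stretch-catch protocol).**  Two 66-trial sessions:
  12 training trials (4 × 3 comparison stiffness, gain 0) followed by 54
  test trials each.  The 108 test trials are 9 repetitions of the 12
  (stiffness × gain) pairs; in each nonzero-gain pair, 3 repetitions carry
  a catch at probe 2, 3 at probe 7, 3 none.  With 8 probes per field this
  makes catch probes exactly 54/1728 = 3.125% of all probes.  Catch probes
  are restricted to nonzero-gain trials: omitting a stretch that would not
  have occurred is physically meaningless, and only this reading yields the
  3.125% figure.
* **Discrimination protocol.**  Group 1 (single probe per field): 20
  training + 320 test trials (10 stiffness × 4 gains × 8 reps), one
  session.  Group 2 (free exploration): two sessions of 20 training + 180
  test trials.  The protocol description is internally ambiguous between
  320 and 360 total test trials; we default to the per-session counts
  (2 × 180 = 9 repetitions per cell, split 4/5 across sessions) and expose
  the total as a parameter.
* Ordering is a seeded uniform shuffle per session; which field comes first
  is randomized 50/50 per trial.  Condition counts are exact and
  seed-independent; only order varies.

## Synthetic data generator

**Kinematics.**  Each probe is a raised-cosine in/out profile: start/end at
+5 mm clearance, −25 mm at mid-movement, 250 ms duration (within the
protocol's validity bounds of ≥ 20 mm depth and ≤ 300 ms), zero velocity at
the endpoints.  Probes are separated by 500 ms rest epochs so baseline
detection has a quiescent segment.  Sampling rate defaults to 1 kHz
(a typical haptic servo rate) and is configurable; the reduced problem
sizes below use 250–500 Hz.

**Grip-force controller.**  During contact the noiseless grip force is
exactly affine in the load:

    GF(t) = B(g, p) + S(g, p) · LF(t)

with probe number p.  The baseline implements the *immediate* safety-margin
effect: `B = baseline0 + baseline_gain_slope · g` from probe 2 onward
(defaults 1.0 N and 0.002 N per mm/m).  The modulation slope implements the
*gradual* anticipatory effect: S ramps linearly from `modulation0` (0.2) to
`modulation0 + modulation_gain_slope · g` (slope 0.001 per mm/m) over
`modulation_buildup_probes` = 4 probe increments, then plateaus.  White
Gaussian measurement noise (sd 0.02 N) is added to the grip channel.  The
measured grip force of the emulated device is a downscaled version of the
true pinch force, so only trends and ratios are meaningful — absolute
newton values are arbitrary, matching the device being emulated.

Between probes the grip settles at the *upcoming* probe's baseline from the
first out-of-contact sample, so the quiescent epoch before probe p reflects
B(g, p) and the baseline detector recovers it exactly on noiseless data.
Before contact the grip ramps to the value that makes the backward-
difference rate at the contact sample satisfy

    GF_peak = a · GF_contact + b · dGF_contact/dt + c

with the controller's intended-peak coefficients (defaults 1.14, 0.06 s,
0.1 N).  This makes the generator exactly self-consistent with the
intended-peak analysis: on noiseless data the refit recovers the
coefficients with R² = 1 and the predicted intended peak equals the true
peak.  One consequence: out-of-contact samples of the approach carry this
anticipatory ramp, so the "grip equals baseline plus slope times load"
identity holds on the in-contact samples that all analyses use, not on the
approach samples.  Catch probes change nothing in the controller (the
stretch omission is unexpected) and no reactive component is generated, so
catch-probe grip traces are single-peaked; reactive double-peak artifacts
of the physical device are out of scope.

**Observer.**  A 2AFC response ("comparison stiffer") is drawn with
probability

    P = lapse/2 + (1 − lapse) · Φ((Δk − pse_per_gain · g) / σ)

Δk the comparison-minus-standard stiffness.  Defaults: lapse 0;
`pse_per_gain` 0.3073 N/m per mm/m (single-probe group) or 0.3910
(free-exploration group), i.e. gain-100 PSE shifts of 30.73 and 39.10 N/m;
σ = 29.65 N/m so the JND is ≈ 20 N/m and independent of gain.

**Cohorts.**  `sample_participants` jitters the controller baseline
(sd 0.1 N), modulation (sd 0.02), modulation gain slope (sd 0.0002) and
observer σ (sd 3 N/m) across participants.  The between-participant spread
of the PSE rate defaults to **zero**: under the default observer, the
sampling noise of a single per-gain psychometric fit at gain 100 (≈ 7–8
N/m) is already as large as the reported between-participant spreads of the
group-level PSE effects (2.26·√10 ≈ 7.2 and 1.87·√9 ≈ 5.6 N/m), so the
observed dispersion is attributed to fit noise rather than to true rate
heterogeneity.  All spreads are parameters.

**What the generator does not emulate.**  Reactive grip responses and
device-specific double peaks, grip-force sensor calibration, drifting or
probe-dependent certainty effects at zero gain (the real decline of the
safety margin over repeated probing), correlated (non-white) sensor noise,
and participant kinematic variability beyond the validity bounds.  Passing
recovery tests therefore demonstrate that the *analysis chain* is correct
and calibrated, not that these additional real-data phenomena are handled.

## Preprocessing

Grip channels are filtered with a 2nd-order Butterworth designed at 12 Hz
and applied forward and backward (zero phase).  The two passes square the
magnitude response, giving an effective 4th-order filter with −3 dB at
`12·(√2−1)^{1/4} ≈ 9.62 Hz`; DC gain is exactly 1.  Edges use reflect
padding of three filter lengths.  Probes are maximal runs of positive load
(the load is identically zero out of contact; for noisy real data a
threshold `contact_eps`, default 0, is exposed), numbered in temporal order
per trial and field; a probe is valid iff depth ≥ 20 mm, contact duration
≤ 300 ms, and the contact run does not touch the series boundary.  Grip
peaks are local maxima above a 0.05 N topographic prominence — a
deterministic replacement for the manual peak correction used with real
recordings.  Trials in which the grip drops below 0.05 N for more than
50 ms count as released-grip trials and are excluded.

## Grip-force decomposition

* `peak_ratio`: peak grip / peak load per probe.
* `gf_lf_regression`: OLS of grip on load over the contact interval;
  intercept ≈ baseline, slope ≈ modulation; negative slopes (large
  grip-load phase shifts) are flagged and excluded.
* `baseline_between_probes`: first out-of-contact instant, at least one
  window after the gap start, where |dGF/dt| < 0.1 N/s; the baseline is the
  mean grip over the trailing 200 ms window.  Ties broken by taking the
  *first* qualifying instant.  No qualifying instant → missing value
  (logged), not an error.
* `contact_features`: grip at the first in-contact sample and its
  backward-difference rate (unstandardized, so the rate coefficient b is in
  seconds).
* `IntendedPeakRegressor`: least squares of peak on (contact, rate) over
  stretch-catch probes, pooled across participants and gains by default
  (per-participant fitting is a caller choice); requires ≥ 3 non-collinear
  points.  The replicate catch probes of each condition are averaged before
  the fit: they share the same intended grip-force state, and averaging
  reduces the regression-attenuation (errors-in-variables) bias that noise
  on the rate regressor would otherwise induce.
* `decompose`: modulation = intended peak − grip at contact, exactly.
* Evolution analyses use probes 1–7 (the last probe is omitted as
  irregular) and difference each (participant, probe, gain) mean against
  its gain-0 value, which is exactly zero after differencing.

Because the 12 Hz zero-phase filter is a fixed linear operator on the
(identical) probe template, the generator's modulation-per-gain parameter
maps onto the measured modulation through a constant computable from the
noiseless filtered template; recovery checks compare against that
band-limited value.

## Psychometrics

Maximum-likelihood cumulative-Gaussian fits (logistic link optional) on
grouped responses per participant and gain; lapse fixed at 0 by default
(freeing it is a parameter).  PSE = 50% point (= μ for symmetric lapse);
JND = half the 25–75% span (= 0.6745·σ for lapse 0).  Degenerate data are
flagged, not raised: single response category, perfectly separated
responses, and fits whose σ reaches half the sampled stimulus span — in the
latter case the sigmoid is effectively linear over the data and location
and spread are no longer jointly identified, a regime that otherwise
produces unbounded location estimates.  Group-level summaries use converged
fits only.  PSE and JND are regressed on gain per participant (OLS), with
the group line the mean of per-participant coefficients.

## Repeated-measures inference

Fixed effects: gain (continuous, 1 df), probe number (categorical,
levels − 1 df), and their interaction; participants are a random factor.
Each fixed effect is tested against the mean square of its interaction with
the participant factor; the gain × probe interaction against the
three-way term.  This is the classical repeated-measures convention and
reproduces the `F(1, N−1)` df pattern for N participants.  Sums of squares
are computed in closed form from the balanced cell-mean cube (the design is
required to be balanced; missing cells are reported explicitly) — for a
balanced design with centered gain this equals the sequential OLS
decomposition, which the test suite verifies against statsmodels
`anova_lm`.  No sphericity correction is applied.

## Problem sizes and numerical choices

* Pipeline smoke configuration: 2 participants, single stiffness (85 N/m),
  3 repetitions per gain, 500 Hz; the `paper` configuration restores
  10 participants, 3 stiffness × 9 repetitions, 1 kHz.
* Parameter-recovery studies run at 250 Hz with the full 9-repetition
  catch structure, 10 participants, 100 simulated cohorts for the
  modulation slope, and 20 replicate protocol-scale simulations for the
  PSE; these sizes give Monte-Carlo standard errors well below the effect
  sizes being recovered.
* All randomness flows from a single root seed through named CRC32-keyed
  SeedSequence substreams, so every stage's draws are independent of the
  presence of other stages and runs are byte-reproducible.
* Optimizer: Nelder-Mead on (μ, log σ) with probabilities clipped at 1e-9;
  collinearity is detected by design-matrix rank; half-open 0-based sample
  index intervals throughout; grip/load in N, rates in N/s, stiffness in
  N/m, gains in mm/m, penetration in m (the mixed mm/m gain unit is applied
  only at the tactor output).

## Known limitations

* The intended-peak model refit on *filtered* data recovers
  filter-transformed coefficients, not the generating (1.14, 0.06, 0.1);
  exact recovery holds on unfiltered noiseless data and at the feature
  level.  Predictions remain exact either way because the feature map is
  linear.
* The psychometric MLE has finite-sample bias when the true PSE approaches
  the edge of the sampled stiffness range; the identifiability guard
  removes the unbounded cases but a small residual bias remains.
* The rm-GLM requires exact balance; unbalanced real data would need cell
  means or a mixed-effects model, which is out of scope.
* Free-exploration probe counts are drawn uniformly (1–8 per field) rather
  than from empirical exploration statistics.
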