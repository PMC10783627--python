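# Methods

This note documents the models, the defaults and the numerical choices
behind `nocirig`, and what the virtual rig does and does not emulate.

## Withdrawal detection

### Reflectance channel

The detector operates entirely on the smoothed signal.  Smoothing is a
*trailing* (causal) running average — sample $k$ is the mean of the window
ending at $k$, truncated at the trace start — because the same arithmetic
must run sample-by-sample in the streaming (closed-loop) detector; a
centered window would need future samples.  The "27 ms" window is realized
as `round(27·fs/1000)` samples (27 samples at 1 kHz); the realized width
is recorded on every result.

The baseline is the mean of the smoothed signal over
$[t_{onset}-500\,\mathrm{ms},\,t_{onset})$; the onset sample itself is in
neither the baseline nor the response window.  Crossing means *strictly*
below baseline − 2 mV (a tie with the threshold does not count), and the
persistence requirement is strict as well: a run of $m$ consecutive
sub-threshold samples qualifies when $m\,\Delta t > 20$ ms, i.e. ≥ 21
samples at 1 kHz.  Latency points at the run's first sample.  Because the
whole rule reads the smoothed signal, a short raw excursion can be smeared
into a longer smoothed excursion: a 5 mV raw dip must be shorter than
about 13 ms (not 20 ms) to be rejected at the default settings.  The
persistence guarantee proper — no smoothed sub-threshold run of ≤ 20 ms is
ever reported — is tested by construction over run lengths 1…20 ms.

Censored trials (no qualifying run by the cutoff) report
`latency = censor_time` with `censored=True`, never a missing value, so
session logs stay rectangular and survival-style analyses can re-censor.

The streaming detector maintains the window sum incrementally and emits
its event the moment the persistence criterion is met — i.e. one
persistence-duration (20 ms at defaults) after the crossing it reports.
This emission lag is exactly the price of confirming the response, and it
bounds closed-loop stimulus duration: `min(latency + lag, cutoff)`.
Equivalence with the offline detector is exact in all discrete decisions;
the two compute window means with different summation orders, so they
could in principle disagree only if a smoothed sample ties the threshold
to within ~1e-12 mV — a measure-zero event for continuous signals, and
the noiseless fixtures use exactly representable values.

### Paw-height channel

Height from video rises with withdrawal; latency is the first post-onset
sample strictly more than 6 px above baseline.  No smoothing is applied by
default (the smoothing prescription is specific to the photodetector
channel; pose estimates are already per-frame point estimates), and no
persistence rule: the criterion is a rise only, so a paw pressed downward
never triggers.  Smoothing can be enabled (`smooth_height`).

### Force channel

"Abrupt drop" is operationalized as: the running-average-smoothed force
falls strictly below `force_drop_fraction` (default 0.5) of its trailing
50 ms rolling maximum.  Comparing against the trailing maximum rather than
the global peak is what makes the criterion *abruptness*: a slow decline
never loses 50 % within 50 ms.  Two auxiliary choices matter:

* `force_min_peak` (default 5 mN): detection is armed only once the raw
  running peak clears this floor.  Early in the ramp the force is within
  the noise floor and the ratio criterion is meaningless — without the
  guard, millinewton-scale noise triggers spuriously.
* `threshold_force` is read from the **raw** running peak, not the
  smoothed one, so in the noiseless case it equals the programmed
  withdrawal force exactly (the trailing mean under-reads a rising ramp
  by `(n−1)/2` samples of slope).

The detected latency lags the true unloading by up to roughly the
smoothing window plus the collapse time (~30 ms at defaults); the
threshold force, the assay's primary mechanical readout, is unaffected.

## Virtual rig

* **Beam**: straight-edge divergence cone, radius
  $r(z) = d/2 + z\tan(\arcsin \mathrm{NA})$ with $d = 5$ mm and
  NA = 0.48.  This is the simplest physically motivated model; measured
  z-sensitivity curves of a real fiber cannot be matched without the full
  fiber-to-platform geometry, so only monotonicity and symmetry are
  asserted.  On-target power is the overlap of the beam disc with a
  paw-shaped aperture (ellipse, 10 × 4 mm, a plausible hind-paw
  footprint), uniform irradiance by default; a Gaussian profile
  (σ = r/2) integrated on a 121×121 grid is optional.  Geometry uses
  shapely polygons (96 segments per quadrant), good to ~0.1 % of area.
* **Jitter**: per-sample i.i.d. Gaussian or Gaussian random-walk offsets
  of the beam axis, contrasting a handheld fiber with a rigid mount.  The
  sds are free parameters (the real contrast is an empirical, tester-
  dependent quantity); tests assert the *ordering* — smaller jitter, higher
  SNR — not absolute dB values.  Power traces default to 100 Hz sampling:
  beam wander is slow, and each sample costs an overlap integral.
* **Virtual paw**: reflectance sits at `baseline` (default 100 mV) with
  optional linear drift and Gaussian noise (default SD 0.3 mV, a clean
  photodetector); at `onset + true_latency` it falls by `reflectance_drop`
  (default 5 mV) linearly over `transition_ms` (default 10 ms, the time a
  ~2 px/ms withdrawal takes to clear the spot).  The generator does not
  model paw micro-movements, breathing artifacts, or reflectance *rises*
  at unusual geometries — so passing tests certify the detector logic, not
  robustness to every real-world artifact.
* **Key points**: six body parts at 30 fps in a 640×480 frame (origin
  top-left, crosshair at (320, 240)), with per-frame Gaussian coordinate
  noise (default 3.33 px, the target-hind-paw test error of the tracking
  network) and stop-and-go "stationary bouts" motion (default 4 s bouts
  with instantaneous relocation) or a frame-to-frame random walk.
  Confidence is 0.95, optionally degraded to model frames where the paw
  is not recognized.  Real mice also rear, groom and guard; the generator
  only reproduces the stop-and-go statistics the controller's timers must
  cope with.

All generators are deterministic functions of (parameters, seed).

## Controller

Discrete time at the 33 ms frame interval (pose inference on the real rig
completes within one frame, so one error sample per frame is the natural
loop rate).  The actuator is an ideal velocity follower; hardware
latencies and motor dynamics are out of scope.  The deadband is applied
per-axis (max-norm) — "within 3 px" read axis-wise, since x and y errors
are measured and actuated independently — switchable to Euclidean.  The
settle timer *resets* (not pauses) whenever the error re-exceeds the
deadband or the target is lost (confidence < 0.5); stimulation fires only
after an uninterrupted in-deadband span ≥ 2 s.  Gain and speed clamp
(0.5, 50 px/frame) are exposed defaults, not measured rig values; any
gain in (0, 1] is geometrically convergent without overshoot under the
linear plant.

Sessions run on a virtual wall clock (aiming time + closed-loop stimulus
duration + a 5 s handling allowance between stations).  The scheduler
never re-stimulates a mouse before its inter-stimulus interval (default
60 s) has elapsed since its previous stimulus *onset*, waiting if
necessary; ordering is a per-round seeded permutation.  Trial seeds derive
from the plan seed, round index and a CRC of the mouse ID, so sessions
are byte-identical across runs.

## Analysis

* SNR is $10\log_{10}(\mu^2/\sigma^2)$ (equivalently
  $20\log_{10}(\mu/\sigma)$); CV is $\sigma/\mu$; SD uses $n-1$.
* Bland-Altman: differences are method1 − method2; fixed bias by
  one-sample t test of the mean difference; proportional bias by OLS of
  difference on average, with the standard t-based prediction band
  $s\sqrt{1 + 1/n + (x-\bar x)^2/S_{xx}}$.
* Fast/slow boundary at 75 ms; an exact 75 ms latency is classed slow
  (the fast class is defined by a strict "< 75 ms").
* χ² is Pearson without Yates continuity correction,
  df = (r−1)(c−1); zero expected counts raise rather than silently
  degrade.
* Power-law fits are OLS in log10-log10 space (`a = 10^intercept`,
  `b = slope`); exact on noiseless power-law data, and the exponent is
  unbiased under symmetric log-normal noise.
* The psychometric function is a maximum-likelihood logistic in log10
  intensity; threshold = intensity at p = 0.5, flagged when extrapolated
  beyond the tested range.  Perfectly separated data (all failures below
  all successes) leave the slope unidentified; the threshold is then the
  geometric midpoint of the bracketing intensities, flagged `separated`.
  The recovery simulations use a generating slope of 10 per decade —
  the withdrawal probability transitions over roughly a factor 2.5 in
  intensity, matching the steepness of titration curves in this assay —
  with the true threshold mid-grid on a 5-point geometric intensity grid,
  5 trials per intensity.
* Behavior-latency association: logistic (occurrence flag) or linear
  (duration) regression on latency, with a case-resampling bootstrap
  (2000 reps, seeded, percentile 95 % CI).  Bootstrap resamples lacking
  both outcome classes are dropped (they carry no slope information);
  complete separation is flagged and the Wald p suppressed, leaving the
  bootstrap CI.
* No multiple-testing correction is applied anywhere; raw p values are
  reported.

## Problem sizes

The test suite and acceptance script use: 1,000 simulated trials (1.5 s
traces at 1 kHz) for streaming/offline equivalence; 40 noiseless trials
against the brute-force oracle; 20 seeded replicates for jitter/SNR
ordering at 50 Hz × 400 ms; 200 seeds for psychometric recovery and for
the association type-I simulation; 40 simulations for the χ² power check;
and 2–3-mouse, 2-trial virtual sessions for scheduling and determinism.
These sizes make every stochastic assertion stable across seeds while the
whole suite runs in well under a minute.

## Known limitations

* No optics beyond the overlap model (no diffraction, skin scattering or
  tissue heating); thermal trials are represented by latency distributions
  with a 20 s censoring cutoff, not by a heat-transfer model.
* The reflectance generator's drop-then-stay-down shape cannot produce
  re-entries into the beam (a paw returning mid-stimulus); the detectors
  handle such traces, but the simulator does not emit them.
* Pose estimation itself (network training/inference) is out of scope;
  key points are simulated directly, and hooks exist only for importing
  externally produced behavior labels.
* The controller models x-y translation only; z is static during a trial.
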