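# Methods

This note documents the models, parameter choices and numerical
conventions behind `batforage`, and what the synthetic-data experiments
do and do not demonstrate.

## The measurement problem

A tagged bat produces three synchronized data streams: ultrasonic audio
(94 or 187.5 kHz, 16 bit, full scale = the tag clipping level), triaxial
acceleration (calibrated m/s², decimated to 100 Hz, clipped at 8 g
≈ 78.5 m/s²) and a triaxial magnetic field at 50 Hz; some tags add a GPS
fix every 15 s. From these we must recover, per night: every prey attack
and its strategy (gleaning from the ground vs aerial hawking), whether it
succeeded, how long the prey took to handle, when the bat was flying,
searching or commuting, and finally the energy ledger of the night.

## Acoustic chain

**Calls.** Audio is high-pass filtered at 20 kHz (4-pole Butterworth,
causal), rectified, and smoothed with a 0.25 ms boxcar; peaks above
`median + 10·MAD` with a 2 ms refractory period are calls. The reported
time is the envelope maximum, i.e. near the call midpoint; for a 2 ms
call the offset from onset is ~1 ms. The threshold is robust rather than
absolute so the detector works across recordings with different noise
floors. Ten MADs keep the false-alarm rate negligible over tens of
millions of samples; at a 20 dB call SNR the calls still sit several
thresholds above noise.

**Buzzes.** A feeding buzz is a maximal run of more than six consecutive
inter-call intervals below 8 ms. The detector is a linear scan over the
ICI sequence and is property-tested against brute-force enumeration of
all runs. Buzzes ending within 1 s before a landing, or outside flight
epochs, are excluded from attack counting (landing buzzes are
orientation behaviour, not prey capture).

**Mastication.** Chewing is scored per inter-call interval from the
capture to the next attack or 100 s, whichever comes first. Each
interval (trimmed 3 ms on both sides to exclude call energy) of the
7–15 kHz band-passed signal is rectified and convolved with a unit-area
40 ms Hanning kernel; the interval is chew-positive iff the smoothed
maximum exceeds 0.012 on normalized full-scale amplitude AND the
spectral peak of the 5 kHz high-passed signal lies strictly between 5
and 20 kHz. Two conventions matter here:

- the Hanning kernel is normalized to unit area, so the 0.012 threshold
  is on the raw amplitude scale (a weighted moving average), and a brief
  broadband transient is diluted by the 40 ms support — which is the
  point of the smoothing;
- the spectral-peak search stops at 25 kHz, which makes the classifier
  insensitive to ultrasonic call energy at any amplitude (the 5–20 kHz
  acceptance band is unchanged).

Only intervals between 20 ms and 0.5 s are evaluated: chewing is a
flight behaviour and flight inter-call intervals are ~0.1 s, while
longer gaps span landings and ground handling whose broadband transients
would otherwise masquerade as chews. One chew is counted per
chew-positive interval, stamped at the smoothed-amplitude maximum.

**Success and handling time.** An attack is successful iff at least one
chew-positive interval occurs in its window. The chew train is
summarized by the 10th and 90th percentile chew times (linear
interpolation between order statistics): onset = q10 − attack time,
duration = q90 − q10, handling time = onset + duration.

## Motion chain

**Conventions.** Body axes are x = surge (forward), y = sway (left),
z = heave (up); at rest the accelerometer reads +g on z. Heading is
clockwise-positive from magnetic north. Running means are centered with
shrinking windows at the edges (no group delay anywhere in the chain).

**Flight.** The heave axis is band-passed 5–25 Hz with a symmetric FIR
filter (1024 requested taps, rounded up to 1025 so the impulse response
is exactly symmetric; the tap mean is removed to pin an exact null at
DC, making flight detection invariant to gravity offsets). Flight epochs
are where the 50 s running mean of the rectified band-passed signal
exceeds 20 m/s². The rectification is essential: a raw running mean of a
zero-mean oscillation could never reach the threshold; for a sinusoid of
amplitude A the rectified mean is 2A/π, so 40 m/s² wingbeats (→ 25.5)
count as flight and 20 m/s² wingbeats (→ 12.7) do not. Sub-second
threshold flicker is merged and epochs shorter than 5 s dropped — the
50 s window exists precisely to suppress few-wingbeat "flights".

**Landings.** A landing is a jerk peak (norm of the first-differenced
acceleration × sample rate) exceeding `median + 6·MAD`, coincident
within ±50 ms with a broadband audio transient (envelope peak above
`median + 8·MAD`), followed by flattening: the standard deviation of the
band-passed heave signal over the next 2 s below 25% of the median
flight-epoch level. The conjunction is what gives specificity — calls
coincide with wingbeat jerk all night, but never with post-event
stillness.

**Heading.** Accelerometer and magnetometer are low-pass filtered at
3 Hz (4-pole Butterworth, zero-phase) and the accelerometer interpolated
onto the magnetometer time base. The gravity direction supplies pitch
and roll; the field is projected onto the horizontal plane spanned by
the projected forward axis e1 and e2 = down × e1, giving heading
ψ = atan2(−m·e2, m·e1). Samples with ‖a‖ < g/2 (free fall) are masked.
On noise-free simulated orientations with pitch/roll ≤ 45° the recovery
is exact to machine precision; the < 2° RMS bound in the tests leaves
room for interpolation effects.

**Foraging bouts.** The heading-variation signal is the 50 s-smoothed
magnitude of the analytic signal of the circular residual (heading minus
its 50 s running circular mean, wrapped). Intervals above 0.05 rad are
foraging; if a night produces more than 10 foraging/commuting switches
the threshold is raised to 0.3 rad and the segmentation recomputed (both
thresholds configurable; the escalation counts transitions in either
direction). Bouts are intersected with flight epochs, and bouts
containing no prey attack are discarded from foraging summaries
(attacks are assigned to bouts by half-open [start, end) intervals).

## GPS chain

Latitude/longitude are projected to metres with a spherical
transverse-Mercator projection about the track centroid (forward and
inverse, roundtrip-tested; at track extents of a few km the spherical
approximation error is far below GPS noise). Fixes are linearly
interpolated onto a 10 s grid; gaps over 60 s split the track.

**First-passage time.** FPT at location i and radius r is the backward
plus forward time for the track to first leave the circle of radius r
centred at i, with the crossing time linearly interpolated between
fixes. Locations where the track ends inside the circle are censored and
excluded from the variance (including them would right-censor exactly
the longest passages). The operating scale is the radius (5–400 m in 5 m
steps) maximising var(log FPT).

**Lavielle segmentation.** The per-10 s step-distance series is
segmented by exact dynamic programming over the per-segment Gaussian
contrast n·log(σ̂²) (mean+variance contrast; a pure-mean contrast is
available), with ≥ 5 locations per segment and at most 50 segments. The
DP is tested for exact agreement with exhaustive changepoint enumeration
at small n. The number of segments is chosen at the elbow of the
normalized contrast curve (largest second difference), with K forcible;
a series with no contrast structure returns K = 1.

**Foraging/traveling threshold.** Sarle's bimodality coefficient
BC = (g₁² + 1)/(g₂ + 3(n−1)²/((n−2)(n−3))) with bias-corrected sample
skewness and excess kurtosis must exceed 5/9 (else the caller must
override); then a 2-component Gaussian mixture (EM, k-means
initialization, fixed random state — the returned threshold is invariant
to the initialization seed) is fitted to the per-10 s distances, the
higher-mean component is traveling, and the threshold is its lower
quartile. Distances below the threshold are foraging
(area-restricted search); the boundary itself classes as traveling. The
mixture is fitted on the per-step distances rather than the handful of
per-segment means because a two-component fit on < 10 points is
unstable; segments are then classed by their mean step distance.

## Energy model

Dry masses come from per-order power laws mass_mg = a·L_mm^b averaged
with niche weights (ground: Carabidae 0.78 / Orthoptera 0.22; aerial:
Diptera 0.65 / Lepidoptera 0.35). The shipped coefficient table contains
typical insect allometries and is explicitly editable; all headline
energy arithmetic anchors instead to the mean observed dry masses
(ground 67.5 mg; aerial 3.0 mg from diet metabarcoding or 21.2 mg from
the mastication ratio), so the table never silently drives results. The
mastication-ratio mass estimate is ground mass × (chews per aerial
capture / chews per ground capture); at the observed medians 23/75 this
formula gives 20.7 mg, slightly below the 21.2 mg obtained when the
ratio is taken over full per-capture distributions rather than medians —
the operation implements the stated ratio; both numbers are carried as
the "higher" aerial estimate's provenance.

Caloric value is mass(g) × density(kJ/g) × 1000 J (ground 25.4, aerial
21.3 kJ/g dry). Nightly intake multiplies per-strategy success counts by
per-prey calories, reported for both aerial-mass estimates; duty-cycled
recordings (50% duty: 30 s on / 30 s off) have counts doubled before the
energy arithmetic. Assimilated energy applies an efficiency in
[0.50, 0.82]; field metabolic rate scales between body masses as
FMR_ref × (m/m_ref)^0.7. Prey profitability is
P = calories / (handling + time between attacks) × success ratio, J/s,
with the between-attack interval as the search-time proxy; success
ratios are only reported for strategies with more than one attack per
night (the bout-level analysis uses > 2, both thresholds configurable).

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with defaults fixed at the study conditions:

- calls: 2 ms linear downward FM sweeps (100 → 25 kHz, capped below
  Nyquist at 94 kHz), amplitude 0.4 full scale, noise floor set by a
  38 dB SNR; search ICI 80 ms, approach ramp 30 → 10 ms, buzz of 10
  intervals at 6 ms ending at the capture;
- gleaning attacks: 2 s of low-amplitude pre-attack calls (passive
  listening), a 5 ms broadband landing click co-timed with a sharp
  sway/heave accelerometer spike (opposite signs), then 2.5 s of
  on-ground stillness before flight resumes;
- chews: 8 ms exponentially damped 7 kHz sinusoids (amplitude 0.6,
  soft-edged) placed midway between consecutive post-capture calls;
  per-capture counts are lognormal with medians 75 (ground) and 23
  (aerial) and log-sigmas 0.79 / 0.96 chosen to reproduce the observed
  interquartile ranges (38.5–111.5 and 15–55);
- capture success is drawn per attack at the nightly mean probabilities
  0.76 (hawking) and 0.30 (gleaning);
- wingbeats: 10 Hz heave sinusoid at 35 m/s² (rectified band-passed mean
  ≈ 22 m/s², above the 20 m/s² flight threshold); the wingbeat frequency
  and amplitude of the study species are not published, so these are
  explicit config placeholders;
- heading: commute jitter σ = 0.01 rad around a fixed bearing; foraging
  bouts superimpose a Brownian-bridge random walk (σ = 0.05 rad/sample
  at 50 Hz) that rejoins the commute heading continuously at both bout
  boundaries;
- magnetic field: unit magnitude, 60° inclination, matching the
  mid-latitude study region;
- GPS: commuting at 8 m/s with small heading noise; area-restricted
  search at 3 m/s with heading-walk σ = 0.6 rad/s, folded back at the
  100 m patch boundary; isotropic 5 m Gaussian fix noise; default phase
  plan of ~5 min patches separated by commutes (typical foraging-bout
  durations). With this movement model the var(log FPT) peak falls at
  65–105 m across seeds, i.e. at the patch scale;
- duty cycling drops sensor rows and events in off-blocks, blanks the
  audio, and records the on/off blocks in a coverage table.

Scenes default to minutes, not a full night, to keep ultrasonic audio
desk-scale; every algorithm is duration-agnostic.

**What passing tests show — and don't.** The generator produces clean
vespertilionid-like signals: calls never overlap chews, the noise floor
is stationary and Gaussian, chew amplitudes are fixed, and there are no
conspecifics, rain, wind gusts, echoes or prey rustling. Perfect
PPV/FNR on these scenes demonstrates that the detection chain is
implemented correctly and is internally consistent with its thresholds;
it does not certify field performance, where weaker aerial chews in
particular raised the false-negative rate. The success-ratio recovery
experiments (≥ 500 attacks per strategy) show the pipeline is an
unbiased estimator of the generating success probabilities within
binomial error.

## Evaluation conditions

The evaluation harness (`batforage.evaluation`, driven by
`scripts/acceptance.py` and the end-to-end tests) uses: 94 kHz audio;
scenes of 12 attacks with alternating strategies and forced alternating
success labels for the classifier PPV (≥ 200 windows pooled across
derived seeds); and dense single-strategy nights (attacks every 2.5 s
hawking / 4.5 s gleaning, 150 s scenes pooled to ≥ 500–1000 attacks) for
success-ratio recovery. Problem sizes were chosen so a full run
completes in a few minutes on one CPU while keeping binomial sampling
error near one percentage point.

## Known limitations

- Field-data effects (variable chew amplitude, overlapping conspecific
  calls, non-stationary noise) are out of the generator's scope.
- The automatic attack detector labels buzz-coincident attacks as
  hawking and landing-coincident as gleaning only when asked; the
  primary workflow takes attack times and strategies from an annotation
  file, as in the field protocol.
- Per-segment habitat labels are an input (manually derived in the field
  workflow); no land-cover classification is attempted.
- Mixed-effects statistical modelling of the resulting tables is out of
  scope; the pipeline emits the tidy per-night tables such models
  consume.
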