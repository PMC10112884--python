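# batforage

Biologging analysis of how a gleaning-specialist bat (*Myotis myotis*-like)
divides its hunting between two foraging strategies: **gleaning** large
ground-dwelling arthropods located by passive listening, and **hawking**
small aerial insects on the wing guided by echolocation. The package
implements the full computational chain that turns raw animal-borne tag
data — ultrasonic audio, triaxial accelerometer and magnetometer, GPS —
into per-night foraging statistics and an energy budget, and ships a
seeded synthetic tag-data generator with ground truth so every stage is
testable end to end without any field data.

For movement ecologists and bioacousticians who want a tested, reusable
implementation of these tag-analysis building blocks:

- **Acoustics** — echolocation-call extraction from the 20 kHz high-passed
  envelope; feeding-buzz detection (more than six consecutive inter-call
  intervals below 8 ms); mastication-sound detection per inter-call
  interval (7–15 kHz band-pass, rectified and smoothed with a 40 ms
  Hanning kernel, amplitude threshold 0.012 on normalized full scale plus
  a 5–20 kHz spectral-peak test); capture-success classification —
  success ⇔ chewing present in the window from the capture to the next
  attack or 100 s; chew-train characterization via the 10th/90th
  quantile times (onset, duration, handling time = onset + duration).
- **Motion** — jerk; zero-phase 5–25 Hz FIR wingbeat band-pass; flight
  epochs where the 50 s running mean of the rectified wingbeat signal
  exceeds 20 m/s²; landing detection (jerk peak + coincident broadband
  audio transient + post-event flattening); tilt-corrected compass
  heading by gimballing the 3 Hz low-passed magnetic field with pitch and
  roll from the low-passed accelerometer; foraging bouts as intervals of
  high heading variation (envelope threshold 0.05 rad, escalated to 0.3
  when a night over-segments into more than 10 mode switches).
- **Track segmentation** — GPS regularization to 10 s in local projected
  metres; first-passage time (FPT) for radii 5–400 m; the operating scale
  as the radius maximising var(log FPT); Lavielle penalized-contrast
  changepoint segmentation (dynamic programming, ≥ 5 locations/segment,
  ≤ 50 segments); Sarle's bimodality coefficient; a 2-component Gaussian
  mixture over per-10 s distances whose traveling-component lower
  quartile is the foraging/traveling threshold.
- **Energetics** — length→dry-mass power laws weighted by the dominant
  prey orders per niche (ground: Carabidae 78% / Orthoptera 22%; aerial:
  Diptera 65% / Lepidoptera 35%); caloric densities 25.4 (ground) and
  21.3 kJ/g dry (aerial); the mastication-ratio estimate of aerial prey
  mass; nightly intake for lower/higher aerial-mass estimates; 50–82%
  assimilation; allometric field metabolic rate scaling (exponent 0.7);
  and the prey-profitability index

  P(i) = prey caloric value(i) / (handling time(i) + time between
  attacks(i)) × success ratio(i)   [J/s]

- **Synthetic tag data** — seeded scenes with search/approach/buzz call
  trains, ~7 kHz damped chew transients placed between calls, broadband
  landing transients co-timed with accelerometer spikes, wingbeat
  oscillation, heading bouts, duty-cycled recording (30 s on/off), and
  commute/area-restricted-search GPS tracks; every generated event is
  written to a truth log.

## Worked example

The numbered scripts under `analysis/` run the chain on one simulated
night (seed 3: 420 s of 94 kHz audio with 5 gleaning and 5 hawking
attacks, and a 30 min GPS track with 100 m search patches):

```bash
python analysis/01_simulate_tag_data.py
python analysis/02_detect_attacks.py
python analysis/03_motion_segmentation.py
python analysis/04_gps_segmentation.py
python analysis/05_energy_budget.py
```

which prints, among other lines:

```
5194 calls, 5 buzzes detected
glean: PPV=1.000 FNR=0.000 (TP1 FP0 FN0 TN4)
hawk: PPV=1.000 FNR=0.000 (TP4 FP0 FN0 TN1)
landings: detected [96.11, 141.67, 187.22, 232.78, 369.44] vs truth [96.11, 141.67, 187.22, 232.78, 369.44]
operating scale (max var log FPT): 70 m (generator patch radius: 100 m)
mixture threshold: 77.6 m per 10 s
success ratios: {'glean': 0.2, 'hawk': 0.8}
ingested energy: 1.97 kJ (lower aerial mass) - 3.52 kJ (higher)
allometric FMR of a 30 g bat (from 45.8 kJ/day at 18 g): 65.5 kJ/day
```

Reading this: all five feeding buzzes (one per hawking attack) and all
five landings (one per gleaning attack) are recovered exactly; the
chewing-based success classifier reproduces the ground-truth success
labels (PPV 1.0); the FPT analysis places the movement operating scale
near the generated 100 m patch radius; and the energy model converts the
five successful captures of this short scene into ingested kJ under both
aerial-mass estimates. A sixth script,
`analysis/06_detector_validation.py`, repeats the success classification
over hundreds of seeded windows and full synthetic nights of ≥ 500
attacks per strategy, recovering the configured nightly success
probabilities (76% aerial, 30% ground) to within sampling error.

The same stages are exposed as a CLI (`batforage simulate|acoustics|
motion|trackseg|energetics|run`) and as plain library functions
(`batforage.acoustics`, `batforage.motion`, …).

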