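# Methods

## Setting and signal model

One night of data is an aligned set of 1 Hz channels: eight pillow
pressure readings `p_0..p_7` (FSR sensors in a line, index 0 leftmost;
arbitrary force units), a sound-pressure level (dB), contactless body
temperature (°C), room temperature (°C), relative humidity (%), CO2
(ppm), and optionally illuminance (lux) and heart rate (bpm).  Time is
integer seconds from session start; every derived event is a half-open
interval `[start, end)` on that grid, which makes duration arithmetic
and per-second attribution exact.  Missing samples are not modelled:
gaps must be imputed upstream (hold-last, at most 5 s) before ingestion.

The pipeline assumes exactly one sleeper whose head rests on the pillow;
an off-pillow state is recognised only as total pressure below a
presence threshold (5 % of a calibration head-on mean, default 10 units).

## Posture discrimination

The lying posture shows as the shape of the pressure profile: centered
mass for supine, mass shifted toward one end for lateral postures.  Two
classifiers share one interface:

* **Centroid heuristic** — the pressure-weighted mean sensor index
  `c = Σ i·p_i / Σ p_i` is scale-free; cuts at `c ≤ 3.0` (left),
  `c ≥ 4.0` (right) leave the symmetric center 3.5 supine.  Which body
  side maps to low indices is a pure convention (`left_is_low_index`),
  configurable because the hardware layout fixes it, not the data.
* **Margin classifier** — an RBF-kernel SVM (scikit-learn, standardized
  inputs, `C = 10`) over 18 per-window features: 8 per-sensor means, 8
  per-sensor SDs (population), the centroid of the mean profile, and the
  mean total.  Windows are one minute by default, matching the
  discrimination cadence.

Night segmentation uses a variable cycle: 60 s windows normally, 10 s
windows whenever a supra-threshold pressure change lies ahead within the
prospective window, so posture boundaries resolve to ±10 s.  Movement
frames carry no posture, so a window containing movement is judged on
its quiet frames from one side of the movement only; a pure-movement
window keeps the previous posture.  Adjacent equal-posture windows merge,
and each boundary emits a posture-change event.

## Event detection

**Toss-and-turn.**  The movement statistic is
`delta(t) = Σ_i |p_i(t) − p_i(t−1)|`.  The threshold is configurable
with a data-driven default of 4× the median nightly delta — the median
tracks the sensor noise floor, making the default invariant to the
arbitrary force scale.  An event opens when `delta` exceeds the
threshold and closes at the start of the first run of 5 consecutive
at-or-below-threshold seconds ("no pressure change for 5 s" ends the
movement); at-threshold noise therefore never opens an event and brief
pauses inside one movement do not split it.  Event duration is a
first-class output: for staging, how long the body moved matters more
than how often.

**Snoring.**  The sound channel is an SPL series, not audio.  A capture
opens strictly above 30 dB, closes when the level falls back or at 15 s,
and the detector re-arms 2 s after the close — mirroring a
threshold-armed recorder.  Distinct threshold crossings are distinct
events even when seconds apart.  Each event records its peak dB and the
onset-to-onset interval to its predecessor; regularity is the
coefficient of variation (population sd / mean) of the trailing window
of 5 intervals, regular iff CV ≤ 0.25.  The cut operationalizes the
qualitative contrast between metronomic ~3 s snoring and erratic
snoring; it is configurable, and events without a full trailing window
report an undefined flag rather than a guess.

**CO2 banding.**  Left-closed bands: good < 400 ≤ average < 700 ≤ poor
< 1000 ≤ very poor (ppm).

**Heart rate.**  Maximal runs with rate strictly below 60 bpm
(bradycardia) or strictly above 100 bpm (tachycardia); runs shorter than
5 s are dropped as sensor flicker, since real episodes last minutes.

**Temperature artifacts.**  The contactless sensor reads the head, so a
posture change produces a spurious dip to ~33.5–34.0 °C.  Samples within
±30 s of any posture-change boundary are flagged and excluded from all
downstream temperature statistics (an all-masked epoch falls back to its
raw samples).  An optional additive offset models the up-to ±2.0 °C
seasonal calibration drift of the sensor.

## Two-stage scoring

Per 60 s epoch the feature builder counts events by onset epoch
(movement duration by overlap), computes the regular fraction of snore
windows, artifact-masked temperature statistics, environment means, and
the dominant posture.  The rule-based scorer is a linear weighted sum of
three bounded sub-scores:

```
nrem_score = 0.5·s_move + 0.3·s_snore + 0.2·s_temp
s_move  = 1 / (1 + toss_turn_rate·epoch_len/60)
s_snore = snore_regular_frac   (0.5 when the epoch has no snoring)
s_temp  = 1 / (1 + body_temp_std)
```

NREM iff `nrem_score ≥ 0.5`.  The functional form is this package's
realization of relations the source signals only support
qualitatively: no closed form exists to derive, so the design criteria
were boundedness (each sub-score in [0, 1]), monotonicity (more
movement never raises the NREM score; more regular snoring never lowers
it — property-tested), and a neutral 0.5 contribution when a channel is
uninformative.  The reciprocal form of `s_move` encodes that the
movement rate is inversely tied to how long each posture is maintained.
One substantive reading had to be fixed: frequent tossing and turning is
treated as REM-ward evidence (with sustained movement plus tachycardia
marking terminal wake), and quiet maintenance of one posture as
NREM-ward.  Movement gets the largest weight because it is the most
direct body signal; weights are configurable and were not fitted.

Tree classifiers (decision tree; random forest, 200 trees) train on the
same feature table.  Heart-rate columns are excluded from predictors by
a hard-coded predictor list — heart rate is the validation reference
(epoch NREM iff mean ≤ 65 bpm and sd ≤ 5 bpm, thresholds between the
slow-stable and fast-variable regimes), and keeping the channels
disjoint makes agreement between scorer and reference a real validation
statistic rather than a tautology.

`evaluate` treats REM as the positive class, thresholds scores at 0.5,
and integrates the empirical ROC by the trapezoidal rule
(scikit-learn's ROC points; an all-thresholds brute-force enumeration
serves as the test oracle).  A single-class reference raises rather
than reporting an undefined AUC.  WAKE reference epochs map to REM for
the binary comparison ("not in quiet sleep"); the hypnogram type itself
keeps all three labels.

## The synthetic-night simulator

The simulator emulates the signal structure the sensor suite exhibits,
with every injected event recorded as ground truth:

* **Hypnogram** — ~90 min cycles of NREM then REM, REM fraction
  interpolating 0.15 → 0.35 across the night, terminal wake tail
  (2 epochs).  Deterministic given the parameters.
* **Posture/pressure** — per-posture mean profiles over the 8 sensors
  plus Gaussian sensor noise (sd 5), a per-segment head-position shift
  (sd 1.0 sensor units ≈ 4.4 cm, the array pitch) and a lognormal
  contact-pressure scale (sd 0.1) — head position and loading genuinely
  vary across a night, and these two terms are what keeps the posture
  benchmark from being trivially separable.  Posture changes are placed
  in REM/wake (2 per REM hour; clean stage recovery is deliberately
  well-posed, and the rate is configurable to break it), with 4 s
  supra-threshold transients; light movements (90 per REM hour, 1–3 s)
  model the frequent twitching of REM sleep.
* **Snoring** — bursts (1–3 s, N(40, 3) dB) over a 25 dB floor; onset
  intervals N(3, 0.3) s in NREM and N(6, 4) s in REM, floored at 3 s so
  that every injected burst stays separable under the 2 s re-arm delay.
  The floor sits below the 30 dB threshold so detection is non-trivial
  but controlled.
* **Heart rate** — N(58, 2) bpm in NREM, N(75, 8) in REM, N(80, 6) in
  wake; ~2 bradycardia and ~1 tachycardia episodes of ~60 s injected
  into REM.  The stage means are stand-ins chosen inside the documented
  slow/fast regimes; no per-participant distributions exist to copy.
* **Environment** — CO2 from 450 ppm drifting +60 ppm/h with +10 ppm
  bumps during snoring; body temperature 36.5 °C with uniform
  33.5–34.0 °C dips for 10 s at posture changes; room temperature
  23 → 22 °C; humidity ~45 %; illuminance ~10 lux.

All draws come from one seed through named substreams (one per
channel, spawned in a fixed, append-only order), so a fixed
(parameters, seed) pair is bit-reproducible and adding a channel never
perturbs another channel's stream.

**What passing tests do and do not show.**  The simulator's stages are
epoch-aligned and its channels are conditionally independent given the
stage; real nights have gradual transitions, within-stage
nonstationarity, correlated artifacts and snore-free stretches.
Synthetic benchmark numbers are therefore upper bounds on real-data
performance — the staging benchmark in particular saturates, because
stage-conditioned generative channels make epochs nearly separable.
What the tests do establish is that each detector implements its stated
rule exactly (brute-force oracle equivalence), that the scorer's
monotonicity and conservation invariants hold, and that the full
pipeline recovers what was injected at realistic noise levels.

## Numerical and interface choices

* CSV storage (RFC 4180, fixed header `t, p0..p7, sound_db,
  body_temp_c, room_temp_c, humidity_pct, co2_ppm, lux, hr_bpm`), floats
  at full repr precision, read back with round-trip float parsing, so
  write-then-read is the identity; gzip by file suffix.  Absent optional
  channels are omitted, never zero-filled.
* Events of one kind are sorted and non-overlapping by construction;
  JSON serialization preserves attributes exactly.
* An event still open at stream end closes at stream end; detectors are
  unaffected by sub-threshold padding.
* An all-zero pressure window has no centroid: the feature vector
  substitutes the array center 3.5 after the presence threshold has
  already routed such windows to off-pillow.
* Population (ddof = 0) standard deviations throughout.
* Tie-breaks: `nrem_score = 0.5` scores NREM; a CV exactly at the cut is
  regular; CO2 bands are closed on the left.
* Benchmark problem sizes: the posture benchmark uses 500 one-minute
  windows per class with a stratified 80/20 split; the staging benchmark
  uses 20 six-hour nights (15 train / 5 held out, per-night AUC
  averaged).  These sizes give stable estimates (seed-to-seed spread
  under one accuracy point) while keeping a full run in seconds.

## Known limitations

* Two-stage scoring only; the four-stage architecture of clinical
  scoring (and PSG concordance generally) is out of scope, as are raw
  audio analysis, apnea diagnosis, and image-based verification.
* The heart-rate reference is itself a heuristic; injected bradycardia
  lowers an REM epoch's mean rate and can flip the reference label, so
  even perfect staging will not reach 100 % agreement with it.
* Three lying postures; prone is indistinguishable from supine for a
  head-only pressure line and is not modelled.
* The rule weights and thresholds are defaults to be tuned per sleeper;
  nothing in the package fits them to data.
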