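# Methods

This note records the model, the numerical conventions, the defaults and
the design choices behind `beatwalk`, and what the synthetic generators do
and do not emulate.

## The measurement model

The experimental design the package analyzes fixes tempo (130 BPM) and
trial duration (30 s) across all stimuli, and instructs participants to
walk in synchrony with the beat on a circular path (diameter 15 m).  Under
synchrony the step rate is pinned to the beat rate, so between-song speed
differences are stride-length differences — a *vigor* response, separate
from timing entrainment.  The analysis chain therefore needs three
quantities per trial: walked distance (from heading), cadence (to verify
synchrony), and a per-song speed aggregated over participants on a scale
where individual physique cancels out.

### Walking speed

The hip sensor reports heading relative to magnetic north.  On a circular
path, distance is `d = |θ_end − θ_start| · r`.  The heading is **unwrapped
before differencing**: the raw stream is wrapped to [0, 2π), and a 30 s walk
at typical speeds covers close to (or more than) a full lap of the 47.1 m
circumference, so the naive modular difference would be wrong.  Gaps longer
than 1 s in the timestamps make a trial unusable.  Speed is distance over
the recorded span.

### Walking tempo

Cadence comes from the magnitude spectrum of the de-meaned foot
acceleration norm `√(x²+y²+z²)` (the axis assignment of a foot-worn sensor
is posture-dependent; the norm is orientation-free).  The signal is
zero-padded so the DFT bin width is exactly 0.5 strides/min (6000 points at
50 Hz), the peak is searched in a plausible 30–120 strides/min band, and
the peak frequency is doubled — one foot strikes once per stride, i.e. once
per two steps.  A trial is *synchronized* when |cadence − stimulus tempo| ≤
2 steps/min (4 DFT bins); tolerance is configurable.  Double and half
tempo are classed separately; everything else is "other".

### Normalization

Only synchronized trials are acceptable.  Per participant, acceptable song
speeds are divided by that participant's mean speed over acceptable
metronome trials and scaled by 100; the per-song speed `v_s` is the mean of
those normalized values over participants.  By construction the metronome
baseline is exactly 100 units — this identity is computed, not assigned,
and is one of the quantities `scripts/acceptance.py` rechecks.
Participants with no acceptable metronome trial are excluded with a
warning.

## Sonic features

### Frame level

Two analyses run over the mono waveform (stereo is averaged down):

* **Loudness**: 30 ms Hann-windowed frames hopped every 5 ms; the
  magnitude-squared spectrum is weighted by six triangular filters with
  centers ≈118, 298, 570, 983, 1609, 2559 Hz.  Vertices sit at the
  neighboring centers, and the outer edges extend geometrically by the mean
  adjacent-center ratio, so the bank tiles the band without gaps.
  Loudness is band energy to the power 0.25; the total-loudness series is
  the fourth root of the summed band energies, which makes the exact
  power-law `loudness(a·x) = √a · loudness(x)` hold.

* **Note evidence**: 150 ms frames hopped every 20 ms; for each of the 52
  equal-tempered notes between 0.1 and 2 kHz (440·2^(k/12), k = −25..26),
  salience is a harmonic sum — spectral magnitude at the fundamental plus
  half the magnitude at harmonics 2 and 3, each taken as the maximum
  within ± one quarter-tone.  The harmonic terms make the salience robust
  to timbre at the cost of sub-octave "ghosts" at half the true salience;
  see the note floor below.

Frame times are labeled at **window centers**: a Hann-weighted energy
measurement is concentrated at the window center, and center labeling is
what makes detected onset positions coincide with physical event times.
Spectra are amplitude-calibrated (a unit-amplitude sine reads ≈1), keeping
all downstream feature scales O(1).

### Beat level

Stimulus tempo is known by design, so the beat tracker fits only the
*phase* of a rigid grid: the phase (searched over a centered range
(−IBI/2, IBI/2] at 1 ms resolution) maximizes the summed onset strength at
the grid points, where onset strength is the half-wave-rectified forward
difference of total loudness.  **Beat count convention**: a stimulus
carries as many beats as there are complete inter-beat intervals strictly
inside the clip — 64 for 30 s at 130 BPM.  The tracker also emits two
scalar oscillator outputs: the mean onset strength at the off-beat comb
positions of the 2× and 3× subdivisions, normalized by the envelope peak.
A stimulus whose beats are subdivided in two excites the 2× output; ternary
subdivision excites the 3× output; a plain metronome leaves both near zero.

Per beat, 47 features (names in `beatwalk.beats.BEAT_FEATURE_NAMES`):

* 7 onset loudness growths: max forward difference of each loudness series
  in a ±70 ms window around the beat (window width is a package choice,
  configurable).
* 3 event descriptors: onset position (total-loudness peak time minus
  nominal beat time), event length (time the total loudness stays above
  half the event peak), and event skewness (third standardized moment of
  the loudness samples in that run; symmetric events read ≈0).
* 21 per-interval loudness statistics: mean, standard deviation and
  temporal centroid of each of the 7 series within the inter-beat interval.
  The centroid is normalized to [0, 1] across the frames in the interval, so
  a uniform pattern reads exactly 0.5; an all-zero interval reports the
  neutral 0.5.
* 10 pitch descriptors: onset position of the most salient note, then
  (frequency, chroma, mean salience) of the top-3 notes by within-interval
  mean salience.  Notes below 0.55× the top salience count as *not found*
  and their slots are zero-filled — the floor sits above the 0.5 ghost
  level of the harmonic sum, so a single pure tone reports exactly one
  note.  Ties are broken toward the lower frequency.  Chroma is
  `round(12·log2(f/440)) mod 12`.
* 6 cosine similarities between consecutive beats over: subband onset
  growths, subband means, subband sds, subband centroids, top-3 note
  frequencies, and the same frequencies folded onto one chromatic octave.
  Zero vectors give similarity 0; the first beat copies the second so the
  matrix stays rectangular for the song-level transform.

### Song level

Each beat-level feature's per-beat sequence is de-meaned and projected on
`e^(−2πi b/p)` for p ∈ {2, 3, 4, 6}; the evidence is 2/N times the
magnitude.  De-meaning matters because 64 is not divisible by 3 or 6, and
without it DC leakage contaminates those probes; the 2/N normalization
makes a unit cosine read 1.0.  No windowing is applied.  The registry
numbering (ids 1–190: feature-major, period order 2, 3, 4, 6, then the 2×
and 3× oscillator outputs) is internal and deterministic.  The four
features a full-scale study retains most often are addressed by name
through `beatwalk.songlevel.TABLE2_ALIASES` (e.g. "period-3 evidence of the
similarity of subband centroids"); their numeric ids in any other
implementation depend on that implementation's ordering and audio and are
not reproducible from structure alone.

## Speed regression

Pairwise pre-selection fits all p(p−1)/2 two-feature OLS models (17,955
for p = 190).  For OLS with intercept, the correlation between fitted
values and the response equals the multiple correlation R, so each pair is
scored in closed form from the feature/response correlation matrix —
the full sweep is a few matrix operations, with a collinearity fallback to
the better single feature.  The top 10% of pairs (rounded up, boundary
ties included) vote for their members; the 10 most frequent features win,
ties broken by best-pair score.  A "single" variant (top-10 |r|) is
available for comparison.

Nested cross-validation splits n songs into 10 outer folds (sizes n//10
and n//10+1 — for 52 songs, 8×5 + 2×6; assignment is a seeded
permutation).  Per outer trial, pre-selection sees only the 9 development
folds, and all 1023 non-empty subsets of the 10 pre-selected features are
scored by pooled validation RMSE over the 9 development folds used as
inner folds.  Normal-equation Gram blocks are accumulated per fold so each
(subset, fold) fit is an O(k³) solve with k ≤ 11.  Subsets are enumerated
smallest-first and improvements must be strict, so ties go to the smaller
subset — with noiseless planted data this makes the chosen subset exactly
the planted support.  The winner is refit on the full development set and
predicts the held-out fold; pooled predictions give RMSE and PCC (and
explained variance = PCC²).  The final model refits the K most frequently
selected features (K = largest subset ever chosen; frequency ties broken
by larger mean |coefficient|) on all songs.  Features enter the regression
unstandardized; evidences are O(1) by construction, and a z-score switch is
not needed for the synthetic scales.

**What recovery can and cannot show.**  With 4 planted features, Σr² ≤ 1
caps the weakest feature's marginal correlation at 0.5.  On 46-song
development folds the maximum chance |r| over 186 noise features is ≈0.43,
so at the study scale (52 songs) exact support recovery is stochastically
impossible for *any* 4-feature planted model — the pairwise screen will
sometimes prefer a lucky noise feature.  This mirrors the selection
instability a full-scale study reports (only a minority of features common
to all trials).  The package therefore demonstrates exact noiseless
recovery on a 120-song synthetic cohort, where the chance ceiling (≈0.26)
clears the planted effects; at 52 songs the tests assert the weaker,
honest properties (pre-selection retains all planted features in ≥9/10
fresh draws; permuted responses give mean held-out PCC ≈ 0; held-out-fold
signal is never preferentially selected).

## Group statistics

Extreme groups: songs sorted by v_s; top 10 = activating (fastest first),
bottom 10 = relaxing (slowest first), and the 10 ranks centered on the
median rank = neutral (ranks 22–31 of 52).  "Middle" is not a uniquely
defined notion; centering on the median rank is the package's choice, with
song-id tie-breaks for determinism.  Speeds are compared by one-way ANOVA
with Scheffé pairwise contrasts (contrast F = T²/(k−1) against
F(k−1, N−k)); features by two-sample t-tests (activating vs relaxing,
equal-variance); ratings by Mann–Whitney U (exact or asymptotic via
scipy's method switch).  Raw p-values are primary — matching the reporting
style of small-n movement studies — with a Holm-adjusted column alongside.
Degenerate inputs (zero variance, all-tied ratings) are flagged rather than
raised.

## Synthetic generators

* **Stimuli.** Metronomes are 1 kHz, 10 ms pips with 2 ms ramps at exact
  beat times — deterministic given the spec.  Music-like stimuli place a
  seeded chord of 1–3 grid notes on each beat; the per-beat amplitude is
  `1 + mod_depth · cos(2πk/mod_period)` with mod_period ∈ {2, 3, 4, 6}, and
  the tone sustain scales with the beat amplitude (louder beats ring
  longer).  The sustain coupling is deliberate: cosine similarity is
  scale-free, so a pure level modulation could never move the similarity
  features — coupling level to articulation length is the minimal
  realistic mechanism (a crescendo is played longer, not just louder) that
  gives every feature family a planted periodicity.  Music-like stimuli
  get the 50 ms fade-in / 100 ms fade-out of the study's excerpts;
  metronomes get none.  An optional per-beat subdivision count exists for
  exercising the oscillator outputs.

* **Walk trials.** Heading advances at `speed/radius` rad/s plus white
  Gaussian noise, wrapped to [0, 2π); foot acceleration is gravity plus one
  Gaussian burst (σ = 30 ms, 10 m/s²) per stride at `cadence/2` per minute
  plus sensor noise.  Default sample rate 50 Hz, radius 7.5 m, duration
  30 s, cadence 130 steps/min, speed 1.4 m/s — the study's layout.  The
  sample grid includes the endpoint so the recorded span equals the nominal
  duration and noiseless ground truth is recovered to machine precision.

* **Planted speed datasets.** Features are iid standard normal over the
  full 190-registry; speeds are `100 + Σ c_j x_j + N(0, noise_sd)`.
  Default coefficients (3.0, −3.0, 2.5, −2.5) give each planted feature a
  marginal correlation of ≈0.45–0.54 — clearly above the pairwise screen's
  chance ceiling at n = 52 (≈0.33), i.e. an identifiable planted model,
  while keeping speed spread (sd ≈ 5.5 units around 100) in the realistic
  range for normalized walking speeds.

* **Ratings.** Nine bipolar adjective scales (0–100), Gaussian around 50,
  with planted ±12.5-unit group shifts on the five adjectives a
  full-scale study finds discriminative (good–bad, tender–aggressive,
  soft–loud, slow–fast, stuttering–flowing; the stuttering direction is
  reversed so activating music reads as stuttering).

**What the generators do not emulate**: polyphonic mixtures, percussion
timbres, vibrato, tempo drift or expressive microtiming in audio; gait
asymmetry, turning dynamics, sensor drift or magnetic disturbance in the
walk traces; rater-level variance in ratings.  Passing tests therefore
show that the *pipeline* measures what it claims on signals with known
ground truth — not that the specific feature set is optimal for real
recordings.

## Numerical conventions and edge cases

* Residual beat-to-beat jitter on perfectly periodic stimuli comes from the
  5/20 ms frame grids being incommensurate with the 461.5 ms inter-beat
  interval; it is bounded in tests (loudness statistics within ~10%,
  similarities > 0.995) rather than assumed zero.
* The first beat of a clip can sit at the analysis edge (its loudness rise
  precedes the first frame); onset growth is then computed on the
  available frames and may be zero.
* Silent clips: flat onset envelope anchors the grid at t = 0 with zero
  oscillator outputs; zero loudness intervals report centroid 0.5; zero
  salience reports all-zero pitch slots; zero vectors give similarity 0.
* Problem sizes in the test suite (30 s stimuli at 22.05 kHz, cohorts of a
  few participants, 20-seed Monte-Carlo loops, one 120-song recovery run)
  were chosen so the full suite completes in about a minute and a half on
  one core while still exercising every stage at study-realistic signal
  scales.

## Known limitations

* The beat tracker fits phase only; unknown-tempo audio is out of scope.
* The pitch salience floor (0.55 of the top note) suppresses harmonic
  ghosts but also genuinely quiet secondary notes; real polyphony would
  need iterative spectral subtraction.
* The oscillator outputs are comb projections of the onset envelope — a
  declared simplification of resonator-bank beat trackers.
* Scheffé contrasts assume homoscedastic groups; with n = 10 per group the
  F test is robust but not assumption-free.
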