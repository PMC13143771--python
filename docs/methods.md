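# Methods

`vogain` quantifies two gaze-stabilisation reflexes from portable
video-oculography during metronome-paced manual head rotation:

* **VVOR** (visually enhanced vestibulo-ocular reflex): the participant
  fixates an earth-fixed target while the head oscillates at low velocity;
  vestibular, smooth-pursuit and optokinetic drives combine and a healthy
  slow-phase gain is close to 1.
* **VOR-S** (VOR suppression): the participant fixates a head-fixed target
  (goggle-projected laser dot); the cerebellum cancels the VOR, gain is low
  at slow rotation and rises with frequency as pursuit-like suppression
  breaks down.

The input is a pair of synchronized head and eye velocity traces
(degrees/second, rightward positive) per test and commanded frequency
(0.25–1.25 Hz). The outputs per recording are the direction-specific
area-under-the-curve gains, the refixation-saccade rate, the realised
rotation frequency and the mean peak head velocity.

## Protocol geometry

The wall set-up places the participant 1.30 m from a wall with guide
markers 0.35 m and 0.47 m lateral of the fixation target, i.e. marker
angles atan(0.35/1.30) ≈ 15° and atan(0.47/1.30) ≈ 20° at the nose bridge.
Because the head's rotation axis lies ≈ 0.10 m behind the nasion, the
rotation amplitude for a turn landing between the markers is
atan(offset/1.40): 14.0–18.5° per side after rounding to the half degree.
For a sinusoid of amplitude `A` degrees at frequency `f`,
`Vpeak = 2πfA` (small-angle assumption, no spherical correction), which
gives the per-frequency predicted velocity bands printed by
`vogain geometry`.

## Pipeline

1. **Artifact flagging** (`preprocess.flag_artifacts`). Untracked samples
   (blink/pupil loss, `missing_mask`) become `track_loss`; |eye velocity|
   above 800 °/s — beyond any voluntary eye movement, so only lid
   artifacts reach it — becomes `blink_spike`. Flagged intervals are
   padded by 50 ms on each side.
2. **Window selection** (`preprocess.select_window`). The analysis window
   must contain ≥ 5 full rotation cycles, be free of flagged samples, and
   avoid the ramp-up/ramp-down of the oscillation: one full cycle adjacent
   to each quiet span of the head trace is discarded ("intermediate
   interval" rule; the count is configurable). Cycles are counted from
   head-velocity zero crossings. Trimming is keyed to the head's moving
   period rather than to artifact runs, which makes selection idempotent
   (re-selecting inside an accepted window is a no-op) and monotone
   (adding flags can only shrink or reject the window).
3. **Half-cycle segmentation** (`kinematics.segment_half_cycles`).
   Crossings use a ±5 °/s hysteresis band so noise near zero does not
   fragment cycles, with linear interpolation between the bracketing
   samples for sub-sample timing. Boundary crossings at the very start or
   end of a trace are recovered by mirror scans so that a window cut
   exactly at a crossing segments identically to the full trace.
   The realised frequency is `1 / (2 · median half-cycle duration)` — the
   median is robust to a single hesitant cycle — with an FFT peak
   available as an independent diagnostic.
4. **Profile classification** (`kinematics.classify_profile`). A single
   least-squares sinusoid at the realised frequency yields `r²`; harmonic
   distortion (energy of harmonics 2–5 over the fundamental) is measured
   on the *cycle-averaged, phase-aligned* half-cycle waveform. The
   cycle-locked estimator matters: pacing jitter randomises the phase of
   global harmonics (a 3f component decoheres three times faster than the
   fundamental), and broadband hesitations would otherwise leak into the
   harmonic regressors, so a global fit cannot separate a square rotation
   from a jerky one. Labels: distortion > 0.10 with odd harmonics
   dominating → `square` (an ideal velocity plateau scores ≈ 0.15, a
   lightly smoothed one ≈ 0.13, a paced sinusoid < 0.02); else `r² ≥ 0.90`
   → `sinusoidal`; else `jerky`. Thresholds are configuration values; the
   labels mirror the qualitative profile types seen in practice.
5. **Saccade detection and removal** (`saccades`). Detection runs on the
   residual eye velocity — eye minus a moving-median slow-phase estimate
   whose kernel is half a half-cycle long — because during VVOR the
   compensatory slow phase itself reaches ~100 °/s and a raw threshold
   cannot isolate fast phases across frequencies. Residual excursions
   > 60 °/s lasting ≥ 10 ms become events; events closer than 20 ms merge;
   bounds extend outward to threshold/3. Desaccading replaces each event
   span by linear interpolation between the samples just outside it,
   which preserves area-under-curve semantics without overshoot. The
   saccade rate is the event count over the window duration.
6. **Gain** (`gain`). Per half-cycle,
   `gain = ∫|desaccaded eye| dt / ∫|head| dt` (trapezoidal), attributed to
   the *head*-turn direction, then averaged per direction and overall.
   The unsigned ratio makes compensatory (opposite-sign) eye movement
   yield positive gain for both tests. Half-cycles whose peak |head| is
   below 10 °/s are skipped rather than divided by a near-zero area.
   Before integration both traces pass through the same 25 ms moving
   average: an identical kernel leaves a noise-free ratio exact
   (linearity) while suppressing the rectification bias that measurement
   noise adds to |·|-integrals when the slow phase is small (for a VOR-S
   trace at 0.25 Hz the uncorrected bias is ≈ +0.02 gain units; smoothed
   it is < 0.005).

## Cohort statistics (`stats_report`)

Spearman's rho (Pearson on midranks), the tie-corrected Friedman test and
the Wilcoxon signed-rank test (exact by sign-assignment enumeration up to
n = 25, implemented as a convolution over the doubled-rank lattice;
tie-corrected normal approximation beyond) are implemented from first
principles with explicit midrank tie handling, because cohort data are
heavily tied across five discrete frequency levels and tie behaviour
drives the reported correlations. They are cross-checked in the test
suite against brute-force enumerations and against scipy.

The cohort effect model is a linear mixed model (statsmodels `MixedLM`):
gain ~ frequency (categorical, Treatment-coded against the 0.50 Hz
reference) + direction (right = 1) + age (centred, per decade), with a
participant random intercept; pairwise frequency contrasts against the
reference are Bonferroni-adjusted. A singular fit falls back to ordinary
least squares with a logged warning. The reliability report gives
Spearman correlations of intended frequency with realised frequency and
with peak head velocity, per-level mean ± SD, and gain/saccade
descriptives (mean, 95 % t-interval, median, range) by frequency and
direction.

## Synthetic cohort generator (`simulate`)

No public recordings are deposited, so validation uses a generative model
of the protocol with full ground truth.

* **Head trace**: a concatenation of half-cycles, each a half-sine whose
  frequency is drawn per half-cycle from N(f₀ + tempo bias, 0.01 Hz) —
  the per-recording tempo bias (SD 0.008 Hz) reproduces the ≈ 0.01 Hz SD
  of realised frequency reported for paced rotation at 1 Hz — and whose
  velocity peak follows `Vpeak = 2πfA` with a per-recording amplitude
  drawn uniformly from 14–18.5° (±5 % per half-cycle). Quiet 0.5 s spans
  lead in and out of the oscillation. Profile variants: `square` replaces
  half-sines with linear-ramp trapezoids (10 % rise), `jerky` adds
  low-pass (< 3 Hz) velocity perturbations at 30 % of the peak.
* **Slow-phase eye**: `-g · head` plus N(0, 2 °/s) noise (a filtered VOG
  trace's noise floor). The gain law: VVOR g = 1.0 ± asymmetry(f)/2 by
  direction with the rightward excess interpolating 0.154 at 0.25 Hz to
  0.037 at 1.25 Hz (right-monocular recording geometry); VOR-S
  g = 0.20 + 0.36/Hz · max(0, f − 0.50) + 0.008 per decade of age.
  Participants carry a gain intercept (SD 0.02), an asymmetry offset
  (SD 0.02) and a VOR-S slope offset (SD 0.05/Hz), matching the
  between-participant variability implied by published cohort intervals;
  without such heterogeneity cohort standard errors would be
  unrealistically small.
* **Refixation saccades**: raised-cosine velocity pulses at
  frequency-dependent Poisson rates (VVOR 0.11→0.29 /s, VOR-S 1.1→3.4 /s
  rising to a plateau above 0.75 Hz, inside the observed clinical
  ranges), ≥ 150 ms apart. Each pulse's displacement cancels 80 % of the
  accumulated gaze-position error (relative to the earth-fixed target for
  VVOR, the head-fixed target for VOR-S), floored at 1.5° and capped at
  12°; duration follows a main-sequence rule (20 + 2.5·A ms, clipped to
  20–80 ms).
* **Artifacts**: blink intervals of 100–300 ms of missing eye data at
  0.5/min (participants suppress blinking during short fixation runs;
  the rate is conventional, not literature-derived).
* **Reproducibility**: one root seed; each (participant, test, frequency)
  recording gets an independent stream via `SeedSequence` spawn keys, so
  any subset regenerates bit-identically.

Defaults: 24 participants aged 20–79 (evenly spread), 5 frequencies ×
2 tests × 30 s at 220 Hz. A full cohort (240 recordings) simulates and
analyses in well under a minute on one CPU; the test suite uses smaller
cohorts (fewer participants or shorter recordings) where the property
under test does not need the full design.

### What the generator does and does not emulate

It reproduces the protocol's pacing, amplitude control, gain structure,
saccade statistics, blink dropouts and profile variants with known ground
truth — sufficient for parameter-recovery validation of every pipeline
stage. It does not model pupil-image noise spectra, goggle slippage,
torsional components, anticipatory versus corrective saccade timing, or
pathological phenotypes beyond what the gain/saccade parameters express.
Passing recovery tests therefore demonstrates correctness of the
algorithms under realistic signal structure, not clinical equivalence on
device data.

## Numerical choices and degenerate inputs

* Zero crossings interpolate linearly between bracketing samples; exact
  zeros count as the far side of a crossing so windows cut at crossings
  behave identically to the full trace.
* The head-area floor (10 °/s peak) guards the gain ratio against
  near-zero denominators; a recording whose half-cycles are all skipped
  fails with an explicit reason rather than returning numbers.
* Window selection returns rejection reasons (`min_cycles`, `artifacts`,
  `no_motion`, `no_crossings`) instead of raising, so cohort runs degrade
  gracefully; at 0.25 Hz with default blinks a few percent of recordings
  are legitimately unanalysable, as in practice.
* Wilcoxon exact p-values double the midranks so tied (half-integer)
  ranks live on an integer lattice; the two-sided p is
  `min(1, 2·min(P(W⁺≤w), P(W⁺≥w)))`.
* All rates/gains are validated non-negative; constant inputs to rank
  statistics raise explicit errors rather than returning NaN.

## Known limitations

* The AUC gain retains a small (< 0.005) residual bias from
  saccade-removal interpolation interacting with noise; it is visible
  only because the simulator's truth is exact.
* The detection thresholds (60 °/s, 10 ms, 20 ms) were not tuned against
  any reference detector; numerical agreement with other toolchains'
  saccade counts is not guaranteed, only recovery of injected events.
* The mixed model intentionally uses a single random intercept; it does
  not replicate any particular commercial GLMM covariance structure.
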