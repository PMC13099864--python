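# Methods

## The model in one paragraph

A big brown bat's FM broadcast (first harmonic, 100 → 20 kHz) returns from
an insect-sized target as two overlapping "glint" mini-reflections.  The
auditory periphery is modelled as a bank of bandpass channels whose
smoothed output envelopes have a temporal ridge width of roughly 350 µs —
the integration time of echo reception.  Echo arrival is marked by the
times at which each channel's envelope first crosses each of ten threshold
levels; subtracting the broadcast's own per-channel crossing times
("dechirping") collapses a delayed copy of the sweep onto a single
residual delay, and the pooled, trimmed-mean residual is the overall echo
delay (spectrogram correlation).  Two reflections closer together than the
integration time merge into one interference spectrum whose nulls sit at
`f = (k + 1/2)/δt`; the receiver locates the nulls as local minima of the
echo/broadcast channel-amplitude ratio and inverts the mean adjacent
spacing, `δt = 1/δf` (spectrogram transformation).  Reflections farther
apart resolve into separate event clusters and are reported as distinct
echoes.  A pursuit loop turns these percepts into flight: azimuth from the
interaural difference of the same detection events, fast beam steering,
rate-limited flight, and an accept/reject decision on the measured glint
delay once the target is nearly dead ahead.

## Receiver design

**Filterbank.**  81 Gaussian channels, 20–100 kHz at 1 kHz spacing,
implemented as zero-phase frequency-domain slices with complex-baseband
envelopes decimated 32× (31.25 kHz envelope rate; threshold crossings are
localised by linear interpolation, giving ~1 µs effective precision).
Zero phase makes the bank group-delay equalised by construction; the
acausal leading tails are handled by explicit pre-padding.  The single
operating point `σ_f = 1 kHz` (≈2.4 kHz FWHM) was chosen analytically to
satisfy both roles of the channel at once: its impulse-response envelope
realises the ~350 µs integration window with no extra smoothing (measured
chirp ridge width ≈ 385 µs), while its frequency resolution attenuates a
δt-periodic spectral ripple by `exp(-2π²σ_f²δt²)` — still ~17 % modulation
at δt = 300 µs, so nulls as close as ~3 kHz remain detectable.  Markedly
wider channels (e.g. 4 kHz FWHM) would erase the nulls for δt ≥ 200 µs;
markedly narrower ones would stretch the ridge beyond the integration
time.  A per-channel `bandwidths` array supports graded tuning widths, and
channels whose impulse response is shorter than `smoothing_time` receive
complementary envelope smoothing.

**Thresholds and latency trading.**  Ten levels spaced in dB from −30 to
−3 relative to the *segment* peak (broadcast and echo each referenced to
their own peak, which makes event times invariant to overall echo level).
Amplitude-latency trading adds 15 µs per dB that a channel's peak sits
below the segment reference — a slope chosen within the physiological
range for this species; the paper-level sources state the phenomenon, not
the value.  This is what draws the scalloped event pattern: null channels
are quiet, so their events retard.  Because the broadcast's own channel
profile enters the dechirp subtraction, the latency term cancels exactly
for a spectrally flat (single-glint) echo; for merged two-glint echoes it
leaves a small positive delay bias (tens of µs), visible in the worked
example in the README.

**Null extraction and inversion.**  Per-channel echo amplitude is taken as
the envelope peak inside a window around the analysed echo mode and
normalised by the broadcast's amplitude in the same channel, removing the
sweep's own spectral shape (band-edge tapers).  Local minima with ≥0.5 dB
prominence and ≥2-channel separation are refined to sub-channel precision
by parabolic interpolation.  Because the mean *adjacent* spacing
telescopes to `(f_last − f_first)/(n − 1)`, interior localisation errors
cancel and recovery error stays below ~1 % across δt = 40–340 µs.  The
inversion is validated for periodicity: a genuine two-glint spectrum has
uniform null spacings, so patterns whose spacing coefficient of variation
exceeds 0.2 (e.g. the aliased minima left by a pair just beyond the
filterbank's resolution, δt ≈ 400 µs) are not inverted.  An inverted value
at or above the integration time is likewise discarded.

**Resolved echoes.**  All upward crossings are kept (not only the first
per cell), residuals are clustered by single linkage with a gap equal to
the integration time, and clusters of ≥10 cells become echo modes.  A
1000 µs pair yields two modes 1 ms apart and no single-mode glint delay;
a 500 µs pair merges into one broad cluster with unmeasurable nulls —
the grey zone between one merged and two resolved echoes.

**Binaural processing.**  The interaural time difference is the trimmed
mean of the differences of the *same* channel × threshold events between
the ears (cell-wise pairing), restricted to cells near the analysed mode
and to physically possible differences.  Pooling cell-wise differences —
rather than differencing two independently clustered delay estimates —
keeps the ITD robust (±0.2 µs on clean echoes, ~0.3° azimuth) even when
neighbouring echoes merge differently in the two ears.  Azimuth is
`arcsin(c·ITD/a)` with ear separation a = 14 mm.

## Synthetic scenes: what they emulate and what they do not

The generator builds 2D range/crossrange arenas of stationary two-glint
targets.  Echoes are exact delayed copies of the broadcast (frequency-
domain phase ramps, sub-sample delays) over mouth → glint → ear paths, so
interaural differences and glint-delay projections emerge from geometry;
independent white noise is added per ear at 40 dB SNR re a glint echo.
As in the source simulations, spreading loss, atmospheric absorption,
beam/receiver directionality, clutter, target motion and conspecific
interference are *not* modelled (an optional flag adds spreading +
absorption for experiments; it is off everywhere in the tests).  Passing
tests therefore demonstrate the signal-processing and control logic under
idealised acoustics, not performance against real echoes.

By default generated targets are "facing": the glint pair lies along the
line of sight, presenting its full end-on delay to any observer.  With a
world-fixed glint axis the measured spacing scales by |cos θ| of the
aspect angle, which makes shape classification ill-posed in a multi-target
scene — a 200 µs pair viewed 60° off-axis is acoustically identical to the
desired 100 µs pair, and conversely the desired target read obliquely is
rejected.  Fixed-axis targets remain available per target (`axis_mode`,
explicit axis in scene files) and the projection geometry is exact and
tested; the facing default makes "glint spacing" an intrinsic target
property, which is the regime the search task needs.

Scene-preset coordinates (the 1/5/8/20/90-target layouts) are this
package's documented constants; the published figures give only
qualitative arrangements, so epoch counts are not comparable run-for-run.
Random scenes draw 5–20 targets in a 3.6 m × 2.8 m arena with ≥0.45 m
separation, distractor spacings from {30, 50, 200, 300, 1000, 2000} µs and
exactly one 100 µs target.

## Pursuit control

Per epoch: slew the beam toward the estimated azimuth (≤60°/epoch), turn
the flight heading toward the beam (≤15°/epoch at cruise speed), advance
0.3 m.  Two behaviours proved necessary beyond the basic loop:

* **Approach-phase deceleration with speed-scaled turning.**  Within
  ~1.2 m the bat slows in proportion to range (floor 0.05 m/epoch).  The
  turn limit is a limit in *time*, so the allowed turn per epoch scales
  inversely with speed (capped at 90°); without this the turning radius is
  speed-independent (~0.19 m) and a tangential pass settles into a stable
  orbit that never brings the azimuth inside the classification gate.
* **Re-acquisition.**  A tracked echo that disappears (target slipped
  behind the beam, or merged with a neighbour) is flown through for up to
  three epochs, then the bat circles toward the side it last saw the
  target, slowed so the loop stays in place; after 10 failed epochs the
  candidate is shelved.  Shelved-as-lost targets get a second chance
  before a scene is declared exhausted — only classified rejections are
  permanent.

**Classification.**  Requires the target within the 5° azimuth gate *and*
within 2 m (at long range neighbouring echoes can merge into the tracked
one and corrupt the measurement).  Accept needs |glint − 100 µs| ≤ 20 µs
and a single-mode echo; resolved multi-mode echoes and measured wrong
spacings reject.  A missing glint measurement is treated as a dropout and
re-probed up to 4 in-gate epochs before rejecting.  Verdicts must agree on
two in-gate looks before they commit (out-of-gate epochs between looks do
not reset the tally) — one look can be corrupted by a momentarily
overlapping neighbour, and the bat's own motion de-correlates such
accidents.  Capture is scored when the accepted target's position lies
within 0.1 m of the epoch's flight segment (a 0.3 m step can hop over a
point check).

**Bookkeeping vs perception.**  Which *echo* belongs to which scene target
(selection at scan time, gating of the tracked echo, attribution of a
resolved second mode to the tracked target rather than to a collinear
neighbour behind it, and the rejected-target memory) is resolved with the
synthesizer's per-target truth table.  These are data-association
problems that a real bat solves with cues this model does not carry
(spectral signatures, track continuity at a 10× higher pulse rate); all
*measurements* — delay, azimuth, glint spacing — remain the receiver's
own.  A consequence worth stating plainly: a distractor target sitting
nearly collinear ~0.3 m behind the tracked one is acoustically identical
to a deep rear glint, and only the bookkeeping disambiguates them.

## Numerical and degenerate-case choices

* Sound speed 340 m/s (makes 17 mm ↔ 100 µs exact); sampling 1 MHz;
  broadcast 2 ms with 5 % raised-cosine tapers.
* Delay estimates use a 25 % two-sided trimmed mean; ≥10 defined cells are
  required ("no echo" otherwise); confidence is the fraction of cells
  within ±50 µs of the estimate.
* Broadside view of a fixed-axis pair returns glint delay 0 (valid, not an
  error); silent input yields an all-absent event matrix; nearest-target
  ties break toward the smaller target id.
* Determinism: one `numpy` generator seeded per run drives all noise, so
  identical (scene, parameters, seed) reproduce identical epoch records;
  random scenes are bit-reproducible from their seed.

## Problem sizes used in the tests

The behavioural acceptance check runs 100 random scenes (5–20 targets,
seeds 0–99) to a 600-epoch cap; typical runs capture in 15–350 epochs.
Receiver-level checks use single synthesized echoes at 6 ms delay in
16k-sample windows.

## Known limitations

* The overall delay of a merged two-glint echo is biased late by a few
  tens of µs (latency trading on the interference scallop); ITD and glint
  inversion are unaffected.
* Glint delays between ~350 and ~700 µs are a grey zone: neither the null
  pattern (too finely spaced for the channels) nor cluster splitting (event
  spreads chain across the linkage gap) measures them, and such targets are
  rejected through the dropout budget rather than a positive measurement.
* Dense scenes whose targets momentarily coincide in delay produce
  unmeasurable merged echoes; the controller waits them out rather than
  segregating them, which inflates epoch counts.
* No propagation losses by default: echo amplitude does not rank target
  distance, only delay does.
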