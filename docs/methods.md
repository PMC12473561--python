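# Methods

This note records the models, parameter choices and numerical decisions behind
`treadgait`, in the spirit of a package methods appendix: what is assumed,
what is configurable, and what the validation does and does not demonstrate.

## Coordinate frame and input model

All computation happens in a canonical anatomical frame: x = medial–lateral,
y = anterior–posterior (anterior positive), z = vertical (up positive);
millimetres and seconds throughout. Device exports differ (some trackers put
the walking direction on x), so readers accept an `AxisConfig` that permutes
and sign-flips source axes once, at load time; the mapping is an isometry and
is property-tested as such. The input is a 20-joint skeleton at a nominal
15 Hz with a per-frame, per-joint validity mask: a sample that is absent or
unparseable is *invalid*, never zero-filled, and gaps are handled per joint —
a lost left hand must not invalidate right-foot event detection.

## Missing data

Depth-camera body tracking loses joints intermittently, concentrated at the
feet. The policy is deliberately minimal: a maximal invalid run of length
exactly 1 (with valid neighbours) is filled by linear interpolation in *time*
(robust to clock jitter), flagged `imputed`; anything longer stays invalid and
excludes the strides that span it. Model-based filling (splines, Kalman) is
out of scope by design — at 15 Hz a two-frame gap straddles a sixth of a
stance phase, and inventing data there would contaminate event timing. The
quality report counts frame loss against a configurable required-joint set
(all 20 for CoM work, the four foot/ankle joints for gait events), reports a
per-joint breakdown and the gap-length histogram, and implements the
participant-level rule: a recording with stride loss strictly above 50 % is
flagged excluded (outputs are still written). With no candidate strides the
stride-loss percentage is reported as missing, not as zero.

## Centre-of-mass model

The body is a rigid system of 14 segments over the 20 tracked joints:
head+neck (merged), trunk, and bilateral upper arms, forearms, hands, thighs,
shanks, feet. Segment CoM: `P_i = P_u − l_i (P_u − P_l)`; whole body:
`CoM = Σ r_i P_i` with `Σ r_i = 1` enforced to 1e−9 on load. The shipped
`l_i`, `r_i` values are conventional Winter-lineage anthropometry normalised
to sum exactly to 1; they live in a YAML data file
(`data/anthropometric_14.yaml`) and are fully user-replaceable (the loader
validates structure, ranges and mass closure; `normalized()` rescales a
near-miss table). Two modelling choices worth knowing:

- The trunk segment runs between the real `spine_chest` and `pelvis` joints
  rather than virtual shoulder/hip midpoints. This keeps the model a pure
  function of tracked joints and makes the 14 segments reference exactly the
  20 canonical joints.
- No sex-specific tables by default; alternates can be supplied as files.

CoM validity propagates per frame: if any referenced joint is invalid the CoM
frame is invalid (no exception — downstream stride exclusion handles it).
Because the model is linear in joint positions the trajectory computation is
a single weighted sum per frame.

## Gait events

On a treadmill the stance foot translates backward at belt speed and the
swing foot returns forward, so the foot's AP velocity is negative in stance
and positive in swing; heel-down and toe-up are its sign changes. Vertical
position thresholds were rejected: at 15 Hz with millimetre jitter they are
unreliable, whereas the direction reversal is large (belt speed on one side,
comparable swing speed on the other).

Numerics, in order:

1. AP position is smoothed by a 3-frame centred moving average (edge frames
   dropped, not shrunk — a shrunk window biases the derivative); velocity is
   the central difference on actual timestamps. Invalidity propagates.
2. Sign changes between adjacent valid samples become candidate events
   (+→− heel-down, −→+ toe-up); a crossing spanning invalid frames is never
   fabricated. Exact-zero samples inherit the previous sign so a grazing
   touch cannot produce a double event.
3. The coarse crossing time (linear interpolation between the bracketing
   smoothed-velocity samples) is refined on the *raw* first differences: the
   frame interval containing the corner has an average velocity that is a
   duration-weighted blend of the pre- and post-event velocities read from
   the adjacent pure intervals; solving that blend for the corner time is
   exact for a sawtooth at any sub-frame phase. This matters: plain
   interpolation of the ±2-frame smoothed velocity carries an O(dt) bias
   wherever stance and swing speeds differ, which at 15 Hz is ~10–20 ms —
   small against a 1.2 s stride but a 10 % error on a 0.12 s double-support
   component. The refinement falls back to plain interpolation when invalid
   samples or noise break the local pattern.
4. Debounce: a crossing within `min_interval` (default 0.3 s) of the last
   accepted event is rejected; output strictly alternates kinds. The default
   reference joint is the ankle for both event kinds (always tracked, same
   sign-change signature); the toe point can be configured for toe-up.

Bilateral validation merges both sides and flags physiological-order
anomalies (e.g. two same-side heel-downs with no opposite heel-down between
them) as warnings; strides missing a constituent event are excluded, never
patched.

## Stride metrics

A stride is heel-down to the next same-side heel-down. Belt speed is
estimated per stride as the negated least-squares slope of the stance foot's
AP position over the central 60 % of stance (the ends are trimmed because
they straddle the event corners); stride length is belt speed × stride time —
the treadmill convention, since the body does not progress over ground.
Support times come from opposite-foot events (single support = opposite
toe-up to opposite heel-down; each double-support component = a heel-down to
the opposite foot's next toe-up; with duty factor d these are (1−d)T and
(d−½)T). Step width is the absolute difference of the mean stance-phase ML
positions of the two ankles. CoM excursions are per-axis max−min over the
stride, and the ML excursion over step width is the stability ratio. Every
exclusion carries a reason (`data_gap`, `missing_event`, `short_stance`,
`invalid_com`), and excluded rows are retained in the stride table. Subject
summaries are mean (SD) over non-excluded strides; gait speed is the mean
belt-speed estimate.

## Phase normalisation and spectra

Strides are resampled linearly in time onto a 101-point phase grid (the gait
convention of 0–100 % in 1 % steps) and mean-centred per axis; phase
alignment follows the left heel-down convention, and averaging uses left
strides only because the ML component of left and right strides is antiphase.
The resampling support includes one valid frame beyond each stride boundary
so float-rounded edges never clamp the interpolation; strides under 4 frames
are skipped with a warning.

The Fourier analysis runs on the longest contiguous valid run of the full
recording (records under 10 s are refused — the frequency resolution 1/T
would be meaningless). Each axis is mean-removed; the AP axis is additionally
linearly detrended (slow drift along the belt is common). The dominant
frequency is the magnitude-spectrum peak above 0.3 Hz, a guard that excludes
DC leakage without touching gait frequencies (slowest plausible stride
~2 s → 0.5 Hz). No window is applied by default: the record is two orders of
magnitude longer than a stride, so leakage is negligible next to bin width.

The bowtie projection pairs the phase-aligned mean ML curve with vertical and
with fore–aft; self-intersections of the closed mean polyline are counted by
brute-force segment-pair tests (adjacent segments skipped, transversal
crossings only). A 1:2 frequency relationship with a generic relative phase
yields exactly one crossing — the figure-eight.

## Statistics

Group comparison: pooled-variance (Student) two-sided t-tests on
subject-level metric means, df = n_a + n_b − 2; zero variance in both groups
with equal means is reported as t = 0, p = 1. Speed effects: per-metric OLS
with intercept on gait speed (slope, SE, t, p, R²); a constant regressor is a
degenerate design and raises. Multiplicity: with 13 metrics under test the
threshold is α/13 (0.05/13 ≈ 3.85 × 10⁻³). Session comparison: per-metric
*unpaired* t-tests across stride-level values of the two recordings — strides
are not naturally paired across sessions, and stride-level samples are what
give a single subject usable power. The t-test and OLS go through
scipy/statsmodels; the tests verify both against textbook closed forms to
1e−10 and calibrate their type-I error by Monte Carlo.

## The synthetic walker

The simulator is a kinematic (not dynamic) model of exactly the structure the
pipeline assumes, with every quantity the pipeline estimates available as
ground truth:

- **Feet**: stance = linear backward drift at belt speed; swing = forward
  return with velocity `belt + (v_peak − belt)·sin⁷(πu)`. The sin⁷ shape
  makes the foot leave and land at exactly belt speed with flat velocity
  shoulders, so the AP velocity flips −belt ↔ +belt sharply at events — the
  regime in which sub-frame event localisation is well conditioned. Vertical
  clearance is a raised cosine (50 mm default); foot ML is ±step_width/2.
- **Body**: pelvis and everything above it ride on sinusoidal drivers — ML at
  stride frequency 1/T, vertical and fore–aft at step frequency 2/T, with
  small phase offsets from −π/2 (vertical minima near double support, peak
  slightly after midstance) so the ML-vs-vertical Lissajous is a proper
  figure-eight rather than the degenerate retraced arc. Remaining joints hang
  off the pelvis and feet by stature-scaled offsets (knees midway between hip
  and ankle), so all 20 model joints exist. Arm swing is available but off by
  default.
- **Calibration by construction**: the kinematic tree is linear in the body
  driver, so the driver's gain onto the whole-body CoM is computed exactly
  (one finite difference) and compensated — the true CoM ML range is exactly
  2·a_ml. Vertical and fore–aft CoM additionally carry genuine leg-swing
  contributions, so their ground truth is taken from the noiseless model
  evaluated on a 10× dense grid (the continuous excursion, to ~0.002 mm).
- **Degradation**: isotropic Gaussian sensor noise and per-joint frame
  dropouts with a configurable gap-length distribution, from independent
  seeded streams; injected gaps are kept non-adjacent per joint so each
  realises its drawn length exactly, and every gap is ledgered
  (joint, start, length).

Default conditions (a ~3-minute steady walk): stride time 1.22 s (stride
frequency 0.82 Hz), belt 575 mm/s (stride length ≈ 0.70 m, gait speed
0.575 m/s), duty factor 0.6, step width 140 mm, CoM amplitudes a_ml = 24,
a_vert = 14, a_ap = 16.5 mm (per-stride excursions ≈ 48/30/43 mm), sensor
noise 2 mm, no dropouts. These are realistic comfortable-walking values for a
short walking-pad treadmill; the slowish belt matches the short deck.

**What passing tests show — and don't.** The simulator reproduces the
*statistical structure* the pipeline relies on (sawtooth feet, sinusoidal CoM,
white sensor noise, independent dropouts), so recovery results demonstrate
the pipeline's numerics: sub-frame event timing, unbiased support times,
belt-speed and step-width recovery, spectral structure. Real gait has
stride-to-stride variability, asymmetries, non-sinusoidal CoM harmonics,
correlated tracking error and systematic (not white) joint noise; none of
these are emulated, so validation here says nothing about tracker accuracy or
about physiological effect sizes — only that *given* joint tracks of this
quality, the computed metrics are faithful.

## Validation problem sizes and tolerances

The test and acceptance runs use 60 s simulations (≈49 strides/side at
T = 1.22 s) and a recovery grid of belt {600, 1000, 1400} mm/s × stride time
{1.04, 1.22, 1.38} s × noise {0, 1, 2} mm. Grid stride times are deliberately
incommensurate with the 15 Hz frame clock so event phases sweep across the
frame; integer-frame stride times (1.0, 1.2, 1.4 s) lock the phase and are
used separately for the event-recovery checks, where that aliasing is
harmless. Recovery tolerance is 3 % per cell on stride time/length, support
times, step width and CoM excursions; observed worst-case errors are ≈1 % for
timing metrics and ≈2–2.5 % for CoM ranges at 2 mm noise (the residual is the
extreme-value inflation of max−min under noise, partly offset by discrete
sampling of the peaks). Type-I calibration uses 1000 Monte-Carlo replicates
(tolerance ±0.02 around α = 0.05). All randomness is seed-controlled.

## Known limitations

- 15 Hz is the binding constraint: double-support components (~0.12 s) are
  under two frames long, so they are the most sensitive output; treat their
  per-stride values as noisy and rely on per-subject means.
- Stride length is belt-referenced (belt speed × stride time); body-referenced
  definitions differ on a treadmill and are not provided.
- The anthropometric defaults are population averages; per-subject scaling
  (mass, sex, limb proportions) is possible only by supplying a custom table.
- Event detection assumes treadmill walking; overground data (no backward
  stance drift) will not produce the required sign changes.
- The statistics are plain t-tests/OLS on (possibly autocorrelated) stride
  series; no mixed-effects or autocorrelation-aware inference is attempted.
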