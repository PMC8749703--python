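# Methods

## Problem setting

An on-spot 360° turn is recorded by four inertial sensors — sternum,
sacrum, and both shanks — each providing 3-axis angular velocity (°/s) and
orientation angles (°) at 60 Hz, labeled anatomically (flexion–extension,
lateral bending, axial rotation). Trials carry a group label (stroke
survivor SS / healthy individual HI), the leading-leg side (stroke
survivors lead with the unaffected leg) and the turn direction. Two
segmentations are computed: temporal, from the leading shank's gait
pattern, and spatial, from the trailing shank's cumulative rotation — the
trailing (affected) leg usually lacks a usable temporal pattern, which is
precisely why the spatial route exists.

## Temporal segmentation

The leading shank's flexion–extension angular velocity is filtered with a
4th-order low-pass Butterworth at 5 Hz, applied forward–backward
(zero-phase). Zero-phase application is a deliberate choice: it leaves the
time index of a symmetric pulse's maximum untouched, so event times carry
no filter lag; the cost is a squared magnitude response (≈ −6 dB at the
nominal −3 dB cutoff), which is irrelevant here because the swing pulses
live far below 5 Hz.

Each swing is a bell-shaped pulse. Detection:

* **mid-swing** — local maxima of the sign-normalized signal with
  prominence ≥ `prominence_frac` (default 0.3) times the global maximum
  and separation ≥ `min_separation_s` (default 0.3 s);
* **toe-off / heel-strike** — on each side of a peak, the first sample
  where the signal drops below `onset_frac` (default 0.1) of that peak's
  height, then extrapolated outward to the pulse base assuming a
  raised-cosine pulse shape: for that shape the q-height crossing sits at
  a fixed fraction `arccos(1 − 2q)/π` of the half-width inside each edge,
  so the peak-to-crossing distance is scaled by
  `1/(1 − arccos(1 − 2q)/π)` (≈ 1.26 at q = 0.1). Without this
  extrapolation a 10 %-height crossing clips about 10 % of the pulse
  support on each side and biases the stance fraction upward by ~8–11
  percentage points; with it the residual error is dominated by filter
  smear (≈ 1–3 pp, slightly negative). The correction is a flag
  (`bell_correction`) so the raw crossings remain available.
* Overlapping claims of adjacent swings are resolved by the midpoint rule
  (split at the midpoint between the two peaks).

Cycles run toe-off→toe-off, so stance (heel-strike to next toe-off) falls
inside one cycle and *n* swings yield *n* − 1 stance values; the turn is
first toe-off to last heel-strike. These boundary conventions are choices
— the quantities themselves ("duration of the turn", "stance portion per
cycle") do not pin them down — and are applied consistently to generator
and detector.

## Spatial segmentation

The trailing shank's axial-rotation angle is unwrapped (±180°
discontinuities, jump threshold half the wrap period), offset to start at
0, and sign-normalized so the turn is positive for either turning
direction. The total rotation is the actually covered angle (participants
cover ~360° but not exactly), never an assumed 360°. Small noise dips are
absorbed by the running maximum before crossing detection; a backtrack
beyond `backtrack_tol` (10°) is an error. Internal boundary *j* of a
k-partition is the sample nearest the crossing of *j*·total/k (nearest
rather than first-at-or-above halves the quantization error on fast
turns, where the mid-turn rotation rate can exceed 2° per sample at
60 Hz); the start/end boundaries are the first samples within `angle_eps`
(2°) of 0 and of the total. Partitions tile the turn as half-open sample
intervals, so duration-weighted per-partition means recompose whole-turn
means exactly. All k ∈ {2,…,7} are computed; comparison tables are built
for k = 2 and 4.

## Features

* Mean absolute angular velocity: mean |ω| over the interval. The absolute
  value is an interpretation — oscillatory trunk velocity has near-zero
  signed mean, and the published group values are all positive — and is
  documented as such.
* Range of motion: max − min of the angle over the interval.
* Sternum-relative-to-sacrum: per-sample difference traces (gyro and
  angle) summarized like any other channel. Differencing summary values
  instead would discard within-trial covariance and is incompatible with
  the published dispersion of the relative measures.
* Leading/trailing ratios: ratio of the two shanks' summaries per
  interval; denominators below 1e-9 yield NaN (flagged, excluded from
  group statistics).

## Group statistics

Unpaired two-tailed t-test, pooled variance by default (Welch selectable),
α = 0.05 per test with no multiple-testing correction — matching the
analysis convention this package mirrors; the inflation of family-wise
error across the many parameters is a known limitation. Degenerate input
(zero variance in both groups, equal means) returns p = 1 by convention.

Two percent conventions are exposed and must not be conflated:

* `pct_diff_reference(a, ref) = (a − ref)/ref·100` — whole-turn group
  contrasts ("SS 67 % larger").
* `pct_change_symmetric(x1, x2) = (x2 − x1)/((x1 + x2)/2)·100` —
  consecutive-partition comparisons. This midpoint-referenced form is
  antisymmetric and bounded by ±200 for same-sign inputs, which is how
  published partition drops can print below −100. The convention was
  identified by recomputing all 200 published comparison cells from their
  printed partition means: every one lands within ±1 of the printed
  integer (the regression test and acceptance script retain this check).

## Synthetic trials

The generator is the package's test bed, not a biomechanical simulator.
For a drawn cycle count *n*, duration *D* and stance fraction *f*:

* cycle period P = D/(n − f), swing width w = (1 − f)·P; leading-shank
  swing *i* is a raised-cosine angular-velocity pulse on
  [t₀ + iP, t₀ + iP + w] with per-pulse peak amplitude drawn from a
  truncated normal (default 6.6 (1.0) °/s, chosen so the whole-turn mean
  |ω| of the pulse train lands near the published leading-shank values for
  both groups' cycle structure). The turn then lasts exactly D and every
  cycle has stance fraction exactly f. The trailing shank swings in the
  n − 1 gaps (offset P/2). Shank flexion–extension angles are the pulse
  integrals in closed form.
* the trailing (and leading) shank rotation is a cubic smoothstep ramp
  from 0 to a total drawn uniformly in [340°, 380°] (signed by turn
  direction), wrapped to ±180° on output; its inverse has a closed form
  used by tests to predict partition boundaries analytically.
* trunk (sternum/sacrum) channels per direction are single-frequency
  oscillations (R/2)·cos(mπ(t − t₀)/D) holding the drawn range of motion R
  exactly with an integer number m of half-periods inside the turn,
  m = max(1, round(V·D/R)) for the drawn target mean |ω| V; the achieved
  mean |ω| = m·R/D is recorded as ground truth. The published whole-turn
  range, velocity and duration values are not mutually consistent for any
  single smooth oscillation (V·D < R in several rows), so range and
  duration take precedence and velocity targets act only through m.
* 1 s of quiet standing pads each side; zero-mean Gaussian noise (default
  SD 0.1 °/s and 0.1°) is added per channel; all draws are truncated
  normals parameterized by the published group means/SDs
  (`turnkin.reference_values`), with truncation bounds keeping draws
  physical (n ≥ 2 after rounding, 0.15 < f < 0.85, D > 1.5 s).

What the generator deliberately does **not** model: inter-segment
coupling (trunk phase is independent of shank phase), linear
acceleration, drift or bias, pathological asymmetry beyond group-level
parameter shifts, and realistic trunk-rotation kinematics during the turn
(the trunk physically rotates ~360°, but the published per-direction
velocity scales are treated as oscillation parameters instead). Passing
recovery tests therefore demonstrates correctness of the segmentation and
feature algebra under the assumed signal structure — not robustness to
every artifact of real IMU data.

## Problem sizes and numerical choices

Recovery checks use 100 trials per group (≈200 × ~600-sample trials,
seconds of runtime); calibration uses 500 replicate 14+14 cohorts drawn at
the parameter level (no waveform synthesis needed to test the t-test);
the closed-form t-test cross-check uses 1000 random small samples. Write
round-trips are exact to float repr; feature keys are unique and rows
deterministically sorted; pipeline reruns with the same config are
byte-identical (no timestamps in outputs, all randomness from the master
seed, output location excluded from the config digest). Observed
performance at defaults: cycle-count recovery ≥ 99 % of trials, stance
MAE ≈ 3 pp, duration error < 1 %, partition-boundary angle MAE ≈ 0.5°,
null rejection rate ≈ 0.06 over 500 cohorts (within 2 Monte-Carlo SE of
α) — recomputed live by `scripts/acceptance.py` and the acceptance tests.

## Known limitations

* The anatomical axis relabeling at ingest is a convention (configurable
  per placement), not a reconstruction of any vendor's sensor-to-segment
  calibration; Euler-sequence effects are out of scope.
* Stance is estimated from the leading leg's swing complement only; true
  double/single-support analysis would require foot-contact sensing.
* Whether orientation channels should also be low-pass filtered is
  unspecified in the source conventions; this package filters
  flexion–extension and lateral angles and leaves the unwrapped rotation
  angle unfiltered (the running maximum handles its noise).
* Printed p-values of the mirrored whole-turn table are not exactly
  reproducible from the printed means/SDs at n = 14 per group under
  either pooled or Welch t; the tables here report the computed values.
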