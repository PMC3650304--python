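# Methods

## Scope and data model

The package quantifies larval zebrafish prey-capture behavior from
dark-field high-speed video (250 or 500 frames/s, 8-bit grayscale) and a
1 kHz tail-position-sensor voltage. Because no recorded data ship with the
package, a first-class synthetic generator (`synthgen`) produces every
input with exact ground truth; all recovery claims in the test suite are
claims about this generator's output, discussed at the end of this note.

Coordinates are image coordinates throughout: origin top-left, x = column,
y = row, angles via `atan2(y, x)`. With y pointing down, a positive angle
is a rotation toward the fish's **right**; a prey left of the body axis has
φ < 0. This single convention fixes the signs of θ, γᵢ, φ, Δθ and the
Direction Index.

## Synthetic bout model

Tail-segment angle of segment *i* (1 = rostral, 5 = caudal):

    γᵢ(t) = turn_gainᵢ · A_turn · P(t)
          + seg_gainᵢ · A_osc · sin(2π f_osc (t − t₀) + φᵢ) · E(t) + ε(t)

- `P(t)`: raised-cosine (Hann) pulse starting at bout onset — the graded
  asymmetric turn component. Default width **1.5 tail-beat cycles**: the
  turn develops within the first half of the bout, but the pulse's spectrum
  stays below the tail-beat band (a one-cycle pulse has main-lobe content
  up to ~2 cycles' bandwidth and measurably perturbs the high-frequency
  spectral peak).
- `E(t)`: flat envelope with 5 ms cosine attack/release over the bout
  (default duration = n_cycles / f_osc; 3 cycles at 28 Hz ≈ 107 ms).
- `φᵢ = lag·(i − c)`: rostro-caudal phase lag (default 0.25 rad/segment).
  The pivot `c` is solved so that Σᵢ seg_gainᵢ·sin φᵢ = 0: the
  across-segment mean of the pure oscillation then has no quadrature
  component and integrates to zero over whole cycles — the symmetric motor
  component is direction-neutral by construction, which is its defining
  property. The lag and amplitude gradients are free parameters of the
  generator, not claims about the fish.
- Heading: θ(t) ramps from θ₀ by Δθ_true following the normalized integral
  of `P`, so θ(offset) − θ(onset) = Δθ_true **exactly** (no hydrodynamics;
  recovery tests need exact truth). `A_turn` defaults to Δθ_true, giving
  peak tail deflections comparable to the turn angle.
- Default A_osc = 20°, segment gains (0.2…1.0) and turn gains (0.3…1.0)
  increasing caudally, f_osc = 28 Hz, n_cycles = 3, 500 frames/s — the
  regime of natural orienting swims (tail beat 20–35 Hz, ~3 cycles,
  ~100–150 ms, |Δθ| up to ~60°).

Rendering rasterizes the 6-segment midline as a tapered bright silhouette
(anti-aliased signed-distance alpha, so binarization recovers the outline
with sub-pixel fidelity) over a static low-spatial-frequency background
texture; the prey is a small bright ellipse. Scene defaults: 256×256 px at
0.033 mm/px, body length 4 mm (~120 px), head width 0.5 mm. The head must
be elongated (width well below head-segment length): a near-circular head
makes the distance-map ridge inside it degenerate toward the rotation
reference and biases θ. Restrained mode fixes the head and draws two dark
eye ellipses inside the bright head at scheduled nasal-positive angles.

The sensor trace is the lateral tail-tip displacement (Σᵢ sin γᵢ in
segment-length units) resampled to 1 kHz, scaled by a gain, plus Gaussian
noise; quiescent stretches are pure noise.

Chained sequences place bouts at scheduled inter-bout intervals (IBIs are
exact by snapping bout durations to the frame grid), turn each bout by
`undershoot_factor · φ_pre` from current geometry, and step the eye angles
through the two-step convergence pattern (contralateral eye near-maximal
after bout 1, both maximal after bout 2; default levels ~13–15° before,
~31–32° converged, from the restrained-assay regime).

## Tracking pipeline

**Free mode.** Background subtraction, thresholding (Otsu by default;
histogram equalization is monotone, so binarization happens equivalently in
difference units), border-object rejection, small-object removal
(`min_area`, default 30 px², above the prey's area), hole filling, largest
component kept.

**Restrained mode.** No background frame: a linear histogram remap
`(v − median)·factor` suppresses background and stretches fish pixels,
followed by a fixed threshold and the same morphology. The dark eyes are
filled as holes, leaving a single solid silhouette.

**Midline.** The frame is rotated (bilinear warp on a padded canvas) so
the previous frame's heading lies along +x — the first frame uses the
silhouette's principal axis, disambiguated by putting the fatter end
forward. The exact Euclidean distance transform is computed and the ridge
is followed column-wise from the global distance maximum toward snout and
tail: in each column the maximal-distance pixel within ±6 rows of the
previous ridge point (ties → nearest), refined to sub-pixel by a parabolic
fit and smoothed with a 5-column moving average (the binary boundary
quantizes ridge rows in ±0.25 px plateaus). The head segment spans a fixed
30% of midline arclength from the snout (`head_fraction`; the swim-bladder
landmark is not resolvable in silhouettes), the remainder is split into
five equal-arclength segments. θ comes from a least-squares line over the
head ridge and is reported **continuous** (θ_rot + previous heading, no
±180° wrap) so Δθ across a bout never aliases; γᵢ are the tailward segment
directions minus the body axis.

Measured accuracy on rendered noise-free bouts: Δθ errors < 2°, tail-angle
RMS error ≈ 1°, rotation-equivariant to < 0.1°. The strict straight-pose
test renders the body at a half-integer row so chord-parity quantization
cancels; general poses carry the ~1° quantization floor.

**Prey.** Nearest-component tracking from a seed centroid with a jump
limit and gap tolerance; large objects (the fish) are rejected by area
first. Geometry: d from the head-segment center (an eye-midpoint reference
is available as an option; it differs by less than the head-segment
half-length), φ signed from the heading, angular size 2·atan(L/2d),
angular velocity by centered differences.

**Eyes.** The bright head is segmented by Otsu inside a user ROI; the two
largest dark holes are the eyes; moment-based ellipse fit; angle = major
axis vs body axis, nasal rotation positive, left/right assigned by the side
of the axis. Recovered within ±2° for eyes rendered at ±20°.

## Bout spectra

Window: 150 ms (free) / 300 ms (restrained) centered on the bout midpoint,
clipped to the series; N = round(window·fs/1000) (37.5 → 38 at
250 frames/s). Bessel band-pass 0.5–100 Hz, order 4, applied
forward–backward (zero phase; sign of the tail-angle integral and cycle
timing preserved). The 0.5 Hz cutoff settles far slower than the window,
so the trace is extended with its edge values for 3 cutoff time constants
before filtering and cropped after — a constant input is then seen (and
removed) as true DC, while a burst picks up no edge transient.

DFT → single-sided RMS amplitude spectrum per segment (B₀ = |A₀|, else
2|A_k|), summed over the five segments, cubic-spline interpolated on a
0.1 Hz grid over [0, 100] Hz. LF peak searched in [2, 8] Hz, HF peak in
[15, 45] Hz (supersets of the observed 3–5 Hz and 20–35 Hz ranges;
configurable). With the windowed Hann turn pulse the LF maximum sits at
the low edge of the search band rather than at a strict interior peak; its
amplitude is what carries the turn information (strictly monotone in the
turn amplitude, exactly linear for the isolated turn component).

DI = sign(∫ mean γ dt) × mean of the interpolated summed spectrum at
{3, 4, 5} Hz (reading the printed summation index as hertz on the
interpolated grid, matching the "average peak amplitude between 3 and
5 Hz"; raw-bin indices are the noted alternative). The sign uses a 2%
relative deadband (|∫| ≤ 0.02·∫|·| → DI = 0): a symmetric bout's
discretization residue is orders of magnitude below it, genuine ≥5° turns
are an order of magnitude above.

Cycle metrics use the >15 Hz component computed as the zero-phase
complement of a Butterworth low-pass (real positive gain at every
frequency, so crossing positions are exact); zero-crossing counting starts
at the first sample reaching 25% of the waveform's maximum, skipping filter
edge artifacts while keeping the low-amplitude final crossing under the
decaying envelope. n_cycles = ⌊crossings/2⌋; first-cycle duration = time
from onset to the second crossing.

Bout detection: onset at the first |x| ≥ threshold sample; offset when |x|
stays below threshold for `min_gap_ms` (50 ms); events shorter than 40 ms
discarded. With the generator's 5 ms envelope ramps, detected IBIs land
within ±2 frames of the schedule.

## Sequence statistics

IBIⱼ = onset(j+1) − offset(j). Straight-line fits use the plotting
reflection conventions: `point` (negate (x, y) pairs with x < 0 — pooling
left and right turns for signed-vs-signed scatter) and `mirror_x` (negate
x only, for magnitude responses); Pearson r is computed on the reflected
data, as plotted. Folded histograms use 10° bins: bin 1 = |a| < 5°, bin
m ≥ 2 = |a| ∈ [10m−15, 10m−5). Sequence start = first bout whose boundary
takes the contralateral eye above `contra_high` with the ipsilateral eye
above `ipsi_high` by the following boundary; the defaults (21.9°, 24.0°)
sit midway between the pre-sequence and converged levels, since no numeric
criterion for "near-maximal convergence" exists — both are config values.

## Closed-loop simulation

Event-driven in continuous float milliseconds (the sensor's 1 ms grid
applies to the stream detector; optional 60 Hz display quantization is off
by default so the loop's logic is separated from hardware artifacts). A
trial: target sweeps the configured zone (e.g. 35–55°) at configured size
(2:1 aspect) and velocity; the responder agent's swim, detected after a
40 ms intrinsic latency (configurable within the ~30–50 ms regime),
triggers translation of target+background at ~400°/s to the update
location (±10° of center; negative = undershoot, staying on the original
side). Paradigms: `open_loop` (first swim or 56 s timeout ends the trial —
the 60 s response-probability interval of the grid assay is a separate
config field), `sequence`/`hold_until_swim_end` (hold until swim end, then
move contralaterally, with an optional per-bout size/velocity escalation
schedule), `delayed_reappearance` (hide on detection, reappear at center
exactly at swim onset + configured delay; the second swim ends the trial).
Left/right sides are interspersed by seeded draw. Timing measures: Δt and
IBI from the end of the first swim, RT from the onset of the second
stimulus; Δt = IBI − RT is asserted on every log.

The responder agent is plumbing, not a fish model: RT = base (420 ms) +
15 ms/° × |update location| + 0.4 ms/ms × |Δt| − 3 ms per escalated
degree and °/s + optional noise, floored at 50 ms, with a 100 ms
refractory period and a response probability (constant or a
size×velocity function) for open-loop trials. It reproduces the
qualitative dependencies (fastest at central, on-time, escalated updates)
so the state machine can be exercised; its magnitudes are not claims.

## What the generator does and does not emulate

It emulates: dark-field photometry (bright fish on textured dark
background), the bout's two-component spectral structure, the two-step eye
convergence, scheduled IBI sequences, undershoot geometry, and sensor
noise. It does not emulate: hydrodynamics or body elasticity, pigmentation
or illumination inhomogeneity of real video, paramecium swimming
statistics, capture or struggle swims, or fin kinematics. Passing recovery
tests therefore demonstrates the correctness and internal consistency of
the measurement chain under the stated image model — not robustness to
arbitrary real recordings, for which thresholds (`min_area`, remap factor,
detection thresholds) are exposed as configuration.

## Problem sizes

The verification panels use 50 rendered bouts (≈170-ms movies at
500 frames/s, 256² px) for end-to-end Δθ recovery, 50 kinematic bouts for
HF recovery, 100 noisy bouts for DI sign accuracy, n = 200 for regression
recovery, and 1000 randomized closed-loop trials for the timing
invariants — sizes at which the binomial margins on the pass rates are
comfortably resolved while the whole suite runs in a couple of minutes.

## Known limitations

- Binary-mask tracking has a ~1° tail-angle quantization floor at the
  default 0.033 mm/px scale; sub-degree work needs finer pixels.
- The column-wise ridge follower assumes the tail stays within ±90° of the
  body axis in the rotated frame; extreme bends (|γ| near 90°) can truncate
  the midline mid-bout (θ is unaffected; it comes from the head).
- The LF spectral peak of a windowed pulse is edge-dominated rather than a
  strict interior maximum; LF *amplitude* comparisons are meaningful, LF
  *frequency* localization is not.
- `extract_midline` requires frame-to-frame heading continuity; it is not
  a single-frame pose estimator for arbitrary orientations without a
  reasonable `prev_heading`.
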