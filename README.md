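# preycap

Quantitative analysis of larval zebrafish prey-capture behavior: automated
midline/eye/prey tracking from dark-field high-speed video, spectral
decomposition of swim bouts, sequence-level statistics, and a discrete-event
simulation of a closed-loop virtual-reality stimulus paradigm. A synthetic
video and tail-trace generator with exact ground truth makes every stage of
the pipeline testable without recorded data.

## Who this is for

Researchers quantifying goal-directed swimming in larval fish (or similar
intermittent locomotion): the package turns an 8-bit grayscale frame stack
into per-frame pose parameters `(d, φ, θ, γ₁…γ₅)` — fish–target distance
and angle, heading, and five tail-segment angles — and turns those into
per-bout kinematic and spectral metrics.

## The model at the core

A swim bout is treated as one **elementary motor pattern**: a symmetric
tail oscillation at ~20–35 Hz lasting ~3 cycles, with a slower, graded
**asymmetric turn component** superimposed. Spectrally, each tail-segment
waveform γᵢ(t) is windowed (150 ms freely swimming / 300 ms restrained),
Bessel band-pass filtered (0.5–100 Hz), and transformed:

    X_k = Σₙ xₙ e^(−i2πnk/N)            (DFT)
    A_k = X_k / N                        (two-sided complex spectrum)
    B_0 = A_0,  B_k = 2·A_k  (k=1…N/2−1) (single-sided RMS spectrum)
    B_mag = |B_k|

The five per-segment spectra are summed and spline-interpolated; the
low-frequency peak (~3–5 Hz) scales with the orientation change Δθ, the
high-frequency peak (~20–35 Hz) is the tail-beat frequency. The
**Direction Index** signs the low-frequency amplitude:

    DI = sign( ∫ dt (1/5) Σᵢ γᵢ(t) ) × (1/3) Σ_{k∈{3,4,5 Hz}} B_mag(k)

so target-directed and avoidance turns get opposite signs.

The tracking pipeline reconstructs the midline from the exact Euclidean
distance transform of the binarized silhouette (column-wise ridge
following) and fits six connected segments: one head segment (the body
axis, giving θ) and five equal-length tail segments (giving γ₁…γ₅,
positive toward the fish's right).

The virtual-reality module simulates the closed loop: a small moving target
sweeps the peripheral visual field; a tail-sensor threshold crossing
triggers (after an intrinsic latency) a fast translation of target and
background toward the center, with paradigms for held updates,
size/velocity escalation across a bout sequence, and delayed reappearance.
Update delay Δt and inter-bout interval IBI are measured from the end of
the first swim, reaction time RT from the onset of the second stimulus, so
Δt = IBI − RT.

## Worked example

Generate a synthetic 30° orienting bout, render it as a dark-field movie,
track it, and analyze the bout:

```python
import numpy as np
from preycap import (GeneratorParams, SceneParams, SpectrumConfig,
                     gen_bout_kinematics, render_frames,
                     preprocess_free, track_stack)
from preycap import boutspec
from preycap.synthgen import _background

params = GeneratorParams(delta_theta_true=30.0, f_osc=28.0, seed=42)
_, truth = gen_bout_kinematics(params, head_center_mm=(4.2, 4.2))

scene = SceneParams()
stack = render_frames(truth, scene)                    # (n, 256, 256) uint8
background = _background(scene).astype(np.uint8)
binary, valid = preprocess_free(stack, background)
poses = track_stack(binary, valid)

dtheta = poses[-1].theta_deg - poses[0].theta_deg
print(f"tracked heading change: {dtheta:+.1f} deg")

cfg = SpectrumConfig()
gamma = np.array([p.gamma_deg for p in poses])
t_ms = np.arange(len(poses)) * 1000.0 / params.fs
bout = boutspec.bout_metrics(t_ms, np.array([p.theta_deg for p in poses]),
                             gamma, (truth.onset_ms, truth.offset_ms), cfg)
print(f"HF peak: {bout.spectrum.hf_peak[0]:.1f} Hz")
print(f"Direction Index: {bout.di:+.1f} deg  ({bout.n_cycles} cycles)")
```

Output:

```
tracked heading change: +29.7 deg
HF peak: 27.2 Hz
Direction Index: +35.3 deg  (3 cycles)
```

The tracked heading change recovers the generator's 30° turn to within a
fraction of a degree; the high-frequency peak sits at the 28 Hz tail-beat
frequency (the 150 ms window limits frequency resolution to ~1 Hz after
interpolation); the positive DI marks a rightward, target-directed turn
whose magnitude scales with the turn angle.

A command-line interface mirrors the pipeline stages:

```bash
preycap simulate bout --seed 3 --out sim/
preycap track --mode free --video sim/frames.tif --out trk/
preycap spectra --poses trk/poses.csv --out spec/
preycap vr-run --paradigm delay --seed 2 --trials 10 --out vr/
```

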