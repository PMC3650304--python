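"""Synthetic generator for larval-zebrafish prey-capture data.

Produces ground-truth swim-bout kinematics, dark-field video renderings of a
larva plus a single prey particle, a 1 kHz tail-position-sensor voltage
trace, and chained multi-bout capture-like sequences.  Every record carries
its generating parameters so that downstream tracking and spectral analysis
can be validated against exact truth.

Model
-----
A swim bout is an elementary motor pattern: a symmetric tail oscillation at
``f_osc`` (~20-35 Hz) lasting ``n_cycles`` cycles, with a slower asymmetric
turn component superimposed.  The tail-segment angle of segment *i* is

    gamma_i(t) = turn_gains[i] * A_turn * P(t)
               + segment_gains[i] * A_osc * sin(2*pi*f_osc*(t-t0) + phi_i) * E(t)
               + noise

where ``P`` is a unimodal raised-cosine pulse of width ``turn_pulse_duration``
starting at bout onset, ``E`` a smooth on/off envelope over the bout, and
``phi_i`` a small rostro-caudal phase lag.  The heading ramps from theta0 to
theta0 + delta_theta_true following the normalized integral of ``P``, so the
net orientation change is exact ground truth (no hydrodynamics).

Sign convention: angles are measured in image coordinates (x right, y down,
``atan2(y, x)``), so positive angles point toward the fish's *right*;
``sign(mean tail-angle integral) == sign(delta_theta_true)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "GeneratorParams",
    "GroundTruth",
    "SceneParams",
    "gen_bout_kinematics",
    "render_frames",
    "gen_capture_sequence",
    "gen_psd_trace",
    "midline_points",
    "write_tiff",
    "write_truth_json",
    "write_trace_csv",
]

# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class GeneratorParams:
    """Parameters of one synthetic swim bout.

    Angles in degrees, times in ms, frequencies in Hz.  ``fs`` is the video
    frame rate (250 or 500 frames/s in the recordings this emulates).
    """

    delta_theta_true: float = 0.0        # signed net heading change, + = right
    f_osc: float = 28.0                  # tail-beat frequency
    n_cycles: int = 3
    bout_duration: float | None = None   # ms; default n_cycles / f_osc
    fs: float = 500.0
    turn_pulse_duration: float | None = None  # ms; default one beat cycle
    osc_amp: float = 20.0                # A_osc, caudal-most oscillation amplitude
    turn_amp: float | None = None        # A_turn; default = delta_theta_true
    segment_gains: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0)
    turn_gains: tuple[float, ...] = (0.30, 0.50, 0.70, 0.85, 1.0)
    phase_lag: float = 0.25              # rad per segment, rostro-caudal
    attack_ms: float = 5.0               # envelope rise
    release_ms: float = 5.0              # envelope fall
    noise_sd: float = 0.0                # deg, per-sample Gaussian on gamma
    theta0: float = 0.0                  # initial heading, deg
    pre_ms: float = 20.0                 # quiescence before bout onset
    post_ms: float = 20.0                # quiescence after bout offset
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bout_duration is None:
            self.bout_duration = 1000.0 * self.n_cycles / self.f_osc
        if self.turn_pulse_duration is None:
            # 1.5 beat cycles: the turn develops within the first half of the
            # bout but its Hann-pulse spectrum stays below the tail-beat band
            self.turn_pulse_duration = min(1500.0 / self.f_osc,
                                           self.bout_duration)
        self.validate()

    def validate(self) -> None:
        if self.fs <= 2.0 * self.f_osc:
            raise ValueError(
                f"Nyquist violation: fs={self.fs} must exceed 2*f_osc={2 * self.f_osc}"
            )
        if self.bout_duration <= 0 or self.turn_pulse_duration <= 0:
            raise ValueError("durations must be positive")
        min_dur = 1000.0 * self.n_cycles / self.f_osc
        if self.bout_duration < min_dur - 1e-9:
            raise ValueError(
                f"bout_duration={self.bout_duration} ms too short for "
                f"{self.n_cycles} cycles at {self.f_osc} Hz (needs >= {min_dur:.1f} ms)"
            )
        if self.turn_pulse_duration > self.bout_duration + 1e-9:
            raise ValueError("turn_pulse_duration must not exceed bout_duration")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name, g in (("segment_gains", self.segment_gains),
                        ("turn_gains", self.turn_gains)):
            if len(g) != 5:
                raise ValueError(f"{name} must have 5 entries")
            if np.any(np.diff(g) < 0):
                raise ValueError(f"{name} must be non-decreasing rostro-caudally")


@dataclass
class SceneParams:
    """Rendering geometry and photometry for synthetic dark-field frames."""

    image_size: tuple[int, int] = (256, 256)   # (height, width) px
    pixel_size: float = 0.033                  # mm / px
    body_length: float = 4.0                   # mm
    head_width: float = 0.5                    # mm
    head_fraction: float = 0.30                # head-segment share of body length
    tail_taper: float = 0.88                   # fractional width loss snout->tip
    fish_intensity: int = 200
    background_intensity: int = 20
    texture_amplitude: float = 6.0             # static low-spatial-freq background
    pixel_noise_sd: float = 0.0                # per-frame Gaussian pixel noise
    prey_length: float = 0.18                  # mm, major axis of the particle
    prey_intensity: int = 150
    mode: str = "free"                         # "free" | "restrained"
    eye_length: float = 0.30                   # mm (restrained mode)
    eye_width: float = 0.13                    # mm
    eye_offset: float = 0.11                   # mm, lateral from the body axis
    eye_intensity: int = 40                    # darker than the head
    texture_seed: int = 1234

    def __post_init__(self) -> None:
        if self.fish_intensity <= self.background_intensity:
            raise ValueError("dark-field contrast requires fish brighter than background")
        if self.body_length / self.pixel_size < 60:
            raise ValueError("body length must be >= 60 px for the midline to resolve")
        if self.mode not in ("free", "restrained"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class GroundTruth:
    """Exact per-frame truth for one bout or a chained sequence.

    All arrays share the time base ``t_ms``.  ``theta_deg[k]`` is the heading
    and ``gamma_deg[k, i]`` the angle of tail segment ``i+1`` at frame ``k``.
    ``head_center_mm`` is the center of the head segment in arena (mm)
    coordinates, x right / y down.
    """

    params: GeneratorParams | list[GeneratorParams]
    t_ms: np.ndarray
    theta_deg: np.ndarray
    gamma_deg: np.ndarray                      # (n_frames, 5)
    onset_ms: float | np.ndarray
    offset_ms: float | np.ndarray
    head_center_mm: np.ndarray                 # (n_frames, 2)
    prey_mm: np.ndarray | None = None          # (n_frames, 2)
    eye_deg: np.ndarray | None = None          # (n_frames, 2) = (left, right), nasal+
    seed: int = 0
    phi_pre_deg: np.ndarray | None = None      # per bout (sequences)
    phi_post_deg: np.ndarray | None = None
    ibi_ms: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return len(self.t_ms)


# ---------------------------------------------------------------------------
# bout kinematics
# ---------------------------------------------------------------------------

def _centered_phases(lag: float, gains: tuple[float, ...]) -> np.ndarray:
    """Rostro-caudal phase offsets ``lag * (i - c)`` with the pivot ``c``
    chosen so the gain-weighted oscillation has no net quadrature component
    (``sum_i gains[i] * sin(phi_i) = 0``): the across-segment mean of a pure
    oscillation then integrates to zero over whole cycles, which keeps the
    symmetric motor component truly direction-neutral."""
    idx = np.arange(5, dtype=float)
    if lag == 0.0:
        return np.zeros(5)
    from scipy.optimize import brentq

    g = np.asarray(gains, dtype=float)
    c = brentq(lambda cc: float(g @ np.sin(lag * (idx - cc))), 0.0, 4.0)
    return lag * (idx - c)


def _raised_cosine_pulse(t_ms: np.ndarray, start: float, width: float) -> np.ndarray:
    """Unimodal raised-cosine pulse on [start, start+width], peak 1."""
    u = (t_ms - start) / width
    p = 0.5 * (1.0 - np.cos(2.0 * np.pi * u))
    p[(u < 0) | (u > 1)] = 0.0
    return p


def _envelope(t_ms: np.ndarray, onset: float, offset: float,
              attack: float, release: float) -> np.ndarray:
    """Smooth on/off envelope: cosine ramps of `attack`/`release`, flat top."""
    e = np.zeros_like(t_ms)
    inside = (t_ms >= onset) & (t_ms <= offset)
    e[inside] = 1.0
    rise = inside & (t_ms < onset + attack)
    e[rise] = 0.5 * (1 - np.cos(np.pi * (t_ms[rise] - onset) / attack))
    fall = inside & (t_ms > offset - release)
    e[fall] = np.minimum(
        e[fall], 0.5 * (1 - np.cos(np.pi * (offset - t_ms[fall]) / release))
    )
    return e


def gen_bout_kinematics(
    params: GeneratorParams,
    head_center_mm: tuple[float, float] | None = None,
    prey_mm: tuple[float, float] | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Generate the tail-angle traces gamma_1..5(t) and exact truth for one bout.

    Returns ``(gamma, truth)`` where ``gamma`` has shape ``(n_frames, 5)`` in
    degrees.  The fish turns in place (no translation); the heading follows
    the normalized integral of the turn pulse, so
    ``theta(offset) - theta(onset) == delta_theta_true`` exactly.
    """
    p = params
    p.validate()
    rng = np.random.default_rng(p.seed)

    total_ms = p.pre_ms + p.bout_duration + p.post_ms
    n = int(round(total_ms * p.fs / 1000.0)) + 1
    t_ms = np.arange(n) * 1000.0 / p.fs
    onset = p.pre_ms
    offset = p.pre_ms + p.bout_duration

    pulse = _raised_cosine_pulse(t_ms, onset, p.turn_pulse_duration)
    env = _envelope(t_ms, onset, offset, p.attack_ms, p.release_ms)

    a_turn = p.delta_theta_true if p.turn_amp is None else p.turn_amp
    tt = (t_ms - onset) / 1000.0  # s from onset
    phases = _centered_phases(p.phase_lag, p.segment_gains)
    gamma = np.empty((n, 5))
    for i in range(5):
        osc = np.sin(2 * np.pi * p.f_osc * tt + phases[i])
        gamma[:, i] = (
            p.turn_gains[i] * a_turn * pulse
            + p.segment_gains[i] * p.osc_amp * osc * env
        )
    if p.noise_sd > 0:
        gamma += rng.normal(0.0, p.noise_sd, size=gamma.shape)

    # heading: closed-form integral of the raised-cosine pulse, normalized to 1
    # int_0^u (1 - cos(2 pi v)) dv / 1 = u - sin(2 pi u)/(2 pi)
    u = np.clip((t_ms - onset) / p.turn_pulse_duration, 0.0, 1.0)
    ramp = u - np.sin(2 * np.pi * u) / (2 * np.pi)
    theta = p.theta0 + p.delta_theta_true * ramp
    theta[t_ms >= onset + p.turn_pulse_duration] = p.theta0 + p.delta_theta_true

    hc = np.tile(np.asarray(head_center_mm if head_center_mm is not None
                            else (0.0, 0.0), dtype=float), (n, 1))
    prey = None
    if prey_mm is not None:
        prey = np.tile(np.asarray(prey_mm, dtype=float), (n, 1))

    truth = GroundTruth(
        params=p, t_ms=t_ms, theta_deg=theta, gamma_deg=gamma,
        onset_ms=onset, offset_ms=offset, head_center_mm=hc,
        prey_mm=prey, seed=p.seed,
    )
    return gamma, truth


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def midline_points(
    head_center_px: np.ndarray,
    theta_deg: float,
    gamma_deg: np.ndarray,
    scene: SceneParams,
    spacing_px: float = 1.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the 6-segment midline as (x, y) pixel points with body radii.

    The head segment (length ``head_fraction * body_length``) points along
    the heading; five equal tail segments extend backward at absolute angles
    ``theta + 180 + gamma_i``.  Returns ``(points, radii)`` where points is
    (m, 2) in pixel (x=col, y=row) coordinates.
    """
    bl_px = scene.body_length / scene.pixel_size
    lh = scene.head_fraction * bl_px
    ls = (1.0 - scene.head_fraction) * bl_px / 5.0
    th = np.deg2rad(theta_deg)
    u = np.array([np.cos(th), np.sin(th)])
    snout = head_center_px + 0.5 * lh * u
    neck = head_center_px - 0.5 * lh * u

    # polyline vertices snout -> neck -> tail joints
    verts = [snout, neck]
    pt = neck
    for g in gamma_deg:
        a = np.deg2rad(theta_deg + 180.0 + g)
        pt = pt + ls * np.array([np.cos(a), np.sin(a)])
        verts.append(pt)
    verts = np.asarray(verts)

    # densify with arclength parameter s measured from the snout
    pts, ss = [], []
    s0 = 0.0
    for a, b in zip(verts[:-1], verts[1:]):
        seg = b - a
        length = float(np.hypot(*seg))
        m = max(2, int(np.ceil(length / spacing_px)) + 1)
        f = np.linspace(0.0, 1.0, m)
        pts.append(a[None, :] + f[:, None] * seg[None, :])
        ss.append(s0 + f * length)
        s0 += length
    pts = np.concatenate(pts)
    ss = np.concatenate(ss)

    # radius profile: elliptical head cap, linearly tapering tail
    rh = 0.5 * scene.head_width / scene.pixel_size
    r_tail0 = 0.55 * rh
    r_tip = max(1.2, (1.0 - scene.tail_taper) * r_tail0)
    radii = np.empty_like(ss)
    head = ss <= lh
    with np.errstate(invalid="ignore"):
        radii[head] = rh * np.sqrt(np.clip(1.0 - ((ss[head] - 0.5 * lh) / (0.55 * lh)) ** 2, 0.0, 1.0))
    radii[head] = np.maximum(radii[head], 1.0)
    tail = ~head
    f = (ss[tail] - lh) / (s0 - lh)
    radii[tail] = r_tail0 + (r_tip - r_tail0) * f
    return pts, radii


def _paint_blob(canvas: np.ndarray, pts: np.ndarray, radii: np.ndarray,
                value: float) -> None:
    """Anti-aliased silhouette: alpha from the signed distance to the union
    of disks along the midline, so a mid-level threshold recovers the body
    outline with sub-pixel fidelity."""
    h, w = canvas.shape
    rmax = float(radii.max())
    x0 = max(0, int(np.floor(pts[:, 0].min() - rmax - 2)))
    x1 = min(w, int(np.ceil(pts[:, 0].max() + rmax + 3)))
    y0 = max(0, int(np.floor(pts[:, 1].min() - rmax - 2)))
    y1 = min(h, int(np.ceil(pts[:, 1].max() + rmax + 3)))
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    field = np.full(yy.shape, -np.inf)
    for (px, py), r in zip(pts, radii):
        d = np.hypot(xx - px, yy - py)
        np.maximum(field, max(r, 1.0) - d, out=field)
    alpha = np.clip(field + 0.5, 0.0, 1.0)
    sub = canvas[y0:y1, x0:x1]
    canvas[y0:y1, x0:x1] = sub * (1.0 - alpha) + value * alpha


def _draw_filled_ellipse(canvas: np.ndarray, center_xy: np.ndarray,
                         a_px: float, b_px: float, angle_deg: float,
                         value: float) -> None:
    """Rasterize a rotated filled ellipse (a = semi-major along angle)."""
    h, w = canvas.shape
    cx, cy = center_xy
    r = int(np.ceil(max(a_px, b_px))) + 2
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    th = np.deg2rad(angle_deg)
    dx, dy = xx - cx, yy - cy
    xr = dx * np.cos(th) + dy * np.sin(th)
    yr = -dx * np.sin(th) + dy * np.cos(th)
    mask = (xr / a_px) ** 2 + (yr / b_px) ** 2 <= 1.0
    canvas[y0:y1, x0:x1][mask] = value


def _background(scene: SceneParams) -> np.ndarray:
    """Static low-spatial-frequency background texture (seeded once)."""
    from scipy.ndimage import gaussian_filter

    h, w = scene.image_size
    rng = np.random.default_rng(scene.texture_seed)
    tex = gaussian_filter(rng.normal(size=(h, w)), sigma=18)
    if tex.std() > 0:
        tex = tex / tex.std()
    return np.clip(scene.background_intensity + scene.texture_amplitude * tex,
                   0, 255)


def render_frames(truth: GroundTruth, scene: SceneParams,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Rasterize a GroundTruth record into an 8-bit grayscale frame stack.

    Free mode: bright tapered larva silhouette plus a small bright prey
    ellipse on a textured dark background.  Restrained mode: head position
    fixed, two dark eye ellipses drawn inside the bright head at the angles
    scheduled in ``truth.eye_deg``.

    Frames whose prey overlaps the fish silhouette are flagged via the
    returned array's companion attribute-free contract: overlap is permitted
    (the prey simply disappears into the silhouette), matching what a real
    occlusion does to the tracker.
    """
    h, w = scene.image_size
    n = truth.n_frames
    if rng is None:
        rng = np.random.default_rng(truth.seed + 7777)
    bg = _background(scene)
    stack = np.empty((n, h, w), dtype=np.uint8)

    for k in range(n):
        frame = bg.copy()
        hc_px = truth.head_center_mm[k] / scene.pixel_size
        if not (0 <= hc_px[0] < w and 0 <= hc_px[1] < h):
            raise ValueError(f"fish out of frame bounds at frame {k}")
        pts, radii = midline_points(hc_px, float(truth.theta_deg[k]),
                                    truth.gamma_deg[k], scene)
        _paint_blob(frame, pts, radii, scene.fish_intensity)

        if scene.mode == "restrained" and truth.eye_deg is not None:
            th = float(truth.theta_deg[k])
            u = np.array([np.cos(np.deg2rad(th)), np.sin(np.deg2rad(th))])
            nvec = np.array([-u[1], u[0]])          # fish's right side (+)
            off = scene.eye_offset / scene.pixel_size
            fwd = 0.05 * scene.body_length / scene.pixel_size
            a = 0.5 * scene.eye_length / scene.pixel_size
            b = 0.5 * scene.eye_width / scene.pixel_size
            eye_l, eye_r = truth.eye_deg[k]
            # nasal-positive: left eye major axis at theta + e, right at theta - e
            _draw_filled_ellipse(frame, hc_px + fwd * u - off * nvec,
                                 a, b, th + eye_l, scene.eye_intensity)
            _draw_filled_ellipse(frame, hc_px + fwd * u + off * nvec,
                                 a, b, th - eye_r, scene.eye_intensity)

        if truth.prey_mm is not None and scene.mode == "free":
            pr_px = truth.prey_mm[k] / scene.pixel_size
            a = 0.5 * scene.prey_length / scene.pixel_size
            _draw_filled_ellipse(frame, pr_px, max(a, 1.5), max(0.5 * a, 1.0),
                                 0.0, scene.prey_intensity)

        if scene.pixel_noise_sd > 0:
            frame = frame + rng.normal(0.0, scene.pixel_noise_sd, frame.shape)
        stack[k] = np.clip(frame, 0, 255).astype(np.uint8)
    return stack


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def gen_capture_sequence(
    n_bouts: int,
    ibi_schedule: list[float],
    undershoot_factor: float = 0.9,
    prey_mm: tuple[float, float] = (6.5, 2.5),
    eye_levels: dict | None = None,
    seed: int = 0,
    fs: float = 500.0,
    theta0: float = 0.0,
    head_center_mm: tuple[float, float] = (4.0, 4.0),
    advance_mm: float = 0.0,
    noise_sd: float = 0.0,
    lead_ms: float = 100.0,
    tail_ms: float = 100.0,
    bout_kwargs: dict | None = None,
) -> GroundTruth:
    """Chain bouts into a prey-capture-like sequence with exact truth.

    Each bout turns by ``undershoot_factor * phi_pre`` where ``phi_pre`` is
    the signed fish-target angle from the current simulated geometry, so
    with a stationary prey and no forward advance ``phi_post = (1 -
    undershoot_factor) * phi_pre`` per bout exactly.  Bouts are separated by
    ``ibi_schedule`` (len >= n_bouts - 1).  The eye-angle course implements
    the two-step convergence pattern: the contralateral eye jumps to a
    near-maximal level at the end of bout 1, both eyes reach the maximal
    level by bout 2.

    Returns a GroundTruth covering the whole sequence (render with
    :func:`render_frames`).
    """
    if n_bouts < 1:
        raise ValueError("n_bouts must be >= 1")
    if len(ibi_schedule) < n_bouts - 1:
        raise ValueError("ibi_schedule shorter than n_bouts - 1")
    eye_levels = eye_levels or {
        "ipsi": (15.4, 20.0, 32.5),     # before 1st / after 1st / after 2nd+
        "contra": (13.1, 28.0, 30.6),
    }
    bout_kwargs = dict(bout_kwargs or {})
    rng = np.random.default_rng(seed)
    dt = 1000.0 / fs
    # snap the bout duration to the frame grid so scheduled IBIs (multiples
    # of the frame period) are realized exactly
    if "bout_duration" not in bout_kwargs:
        n_cyc = bout_kwargs.get("n_cycles", 3)
        f_osc = bout_kwargs.get("f_osc", 28.0)
        bout_kwargs["bout_duration"] = np.ceil(
            1000.0 * n_cyc / f_osc / dt) * dt

    t_list, th_list, ga_list, hc_list = [], [], [], []
    onsets, offsets, phi_pre_l, phi_post_l = [], [], [], []
    params_list = []
    theta = float(theta0)
    hc = np.array(head_center_mm, dtype=float)
    prey = np.array(prey_mm, dtype=float)

    # quiet lead-in before the first bout
    m0 = max(1, int(round(lead_ms / dt)))
    t_list.append(np.arange(m0 + 1) * dt)
    th_list.append(np.full(m0 + 1, theta))
    g0 = np.zeros((m0 + 1, 5))
    if noise_sd > 0:
        g0 += rng.normal(0, noise_sd, g0.shape)
    ga_list.append(g0)
    hc_list.append(np.tile(hc, (m0 + 1, 1)))
    t_cursor = t_list[-1][-1]

    def phi_of() -> float:
        v = prey - hc
        u = np.array([np.cos(np.deg2rad(theta)), np.sin(np.deg2rad(theta))])
        return float(np.degrees(np.arctan2(u[0] * v[1] - u[1] * v[0],
                                           u[0] * v[0] + u[1] * v[1])))

    for b in range(n_bouts):
        phi_pre = phi_of()
        dtheta = undershoot_factor * phi_pre
        params = GeneratorParams(
            delta_theta_true=dtheta, fs=fs, theta0=theta,
            noise_sd=noise_sd, seed=int(rng.integers(0, 2**31 - 1)),
            pre_ms=0.0, post_ms=0.0, **bout_kwargs,
        )
        gamma, bt = gen_bout_kinematics(params, head_center_mm=tuple(hc))
        # drop the duplicated first sample when concatenating
        t_list.append(bt.t_ms[1:] + t_cursor)
        th_list.append(bt.theta_deg[1:])
        ga_list.append(bt.gamma_deg[1:])
        hc_list.append(bt.head_center_mm[1:])
        onsets.append(t_cursor + bt.onset_ms)
        offsets.append(t_cursor + bt.offset_ms)
        params_list.append(params)
        t_cursor = t_list[-1][-1]
        theta += dtheta
        if advance_mm:
            u = np.array([np.cos(np.deg2rad(theta)), np.sin(np.deg2rad(theta))])
            hc = hc + advance_mm * u
            hc_list[-1][-1] = hc
        phi_pre_l.append(phi_pre)
        phi_post_l.append(phi_of())

        if b < n_bouts - 1:
            gap = float(ibi_schedule[b])
            m = int(round(gap / dt))
            tg = t_cursor + np.arange(1, m + 1) * dt
            t_list.append(tg)
            th_list.append(np.full(m, theta))
            gg = np.zeros((m, 5))
            if noise_sd > 0:
                gg += rng.normal(0, noise_sd, gg.shape)
            ga_list.append(gg)
            hc_list.append(np.tile(hc, (m, 1)))
            t_cursor = tg[-1]

    # quiet tail after the last bout
    m1 = max(1, int(round(tail_ms / dt)))
    tg = t_cursor + np.arange(1, m1 + 1) * dt
    t_list.append(tg)
    th_list.append(np.full(m1, theta))
    g1 = np.zeros((m1, 5))
    if noise_sd > 0:
        g1 += rng.normal(0, noise_sd, g1.shape)
    ga_list.append(g1)
    hc_list.append(np.tile(hc, (m1, 1)))

    t_ms = np.concatenate(t_list)
    n = len(t_ms)
    onsets = np.array(onsets)
    offsets = np.array(offsets)

    # eye schedule: step at each bout offset (smoothly irrelevant for tests)
    ipsi_lv, contra_lv = eye_levels["ipsi"], eye_levels["contra"]
    prey_side = np.sign(phi_pre_l[0]) or 1.0   # + = prey on fish's right
    ipsi = np.full(n, ipsi_lv[0])
    contra = np.full(n, contra_lv[0])
    for b in range(min(n_bouts, 2)):
        after = t_ms >= offsets[b]
        ipsi[after] = ipsi_lv[min(b + 1, len(ipsi_lv) - 1)]
        contra[after] = contra_lv[min(b + 1, len(contra_lv) - 1)]
    # left eye is ipsilateral when prey is on the left (phi_pre < 0)
    if prey_side < 0:
        eye = np.stack([ipsi, contra], axis=1)   # (left, right)
    else:
        eye = np.stack([contra, ipsi], axis=1)

    truth = GroundTruth(
        params=params_list, t_ms=t_ms,
        theta_deg=np.concatenate(th_list),
        gamma_deg=np.concatenate(ga_list),
        onset_ms=onsets, offset_ms=offsets,
        head_center_mm=np.concatenate(hc_list),
        prey_mm=np.tile(prey, (n, 1)),
        eye_deg=eye, seed=seed,
        phi_pre_deg=np.array(phi_pre_l),
        phi_post_deg=np.array(phi_post_l),
        ibi_ms=onsets[1:] - offsets[:-1],
    )
    return truth


# ---------------------------------------------------------------------------
# tail position sensor
# ---------------------------------------------------------------------------

def gen_psd_trace(
    truth: GroundTruth,
    gain: float = 1.0,
    noise_sd: float = 0.0,
    fs_out: float = 1000.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize the 1 kHz position-sensor voltage from tail-tip displacement.

    The sensor sees the lateral displacement of the tail tip relative to the
    body axis (sum of segment-length * sin(gamma_i) contributions), resampled
    to ``fs_out`` and scaled by ``gain``, plus Gaussian noise.  Returns
    ``(t_ms, voltage)``.
    """
    params = truth.params[0] if isinstance(truth.params, list) else truth.params
    f_osc = params.f_osc
    if fs_out < 2.0 * f_osc:
        raise ValueError("fs_out below Nyquist for the oscillation")
    # lateral tip displacement in units of tail-segment length
    disp = np.sin(np.deg2rad(truth.gamma_deg)).sum(axis=1)
    t_out = np.arange(0.0, truth.t_ms[-1] + 1e-9, 1000.0 / fs_out)
    v = gain * np.interp(t_out, truth.t_ms, disp)
    if noise_sd > 0:
        rng = np.random.default_rng(truth.seed + 31 if seed is None else seed)
        v = v + rng.normal(0.0, noise_sd, v.shape)
    return t_out, v


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_tiff(path: str | Path, stack: np.ndarray) -> None:
    """Write a frame stack as 8-bit multi-page TIFF."""
    tifffile.imwrite(str(path), stack.astype(np.uint8),
                     photometric="minisblack")


def write_truth_json(path: str | Path, truth: GroundTruth) -> None:
    """Write a GroundTruth record as a JSON sidecar."""
    def conv(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, GeneratorParams):
            return dataclasses.asdict(v)
        if isinstance(v, list):
            return [conv(x) for x in v]
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        return v

    d = {f.name: conv(getattr(truth, f.name)) for f in dataclasses.fields(truth)}
    Path(path).write_text(json.dumps(d))


def write_trace_csv(path: str | Path, t_ms: np.ndarray, v: np.ndarray) -> None:
    """Write a sensor trace as CSV with columns time_ms, voltage."""
    import pandas as pd

    pd.DataFrame({"time_ms": t_ms, "voltage": v}).to_csv(path, index=False)
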