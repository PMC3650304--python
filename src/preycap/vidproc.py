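"""Image pipeline: grayscale frame stacks -> per-frame pose and prey geometry.

Implements the dark-field tracking chain for both freely swimming and
partially restrained larvae: background subtraction / histogram remapping,
thresholding and morphological cleanup, Euclidean-distance-map midline
reconstruction with a six-segment fit (one head segment plus five
equal-length tail segments), prey-particle tracking, fish-target geometry
(phi, d, angular size/velocity), and moment-based eye-ellipse fitting.

Coordinates are image coordinates: origin top-left, x = column (right),
y = row (down), 0-based.  Angles use ``atan2(y, x)`` in this frame, which
makes positive angles point toward the fish's right.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology, segmentation, transform

__all__ = [
    "MidlinePose",
    "EyePose",
    "PreyObservation",
    "NoObjectError",
    "TrackLostError",
    "preprocess_free",
    "preprocess_restrained",
    "extract_midline",
    "initial_heading",
    "track_prey",
    "prey_geometry",
    "prey_geometry_series",
    "fit_eyes",
    "track_stack",
    "poses_to_dataframe",
]


class NoObjectError(ValueError):
    """Raised when a frame contains no usable foreground object."""


class TrackLostError(RuntimeError):
    """Raised when the prey track cannot be continued."""

    def __init__(self, frame: int):
        super().__init__(f"prey track lost at frame {frame}")
        self.frame = frame


@dataclass
class MidlinePose:
    """Per-frame fish pose: heading plus five tail-segment angles.

    ``theta_deg`` is the angle of the head segment in the global image frame;
    ``gamma_deg[i]`` the signed deviation of tail segment i+1 from the body
    axis (positive toward the fish's right).  ``vertices`` holds the 7 points
    of the 6-segment midline polyline from snout to tail tip, (x, y) pixels.
    """

    frame_index: int
    theta_deg: float
    gamma_deg: np.ndarray
    head_center: np.ndarray
    snout: np.ndarray
    vertices: np.ndarray
    valid: bool = True

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.hypot(*np.diff(self.vertices, axis=0).T)


@dataclass
class EyePose:
    frame_index: int
    left_deg: float = np.nan      # nasal-positive angle vs body axis
    right_deg: float = np.nan
    centers: np.ndarray | None = None     # (2, 2) (x, y), left then right
    axes: np.ndarray | None = None        # (2, 2) (major, minor) px
    missing: bool = False


@dataclass
class PreyObservation:
    frame_index: int
    centroid: np.ndarray            # (x, y) px
    phi_deg: float                  # signed fish-target angle, right positive
    d_mm: float
    angular_size_deg: float
    angular_velocity_deg_s: float = np.nan


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _clean_binary(binary: np.ndarray, min_area: int, fill_holes: bool) -> np.ndarray:
    """Border rejection, small-object removal, hole filling, largest kept."""
    binary = segmentation.clear_border(binary)
    binary = morphology.remove_small_objects(binary, max_size=min_area - 1)
    if fill_holes:
        binary = ndi.binary_fill_holes(binary)
    lab, n = ndi.label(binary)
    if n > 1:
        sizes = ndi.sum_labels(binary, lab, index=np.arange(1, n + 1))
        binary = lab == (1 + int(np.argmax(sizes)))
    return binary


def preprocess_free(
    stack: np.ndarray,
    background_frame: np.ndarray,
    threshold: float | None = None,
    min_area: int = 30,
    fill_holes: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Background-subtract, equalize, threshold, and clean each frame.

    Returns ``(binary_stack, valid)`` where ``valid[k]`` is False for frames
    with no foreground left after filtering (e.g. a frame identical to the
    background).  Histogram equalization is a monotone intensity scaling, so
    the binarization is carried out equivalently in background-subtracted
    units: ``threshold`` applies to the difference image (0-255); None
    selects Otsu's threshold per frame.
    """
    from skimage.filters import threshold_otsu

    stack = np.atleast_3d(stack if stack.ndim == 3 else stack[None])
    if background_frame.shape != stack.shape[1:]:
        raise ValueError("background frame shape mismatch")
    out = np.zeros(stack.shape, dtype=bool)
    valid = np.zeros(len(stack), dtype=bool)
    bg = background_frame.astype(np.int16)
    for k, frame in enumerate(stack):
        diff = np.clip(frame.astype(np.int16) - bg, 0, 255).astype(np.uint8)
        if diff.max() < 8:           # nothing above background
            continue
        thr = threshold if threshold is not None else threshold_otsu(diff)
        binary = _clean_binary(diff > thr, min_area, fill_holes)
        if binary.any():
            out[k] = binary
            valid[k] = True
    return out, valid


def preprocess_restrained(
    stack: np.ndarray,
    remap_factor: float = 2.0,
    fixed_threshold: float = 100.0,
    min_area: int = 30,
    fill_holes: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear histogram remap plus fixed threshold (no background frame).

    Pixel values are remapped as ``(v - v_low) * remap_factor`` with ``v_low``
    the per-frame median (the background level), which suppresses background
    and stretches fish pixels while preserving pixel ordering.
    """
    if remap_factor <= 1:
        raise ValueError("remap_factor must exceed 1")
    stack = np.atleast_3d(stack if stack.ndim == 3 else stack[None])
    out = np.zeros(stack.shape, dtype=bool)
    valid = np.zeros(len(stack), dtype=bool)
    for k, frame in enumerate(stack):
        lo = np.median(frame)
        remapped = np.clip((frame.astype(float) - lo) * remap_factor, 0, 255)
        binary = _clean_binary(remapped > fixed_threshold, min_area, fill_holes)
        if binary.any():
            out[k] = binary
            valid[k] = True
    return out, valid


# ---------------------------------------------------------------------------
# midline extraction
# ---------------------------------------------------------------------------

def _rotation_ingredients(shape: tuple[int, int], angle_deg: float):
    """Warp transform aligning a direction ``angle_deg`` with +x.

    Returns ``(tf_matrix, out_shape, to_original)`` where ``to_original``
    maps (x, y) points in the rotated canvas back to the input frame.
    """
    h, w = shape
    d = int(np.ceil(np.hypot(h, w))) + 2
    a = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    c_in = np.array([w / 2.0, h / 2.0])
    c_out = np.array([d / 2.0, d / 2.0])
    t = c_in - rot @ c_out
    m = np.eye(3)
    m[:2, :2] = rot
    m[:2, 2] = t

    def to_original(pts: np.ndarray) -> np.ndarray:
        return (rot @ (np.atleast_2d(pts) - c_out).T).T + c_in

    return m, (d, d), to_original


def _follow_ridge(dist: np.ndarray, window: int = 6) -> np.ndarray:
    """Column-wise ridge following on a distance map.

    Starting from the global maximum, the maximal-distance pixel of each
    column is located iteratively toward both ends, constrained to stay
    within ``window`` rows of the previous column's ridge point (ties go to
    the row nearest the previous one).  Rows are refined to sub-pixel by a
    parabolic fit.  Returns (m, 2) ridge points (x, y) ordered by x.
    """
    h, w = dist.shape
    r0, c0 = np.unravel_index(int(np.argmax(dist)), dist.shape)

    def refine(col: int, row: int) -> float:
        if 0 < row < h - 1:
            y0, y1, y2 = dist[row - 1, col], dist[row, col], dist[row + 1, col]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                return row + 0.5 * (y0 - y2) / denom
        return float(row)

    def march(direction: int) -> list[tuple[float, float]]:
        pts = []
        prev = float(r0)
        col = c0 + direction
        while 0 <= col < w:
            lo = max(0, int(round(prev)) - window)
            hi = min(h, int(round(prev)) + window + 1)
            seg = dist[lo:hi, col]
            if seg.max() <= 0:
                break
            peak = seg.max()
            cand = np.flatnonzero(seg == peak) + lo
            row = int(cand[np.argmin(np.abs(cand - prev))])
            prev_f = refine(col, row)
            pts.append((float(col), prev_f))
            prev = prev_f
            col += direction
        return pts

    left = march(-1)[::-1]
    mid = [(float(c0), refine(c0, r0))]
    right = march(+1)
    return np.array(left + mid + right)


def _wrap180(a):
    return (np.asarray(a) + 180.0) % 360.0 - 180.0


def initial_heading(binary: np.ndarray) -> float:
    """Heading estimate for the first frame: silhouette principal axis,
    disambiguated by putting the fatter (head) end forward."""
    if not binary.any():
        raise NoObjectError("no object")
    ys, xs = np.nonzero(binary)
    cx, cy = xs.mean(), ys.mean()
    dx, dy = xs - cx, ys - cy
    cov = np.array([[np.mean(dx * dx), np.mean(dx * dy)],
                    [np.mean(dx * dy), np.mean(dy * dy)]])
    evals, evecs = np.linalg.eigh(cov)
    u = evecs[:, int(np.argmax(evals))]         # (x, y) major axis
    dist = ndi.distance_transform_edt(binary)
    side = (dx * u[0] + dy * u[1]) > 0
    w_pos = dist[ys[side], xs[side]].sum()
    w_neg = dist[ys[~side], xs[~side]].sum()
    if w_neg > w_pos:
        u = -u
    return float(np.degrees(np.arctan2(u[1], u[0])))


def extract_midline(
    binary: np.ndarray,
    prev_heading: float,
    head_fraction: float = 0.30,
    frame_index: int = 0,
    min_area: int = 30,
) -> MidlinePose:
    """Fit the six-segment midline to a single binary frame.

    The frame is rotated so ``prev_heading`` aligns with +x, the exact
    Euclidean distance transform is computed, and the midline ridge is
    followed column-wise from the distance maximum toward snout and tail.
    The head segment spans ``head_fraction`` of the midline arclength from
    the snout; the remainder is split into five equal-arclength segments.
    ``theta_deg`` is reported in the global (unrotated) frame.
    """
    if binary.sum() < min_area:
        raise NoObjectError("no object")
    ys, xs = np.nonzero(binary)
    pad = 4
    y0, x0 = max(0, ys.min() - pad), max(0, xs.min() - pad)
    sub = binary[y0:ys.max() + pad + 1, x0:xs.max() + pad + 1]
    m, out_shape, to_orig_sub = _rotation_ingredients(sub.shape, prev_heading)
    offset = np.array([x0, y0], dtype=float)

    def to_orig(pts: np.ndarray) -> np.ndarray:
        return to_orig_sub(pts) + offset

    tf = transform.AffineTransform(matrix=m)
    rot = transform.warp(sub.astype(float), inverse_map=tf,
                         output_shape=out_shape, order=1) > 0.5
    if not rot.any():
        raise NoObjectError("no object after rotation")
    dist = ndi.distance_transform_edt(rot)
    ridge = _follow_ridge(dist)
    if len(ridge) < 12:
        raise NoObjectError("midline too short")

    # snout is the +x end (heading was aligned with +x)
    ridge = ridge[np.argsort(ridge[:, 0])][::-1]     # snout -> tail order
    # sub-pixel ridge rows are noisy at +/-0.5 px; a short moving average
    # suppresses the quantization without flattening real bends
    ridge[:, 1] = ndi.uniform_filter1d(ridge[:, 1], size=5, mode="nearest")
    seglen = np.hypot(*np.diff(ridge, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seglen)])
    total = s[-1]

    # interpolate nodes at equal-arclength targets
    targets = np.concatenate([
        [0.0, head_fraction * total],
        head_fraction * total + (1 - head_fraction) * total * np.arange(1, 6) / 5.0,
    ])
    nodes = np.column_stack([np.interp(targets, s, ridge[:, 0]),
                             np.interp(targets, s, ridge[:, 1])])

    # head segment direction by least squares over the head ridge points
    head_pts = ridge[s <= targets[1]]
    if len(head_pts) >= 3:
        coef = np.polyfit(head_pts[:, 0], head_pts[:, 1], 1)
        u = np.array([1.0, coef[0]])
    else:
        u = nodes[0] - nodes[1]
    u = u / np.hypot(*u)
    theta_rot = float(np.degrees(np.arctan2(u[1], u[0])))
    # theta_rot lies within +/-90 of the rotation reference, so adding it to
    # prev_heading yields a heading that is continuous across frames (no
    # +/-180 wrap); wrap externally if a compass angle is needed
    theta = theta_rot + prev_heading

    gammas = np.empty(5)
    for i in range(5):
        d = nodes[i + 2] - nodes[i + 1]
        a = np.degrees(np.arctan2(d[1], d[0]))
        gammas[i] = _wrap180(a - theta_rot - 180.0)

    nodes_orig = to_orig(nodes)
    head_center = 0.5 * (nodes_orig[0] + nodes_orig[1])
    return MidlinePose(
        frame_index=frame_index, theta_deg=float(theta), gamma_deg=gammas,
        head_center=head_center, snout=nodes_orig[0], vertices=nodes_orig,
    )


def track_stack(
    binary_stack: np.ndarray,
    valid: np.ndarray | None = None,
    head_fraction: float = 0.30,
    initial_heading_deg: float | None = None,
) -> list[MidlinePose]:
    """Run midline extraction over a stack with frame-to-frame heading
    continuity (each frame is rotated to the previous frame's theta)."""
    poses: list[MidlinePose] = []
    heading = initial_heading_deg
    for k, frame in enumerate(binary_stack):
        if valid is not None and not valid[k]:
            poses.append(MidlinePose(k, np.nan, np.full(5, np.nan),
                                     np.full(2, np.nan), np.full(2, np.nan),
                                     np.full((7, 2), np.nan), valid=False))
            continue
        if heading is None:
            heading = initial_heading(frame)
        pose = extract_midline(frame, heading, head_fraction, frame_index=k)
        poses.append(pose)
        heading = pose.theta_deg
    return poses


# ---------------------------------------------------------------------------
# prey tracking and geometry
# ---------------------------------------------------------------------------

def track_prey(
    binary_stack: np.ndarray,
    seed_centroid: tuple[float, float],
    max_jump_px: float = 15.0,
    max_gap: int = 5,
    max_area: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Track the prey particle across a binary stack.

    ``binary_stack`` should contain the prey as a small component; if
    ``max_area`` is given, larger objects (the fish) are rejected first.
    The per-frame centroid is the component centroid nearest the previous
    centroid within ``max_jump_px``.  Frames without a candidate are flagged
    (centroid carried over); more than ``max_gap`` consecutive misses raises
    :class:`TrackLostError`.  Returns ``(centroids, found)``.
    """
    prev = np.asarray(seed_centroid, dtype=float)
    centroids = np.empty((len(binary_stack), 2))
    found = np.zeros(len(binary_stack), dtype=bool)
    gap = 0
    for k, frame in enumerate(binary_stack):
        lab, n = ndi.label(frame)
        best, best_d = None, np.inf
        if n:
            idx = np.arange(1, n + 1)
            sizes = ndi.sum_labels(frame, lab, index=idx)
            keep = idx if max_area is None else idx[sizes <= max_area]
            if len(keep):
                cys_cxs = ndi.center_of_mass(frame, lab, keep)
                for (cy, cx) in np.atleast_2d(cys_cxs):
                    d = np.hypot(cx - prev[0], cy - prev[1])
                    if d < best_d:
                        best, best_d = np.array([cx, cy]), d
        if best is not None and best_d <= max_jump_px:
            prev = best
            centroids[k] = best
            found[k] = True
            gap = 0
        else:
            centroids[k] = prev
            gap += 1
            if gap > max_gap:
                raise TrackLostError(k)
    return centroids, found


def _signed_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Signed angle from u to v in degrees, positive toward the fish's right
    (clockwise on screen with y down)."""
    return float(np.degrees(np.arctan2(u[0] * v[1] - u[1] * v[0],
                                       u[0] * v[0] + u[1] * v[1])))


def prey_geometry(
    pose: MidlinePose,
    prey_centroid: np.ndarray,
    prey_major_px: float,
    pixel_size: float,
    reference: str = "head_center",
    eye_offset_fraction: float = 0.25,
) -> PreyObservation:
    """Fish-target angle phi, distance d and angular size for one frame.

    ``reference`` selects the fish-side reference point: ``"head_center"``
    (center of the head segment, as used for d) or ``"eye_midpoint"`` (a
    point ``eye_offset_fraction`` of the head-segment length forward of the
    head center, approximating the midpoint between the eyes).
    """
    th = np.deg2rad(pose.theta_deg)
    u = np.array([np.cos(th), np.sin(th)])
    ref = np.asarray(pose.head_center, dtype=float)
    if reference == "eye_midpoint":
        head_len = np.hypot(*(pose.vertices[0] - pose.vertices[1]))
        ref = ref + eye_offset_fraction * head_len * u
    elif reference != "head_center":
        raise ValueError(f"unknown reference {reference!r}")
    v = np.asarray(prey_centroid, dtype=float) - ref
    d_px = float(np.hypot(*v))
    if d_px == 0:
        raise ValueError("degenerate geometry: prey at reference point")
    phi = _signed_angle(u, v)
    d_mm = d_px * pixel_size
    ang = 2.0 * np.degrees(np.arctan(prey_major_px * pixel_size / (2.0 * d_mm)))
    return PreyObservation(pose.frame_index, np.asarray(prey_centroid, float),
                           phi, d_mm, ang)


def prey_geometry_series(
    poses: list[MidlinePose],
    centroids: np.ndarray,
    prey_major_px: float,
    pixel_size: float,
    fs: float,
    **kwargs,
) -> list[PreyObservation]:
    """Per-frame prey geometry with angular velocity from centered
    differences of phi scaled by the frame rate."""
    obs = [prey_geometry(p, c, prey_major_px, pixel_size, **kwargs)
           for p, c in zip(poses, centroids)]
    phi = np.array([o.phi_deg for o in obs])
    if len(phi) >= 3:
        vel = np.gradient(phi) * fs
        for o, v in zip(obs, vel):
            o.angular_velocity_deg_s = float(v)
    return obs


# ---------------------------------------------------------------------------
# eyes
# ---------------------------------------------------------------------------

def _ellipse_from_moments(mask: np.ndarray):
    """Center, major-axis angle (deg, x-right/y-down), and axis lengths."""
    ys, xs = np.nonzero(mask)
    cx, cy = xs.mean(), ys.mean()
    dx, dy = xs - cx, ys - cy
    vxx, vyy, vxy = np.mean(dx * dx), np.mean(dy * dy), np.mean(dx * dy)
    angle = 0.5 * np.degrees(np.arctan2(2 * vxy, vxx - vyy))
    common = np.sqrt((vxx - vyy) ** 2 + 4 * vxy ** 2)
    major = 4.0 * np.sqrt(max((vxx + vyy + common) / 2.0, 0))
    minor = 4.0 * np.sqrt(max((vxx + vyy - common) / 2.0, 0))
    return np.array([cx, cy]), angle, major, minor


def fit_eyes(
    frame: np.ndarray,
    roi: tuple[int, int, int, int],
    body_axis_deg: float,
    min_area: int = 5,
    frame_index: int = 0,
) -> EyePose:
    """Fit the two eyes inside ``roi`` as dark ellipses against the bright head.

    ``roi`` is (row0, row1, col0, col1) and must contain both eyes.  An
    adaptive (Otsu) threshold segments the bright head; the eyes are the two
    largest dark holes inside it.  Eye angle is the signed angle between the
    ellipse major axis and the body axis, nasal rotation positive; left and
    right are assigned by the side of the body axis.
    """
    from skimage.filters import threshold_otsu

    r0, r1, c0, c1 = roi
    sub = frame[r0:r1, c0:c1]
    head = sub >= threshold_otsu(sub)
    holes = ndi.binary_fill_holes(head) & ~head
    holes = morphology.remove_small_objects(holes, max_size=min_area - 1)
    lab, n = ndi.label(holes)
    if n < 2:
        return EyePose(frame_index, missing=True)
    sizes = ndi.sum_labels(holes, lab, index=np.arange(1, n + 1))
    pick = 1 + np.argsort(sizes)[-2:]

    th = np.deg2rad(body_axis_deg)
    u = np.array([np.cos(th), np.sin(th)])
    ys, xs = np.nonzero(head)
    axis_pt = np.array([xs.mean() + c0, ys.mean() + r0])

    eyes = []
    for p in pick:
        center, angle, major, minor = _ellipse_from_moments(lab == p)
        center = center + np.array([c0, r0])
        raw = _wrap180(angle - body_axis_deg)
        if raw > 90:
            raw -= 180
        elif raw <= -90:
            raw += 180
        v = center - axis_pt
        side = u[0] * v[1] - u[1] * v[0]       # > 0: fish's right
        eyes.append((side, center, raw, major, minor))

    eyes.sort(key=lambda e: e[0])              # left (negative side) first
    (sl, cl, rawl, majl, minl), (sr, cr, rawr, majr, minr) = eyes
    # nasal-positive: left eye major axis at theta + e, right eye at theta - e
    return EyePose(
        frame_index,
        left_deg=float(rawl),
        right_deg=float(-rawr),
        centers=np.stack([cl, cr]),
        axes=np.array([[majl, minl], [majr, minr]]),
    )


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def poses_to_dataframe(
    poses: list[MidlinePose],
    prey: list[PreyObservation] | None = None,
    eyes: list[EyePose] | None = None,
    fs: float = 500.0,
):
    """Assemble per-frame results into the standard pose table."""
    import pandas as pd

    rows = []
    for k, p in enumerate(poses):
        row = {
            "frame": p.frame_index,
            "time_ms": p.frame_index * 1000.0 / fs,
            "theta_deg": p.theta_deg,
        }
        for i in range(5):
            row[f"gamma{i + 1}_deg"] = p.gamma_deg[i]
        if prey is not None:
            row["phi_deg"] = prey[k].phi_deg
            row["d_mm"] = prey[k].d_mm
        if eyes is not None:
            row["eye_l_deg"] = eyes[k].left_deg
            row["eye_r_deg"] = eyes[k].right_deg
        rows.append(row)
    return pd.DataFrame(rows)
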