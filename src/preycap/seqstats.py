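"""Sequence-level statistics for prey-capture bout sequences.

Covers inter-bout intervals, the two-step eye-convergence criterion that
marks the start of a capture sequence, straight-line fits with the
left/right reflection conventions used for pooling (point reflection about
the origin for signed-angle scatter, mirror reflection about the y-axis for
magnitude-vs-angle scatter), and the folded 10-degree-bin histograms of
fish-target angles and orientation changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .boutspec import SwimBout

__all__ = [
    "CaptureSequence",
    "FitResult",
    "SequenceStart",
    "compute_ibis",
    "linefit",
    "angle_histograms",
    "classify_sequence_start",
]


@dataclass
class FitResult:
    slope: float
    intercept: float
    r: float
    n: int
    reflect_mode: str


@dataclass
class SequenceStart:
    index: int | None
    reason: str = ""


@dataclass
class CaptureSequence:
    """An ordered bout list with its IBI series and eye-angle course.

    ``eye_course`` holds (ipsi, contra) angles at each bout boundary
    (before bout 1, after bout 1, ...), with the ipsilateral/contralateral
    assignment fixed by the prey side before the first swim.
    """

    bouts: list[SwimBout]
    ibi_ms: np.ndarray
    eye_course: np.ndarray | None = None       # (n_bouts + 1, 2) = (ipsi, contra)
    start_index: int | None = None


def compute_ibis(bouts: list[SwimBout] | np.ndarray) -> np.ndarray:
    """IBI_j = onset_{j+1} - offset_j for time-ordered, non-overlapping bouts.

    Accepts SwimBout lists or an (n, 2) array of (onset, offset) pairs.
    A single bout yields an empty series; overlap raises ValueError.
    """
    if len(bouts) and isinstance(bouts[0], SwimBout):
        win = np.array([[b.onset_ms, b.offset_ms] for b in bouts])
    else:
        win = np.atleast_2d(np.asarray(bouts, dtype=float))
    if len(win) < 2:
        return np.empty(0)
    ibis = win[1:, 0] - win[:-1, 1]
    if np.any(ibis <= 0):
        raise ValueError("bouts overlap or are out of order")
    return ibis


def linefit(xs, ys, reflect_mode: str = "none") -> FitResult:
    """Least-squares line with the plotting reflection conventions.

    ``point``: pairs with x < 0 are point-reflected about the origin
    (both x and y negated) — used for signed-vs-signed angle scatter so left
    and right turns pool.  ``mirror_x``: only x is negated for pairs with
    x < 0 — used when y is a magnitude.  Pearson r is computed on the
    reflected data, matching the fit as plotted.
    """
    xs = np.asarray(xs, dtype=float).copy()
    ys = np.asarray(ys, dtype=float).copy()
    if len(xs) != len(ys) or len(xs) < 3:
        raise ValueError("need at least 3 (x, y) pairs")
    neg = xs < 0
    if reflect_mode == "point":
        xs[neg] *= -1
        ys[neg] *= -1
    elif reflect_mode == "mirror_x":
        xs[neg] *= -1
    elif reflect_mode != "none":
        raise ValueError(f"unknown reflect_mode {reflect_mode!r}")
    if np.ptp(xs) == 0:
        raise ValueError("zero variance in x")
    slope, intercept = np.polyfit(xs, ys, 1)
    r = _stats.pearsonr(xs, ys).statistic if np.ptp(ys) > 0 else 0.0
    return FitResult(float(slope), float(intercept), float(r), len(xs),
                     reflect_mode)


def _fold_bin(a: np.ndarray) -> np.ndarray:
    """Folded 10-degree bin index: bin 1 is |a| < 5, bin m >= 2 covers
    |a| in [10m - 15, 10m - 5)."""
    a = np.abs(np.asarray(a, dtype=float))
    return np.where(a < 5.0, 1, (np.floor((a - 5.0) / 10.0) + 2).astype(int))


def angle_histograms(
    phi_pre: np.ndarray,
    dtheta: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Folded-absolute 10-degree histograms and their ratio.

    Returns ``(phi_counts, dtheta_counts, normalized)`` over a common bin
    range, where ``normalized[m] = dtheta_counts[m] / phi_counts[m]`` (NaN
    where the occurrence count is zero — undefined bins).
    """
    phi_bins = _fold_bin(phi_pre)
    dth_bins = _fold_bin(dtheta)
    m = int(max(phi_bins.max(initial=1), dth_bins.max(initial=1)))
    phi_counts = np.bincount(phi_bins, minlength=m + 1)[1:]
    dth_counts = np.bincount(dth_bins, minlength=m + 1)[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(phi_counts > 0, dth_counts / phi_counts, np.nan)
    return phi_counts, dth_counts, norm


def classify_sequence_start(
    eye_course: np.ndarray,
    contra_high: float = 21.9,
    ipsi_high: float = 24.0,
) -> SequenceStart:
    """Locate the sequence start by the two-step eye convergence pattern.

    ``eye_course`` is (n_boundaries, 2) = (ipsi, contra) nasal-positive eye
    angles at bout boundaries (entry b is the state after bout b; entry 0 is
    pre-sequence).  The sequence starts at the first bout whose boundary
    brings the contralateral eye above ``contra_high`` with the ipsilateral
    eye above ``ipsi_high`` by the following boundary.  The default
    thresholds sit midway between typical pre-sequence and fully converged
    angles (~13-15 vs ~31-32 degrees).
    """
    eye = np.asarray(eye_course, dtype=float)
    if eye.ndim != 2 or eye.shape[1] != 2 or len(eye) < 2:
        return SequenceStart(None, "missing eye data")
    if np.isnan(eye).any():
        return SequenceStart(None, "missing eye data")
    ipsi, contra = eye[:, 0], eye[:, 1]
    n_bouts = len(eye) - 1
    for b in range(1, n_bouts + 1):
        if contra[b] >= contra_high:
            j_next = min(b + 1, n_bouts)
            if ipsi[j_next] >= ipsi_high:
                return SequenceStart(b - 1)     # 0-based bout index
    return SequenceStart(None, "no two-step convergence found")
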