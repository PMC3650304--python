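"""Spectral decomposition of swim bouts and per-bout kinematic metrics.

A swim bout's five tail-segment angle waveforms gamma_1..gamma_5 are
windowed (150 ms free / 300 ms restrained), Bessel band-pass filtered
(0.5-100 Hz, order 4, zero phase), transformed with the DFT and converted to
single-sided RMS amplitude spectra::

    X_k = sum_n x_n exp(-i 2 pi n k / N)        (DFT)
    A_k = X_k / N                               (two-sided complex spectrum)
    B_0 = A_0;  B_k = 2 A_k  for k = 1..N/2-1   (single-sided RMS spectrum)
    B_mag = |B_k|

The five per-segment spectra are summed, cubic-spline interpolated onto a
fine frequency grid, and the low-frequency (LF, ~3-5 Hz, scales with the
turn) and high-frequency (HF, ~20-35 Hz, the tail-beat frequency) peaks are
read off.  The Direction Index assigns a sign to the LF amplitude:

    DI = sign( integral of the across-segment mean tail angle )
         * mean of the summed spectrum over {3, 4, 5} Hz

so target-directed (rightward-positive) and avoidance turns get opposite
signs while symmetric forward swims get DI ~ 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

__all__ = [
    "SpectrumConfig",
    "BoutSpectrum",
    "SwimBout",
    "detect_bouts",
    "bandpass",
    "rms_spectrum",
    "summed_spectrum",
    "direction_index",
    "bout_metrics",
    "analyze_series",
]


@dataclass
class SpectrumConfig:
    """Windowing, filtering, and peak-search settings.

    ``window_ms`` is 150 for freely moving and 300 for restrained larvae.
    ``N`` (the DFT length) is ``round(window_ms * fs / 1000)`` — at
    250 frames/s and 150 ms this is non-integer (37.5) and rounds to 38.
    """

    window_ms: float = 150.0
    fs: float = 500.0
    band: tuple[float, float] = (0.5, 100.0)
    filter_order: int = 4
    grid_step_hz: float = 0.1
    grid_max_hz: float = 100.0
    lf_band: tuple[float, float] = (2.0, 8.0)
    hf_band: tuple[float, float] = (15.0, 45.0)
    di_freqs: tuple[float, ...] = (3.0, 4.0, 5.0)
    high_cut_for_cycles_hz: float = 15.0

    def __post_init__(self) -> None:
        if not (0 < self.band[0] < self.band[1] < self.fs / 2):
            raise ValueError("filter band must lie within (0, fs/2)")
        if self.lf_band[1] > self.grid_max_hz:
            raise ValueError("LF search band outside interpolation grid")

    @property
    def n_samples(self) -> int:
        return int(round(self.window_ms * self.fs / 1000.0))

    @classmethod
    def for_mode(cls, mode: str, fs: float = 500.0, **kw) -> "SpectrumConfig":
        window = 150.0 if mode == "free" else 300.0
        return cls(window_ms=window, fs=fs, **kw)


@dataclass
class BoutSpectrum:
    """Per-segment and summed single-sided RMS amplitude spectra (degrees)."""

    freq_hz: np.ndarray                 # native DFT bin grid
    per_segment: np.ndarray             # (n_bins, 5)
    summed: np.ndarray                  # (n_bins,)
    grid_hz: np.ndarray                 # interpolated grid
    summed_interp: np.ndarray
    lf_peak: tuple[float, float] | None     # (freq, amplitude)
    hf_peak: tuple[float, float] | None


@dataclass
class SwimBout:
    onset_ms: float
    offset_ms: float
    dtheta_deg: float = np.nan
    phi_pre_deg: float = np.nan
    phi_post_deg: float = np.nan
    di: float = np.nan
    spectrum: BoutSpectrum | None = None
    first_cycle_ms: float = np.nan
    n_cycles: int = 0
    dd_mm: float = np.nan
    ordinal: int = 0


# ---------------------------------------------------------------------------
# detection and filtering
# ---------------------------------------------------------------------------

def detect_bouts(
    trace: np.ndarray,
    fs: float,
    threshold: float,
    min_duration_ms: float = 40.0,
    min_gap_ms: float = 50.0,
) -> list[tuple[float, float]]:
    """Detect swim bouts as threshold crossings of ``|trace|``.

    Onset is the first sample with ``|x| >= threshold``; the bout ends when
    ``|x|`` stays below threshold for ``min_gap_ms`` (the offset timestamp is
    the start of that quiet stretch).  Events shorter than
    ``min_duration_ms`` are discarded.  Returns time-ordered, non-overlapping
    ``(onset_ms, offset_ms)`` pairs.
    """
    x = np.abs(np.asarray(trace, dtype=float)) >= threshold
    dt = 1000.0 / fs
    gap_n = max(1, int(round(min_gap_ms / dt)))
    events: list[tuple[float, float]] = []
    idx = np.flatnonzero(x)
    if len(idx) == 0:
        return events
    onset = idx[0]
    last = idx[0]
    for i in idx[1:]:
        if i - last > gap_n:
            events.append((onset * dt, (last + 1) * dt))
            onset = i
        last = i
    events.append((onset * dt, (last + 1) * dt))
    return [(a, b) for a, b in events if b - a >= min_duration_ms]


def bandpass(trace: np.ndarray, cfg: SpectrumConfig) -> np.ndarray:
    """Zero-phase Bessel band-pass (order ``cfg.filter_order``, 0.5-100 Hz).

    The 0.5 Hz low cutoff has a settling time far longer than a 150 ms
    analysis window, so the trace is extended with its edge values for
    three low-cutoff time constants on either side before filtering and
    cropped afterwards.  A constant input is then seen as true DC (and
    suppressed), while a swim burst whose window edges are near rest picks
    up no spurious edge transient.
    """
    lo, hi = cfg.band
    if hi >= cfg.fs / 2:
        raise ValueError("high cutoff at or above Nyquist")
    sos = signal.bessel(cfg.filter_order, [lo, hi], btype="bandpass",
                        fs=cfg.fs, output="sos")
    x = np.atleast_1d(np.asarray(trace, dtype=float))
    pad = int(np.ceil(3.0 * cfg.fs / lo))
    first = np.repeat(x[:1], pad, axis=0)
    last = np.repeat(x[-1:], pad, axis=0)
    ext = np.concatenate([first, x, last], axis=0)
    y = signal.sosfiltfilt(sos, ext, axis=0)
    return y[pad:pad + len(x)]


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def rms_spectrum(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Single-sided RMS amplitude spectrum of one windowed trace.

    Returns ``(freq_hz, b_mag)`` on the native bin grid ``k * fs / N`` for
    ``k = 0 .. N//2 - 1``: the DC bin keeps ``|A_0|`` while every other bin
    is doubled (``|2 A_k|``), so a unit cosine at an exact bin has amplitude
    exactly 1.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 8:
        raise ValueError("window too short (N >= 8 required)")
    a = np.fft.fft(x) / n
    k = n // 2
    b = a[:k].copy()
    b[1:] *= 2.0
    freqs = np.arange(k) * fs / n
    return freqs, np.abs(b)


def summed_spectrum(
    gammas: np.ndarray,
    cfg: SpectrumConfig,
    apply_bandpass: bool = True,
) -> BoutSpectrum:
    """Per-segment RMS spectra of the five windowed tail-angle traces,
    summed and spline-interpolated; LF/HF peaks are the interpolated maxima
    in the configured search bands (flagged None for all-zero input)."""
    gammas = np.asarray(gammas, dtype=float)
    if gammas.ndim != 2 or gammas.shape[1] != 5:
        raise ValueError("expected (N, 5) tail-angle window")
    if apply_bandpass:
        gammas = bandpass(gammas, cfg)
    per = []
    for i in range(5):
        freqs, bmag = rms_spectrum(gammas[:, i], cfg.fs)
        per.append(bmag)
    per = np.stack(per, axis=1)
    summed = per.sum(axis=1)

    grid = np.arange(0.0, min(cfg.grid_max_hz, freqs[-1]) + 1e-9,
                     cfg.grid_step_hz)
    spline = CubicSpline(freqs, summed)
    interp = np.clip(spline(grid), 0.0, None)

    if not np.any(summed > 1e-12):
        lf = hf = None
    else:
        lf = _peak_in_band(grid, interp, cfg.lf_band)
        hf = _peak_in_band(grid, interp, cfg.hf_band)
    return BoutSpectrum(freqs, per, summed, grid, interp, lf, hf)


def _peak_in_band(grid, vals, band) -> tuple[float, float]:
    sel = (grid >= band[0]) & (grid <= band[1])
    i = int(np.argmax(vals[sel]))
    return float(grid[sel][i]), float(vals[sel][i])


def direction_index(
    gammas: np.ndarray,
    spectrum: BoutSpectrum,
    cfg: SpectrumConfig,
    apply_bandpass: bool = True,
    zero_tol: float = 0.02,
) -> float:
    """DI = sign(time integral of the mean tail angle) * mean summed-spectrum
    amplitude over the DI frequency set (3, 4, 5 Hz).

    A symmetric oscillation integrates to zero only up to discretization
    residue, so the sign is taken as 0 whenever ``|integral|`` falls below
    ``zero_tol`` times the integral of ``|mean trace|`` (direction
    undefined); genuine turns exceed this by an order of magnitude.
    """
    gammas = np.asarray(gammas, dtype=float)
    if apply_bandpass:
        gammas = bandpass(gammas, cfg)
    mean_trace = gammas.mean(axis=1)
    integral = np.trapezoid(mean_trace, dx=1.0 / cfg.fs)
    scale = np.trapezoid(np.abs(mean_trace), dx=1.0 / cfg.fs)
    if abs(integral) <= zero_tol * scale:
        return 0.0
    s = np.sign(integral)
    spline = CubicSpline(spectrum.freq_hz, spectrum.summed)
    amp = float(np.mean(np.clip(spline(np.asarray(cfg.di_freqs)), 0.0, None)))
    return float(s * amp)


# ---------------------------------------------------------------------------
# per-bout metrics
# ---------------------------------------------------------------------------

def _window_indices(t_ms: np.ndarray, onset: float, offset: float,
                    cfg: SpectrumConfig) -> np.ndarray:
    """Indices of the analysis window centered on the bout midpoint,
    clipped to the series."""
    mid = 0.5 * (onset + offset)
    n = cfg.n_samples
    if len(t_ms) <= n:
        return np.arange(len(t_ms))          # clipped to the series
    k_mid = int(np.argmin(np.abs(t_ms - mid)))
    lo = max(0, min(k_mid - n // 2, len(t_ms) - n))
    return np.arange(lo, lo + n)


def bout_metrics(
    t_ms: np.ndarray,
    theta_deg: np.ndarray,
    gamma_deg: np.ndarray,
    window: tuple[float, float],
    cfg: SpectrumConfig,
    phi_deg: np.ndarray | None = None,
    d_mm: np.ndarray | None = None,
    ordinal: int = 0,
) -> SwimBout:
    """Assemble one SwimBout from pose (and optional prey) series.

    dtheta is theta at the first frame after offset minus theta at the last
    frame before onset; phi_pre/phi_post and the distance advance dd use the
    same two frames.  The first-cycle duration is the time from onset to the
    second zero crossing of the high-band (>15 Hz) mean tail angle, and
    ``n_cycles = floor(zero-crossing count / 2)``.
    """
    onset, offset = window
    pre = np.flatnonzero(t_ms < onset)
    post = np.flatnonzero(t_ms > offset)
    if len(pre) == 0 or len(post) == 0:
        raise ValueError("bout at the edge of the series")
    i_pre, i_post = pre[-1], post[0]

    bout = SwimBout(onset_ms=onset, offset_ms=offset, ordinal=ordinal)
    bout.dtheta_deg = float(theta_deg[i_post] - theta_deg[i_pre])
    if phi_deg is not None:
        bout.phi_pre_deg = float(phi_deg[i_pre])
        bout.phi_post_deg = float(phi_deg[i_post])
    if d_mm is not None:
        bout.dd_mm = float(d_mm[i_pre] - d_mm[i_post])

    idx = _window_indices(t_ms, onset, offset, cfg)
    win = gamma_deg[idx]
    bout.spectrum = summed_spectrum(win, cfg)
    bout.di = direction_index(win, bout.spectrum, cfg)

    # cycle metrics from the high-band mean tail angle inside the bout
    high = highband(gamma_deg.mean(axis=1), cfg)
    inb = (t_ms >= onset) & (t_ms <= offset)
    times = zero_crossings(high[inb], t_ms[inb])
    bout.n_cycles = len(times) // 2
    if len(times) >= 2:
        bout.first_cycle_ms = float(times[1] - onset)
    return bout


def highband(x: np.ndarray, cfg: SpectrumConfig) -> np.ndarray:
    """High-band (> ``high_cut_for_cycles_hz``) component as the zero-phase
    complement of a Butterworth low-pass.  The complement has real positive
    gain at every frequency, so the tail-beat zero-crossing positions are
    preserved exactly while the slow turn component is removed."""
    x = np.asarray(x, dtype=float)
    sos = signal.butter(4, cfg.high_cut_for_cycles_hz, btype="lowpass",
                        fs=cfg.fs, output="sos")
    pad = int(np.ceil(3.0 * cfg.fs / cfg.high_cut_for_cycles_hz))
    ext = np.concatenate([np.repeat(x[:1], pad, axis=0), x,
                          np.repeat(x[-1:], pad, axis=0)], axis=0)
    low = signal.sosfiltfilt(sos, ext, axis=0)[pad:pad + len(x)]
    return x - low


def zero_crossings(x: np.ndarray, t: np.ndarray | None = None,
                   sig_frac: float = 0.25):
    """Tail-beat zero-crossing times (linearly interpolated).

    Counting starts at the first sample where the waveform reaches
    ``sig_frac`` of its absolute maximum (the rise of the first beat), which
    skips filter edge artifacts preceding the oscillation; from there every
    sign change counts, including the low-amplitude final crossing under the
    decaying envelope.
    """
    x = np.asarray(x, dtype=float)
    if t is None:
        t = np.arange(len(x), dtype=float)
    if len(x) == 0 or np.max(np.abs(x)) == 0:
        return np.asarray([])
    start = int(np.argmax(np.abs(x) >= sig_frac * np.max(np.abs(x))))
    xs, ts = x[start:], t[start:]
    sgn = np.sign(xs)
    nz = sgn != 0
    xs, ts = xs[nz], ts[nz]
    flips = np.flatnonzero(np.sign(xs[:-1]) * np.sign(xs[1:]) < 0)
    times = [ts[j] + (ts[j + 1] - ts[j]) * (0.0 - xs[j]) / (xs[j + 1] - xs[j])
             for j in flips]
    return np.asarray(times)


def analyze_series(
    t_ms: np.ndarray,
    theta_deg: np.ndarray,
    gamma_deg: np.ndarray,
    cfg: SpectrumConfig,
    threshold: float = 3.0,
    phi_deg: np.ndarray | None = None,
    d_mm: np.ndarray | None = None,
    **detect_kw,
) -> list[SwimBout]:
    """Detect bouts on the mean tail angle and compute metrics for each."""
    mean_gamma = np.abs(gamma_deg).mean(axis=1)
    windows = detect_bouts(mean_gamma, cfg.fs, threshold, **detect_kw)
    bouts = []
    for k, (a, b) in enumerate(windows):
        try:
            bouts.append(bout_metrics(t_ms, theta_deg, gamma_deg, (a, b), cfg,
                                      phi_deg=phi_deg, d_mm=d_mm, ordinal=k))
        except ValueError:
            continue
    return bouts


def bouts_to_dataframe(bouts: list[SwimBout]):
    """Per-bout table with the standard column layout."""
    import pandas as pd

    rows = []
    for b in bouts:
        lf = b.spectrum.lf_peak if b.spectrum else None
        hf = b.spectrum.hf_peak if b.spectrum else None
        rows.append({
            "onset_ms": b.onset_ms, "offset_ms": b.offset_ms,
            "dtheta_deg": b.dtheta_deg, "phi_pre_deg": b.phi_pre_deg,
            "phi_post_deg": b.phi_post_deg, "DI": b.di,
            "lf_hz": lf[0] if lf else np.nan,
            "lf_amp": lf[1] if lf else np.nan,
            "hf_hz": hf[0] if hf else np.nan,
            "hf_amp": hf[1] if hf else np.nan,
            "first_cycle_ms": b.first_cycle_ms, "n_cycles": b.n_cycles,
            "dd_mm": b.dd_mm,
        })
    return pd.DataFrame(rows)
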