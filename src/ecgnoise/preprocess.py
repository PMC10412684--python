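"""Signal conditioning for ECG blocks.

The chain, in order: cubic-spline baseline-wander removal (median knots on
non-overlapped 1.2-s windows), a 50 Hz powerline notch, a 0.5-40 Hz bandpass
built from cascaded 5th-order Butterworth high- and lowpass sections, and a
per-block amplitude normalization to zero mean and unit standard deviation.

Offline filtering is forward-backward (zero phase) so R-peak timing is not
shifted; the streaming tracker reuses the same filters single-pass and
documents the group delay instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import interpolate, signal


class DegenerateBlockError(ValueError):
    """The block has zero variance (flatline / T4-like) and must be excluded."""


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class PreprocessConfig:
    knot_window: float = 1.2          # s, baseline knot spacing
    notch_freq: float = 50.0          # Hz
    notch_q: float = 30.0             # ~1.7 Hz -3 dB width at 50 Hz
    band: tuple[float, float] = (0.5, 40.0)   # Hz
    butter_order: int = 5

    def validate(self, fs: float) -> None:
        low, high = self.band
        if not (0 < low < high < fs / 2):
            raise PreprocessError(f"band {self.band} outside (0, fs/2={fs / 2})")
        if not (0 < self.notch_freq < fs / 2):
            raise PreprocessError(f"notch {self.notch_freq} Hz outside (0, fs/2)")
        if self.knot_window <= 0:
            raise PreprocessError("knot_window must be positive")


def estimate_baseline(
    samples: np.ndarray, fs: float, knot_window: float = 1.2
) -> np.ndarray:
    """Estimate baseline drift with a cubic spline through windowed medians.

    Knots are (window-center time, window median) over non-overlapped
    ``knot_window``-second windows; the spline is evaluated at every sample.
    Beyond the first/last knot the estimate is clamped to the boundary knot
    value to avoid wild extrapolation.
    """
    x = np.asarray(samples, dtype=float)
    w = int(round(knot_window * fs))
    n_win = x.size // w
    if n_win < 2:
        raise PreprocessError(
            f"signal of {x.size} samples shorter than two {knot_window}-s windows"
        )
    centers = (np.arange(n_win) + 0.5) * w
    knots = np.array([np.median(x[i * w : (i + 1) * w]) for i in range(n_win)])
    t = np.arange(x.size, dtype=float)
    if n_win >= 4:
        spline = interpolate.CubicSpline(centers, knots, bc_type="natural")
        drift = spline(np.clip(t, centers[0], centers[-1]))
    else:
        # too few knots for a cubic piece; fall back to linear interpolation
        drift = np.interp(t, centers, knots)
    return drift


def remove_baseline(
    samples: np.ndarray, fs: float, knot_window: float = 1.2
) -> np.ndarray:
    return np.asarray(samples, float) - estimate_baseline(samples, fs, knot_window)


def remove_powerline(
    samples: np.ndarray,
    fs: float,
    notch_freq: float = 50.0,
    q: float = 30.0,
    zero_phase: bool = True,
) -> np.ndarray:
    """Second-order IIR notch at the powerline frequency."""
    if fs <= 2 * notch_freq:
        raise PreprocessError(
            f"notch at {notch_freq} Hz needs fs > {2 * notch_freq} Hz, got {fs}"
        )
    b, a = _notch_ba(notch_freq, q, fs)
    x = np.asarray(samples, float)
    if zero_phase:
        return signal.filtfilt(b, a, x)
    return signal.lfilter(b, a, x)


@lru_cache(maxsize=64)
def butter_sos(order: int, lo: float, hi: float | None, btype: str, fs: float):
    """Cached Butterworth design (filter design dominates short-block cost)."""
    wn = lo if hi is None else (lo, hi)
    return signal.butter(order, wn, btype=btype, fs=fs, output="sos")


@lru_cache(maxsize=16)
def _notch_ba(notch_freq: float, q: float, fs: float):
    return signal.iirnotch(notch_freq, q, fs=fs)


def _band_sos(fs: float, band: tuple[float, float], order: int):
    low, high = band
    if not (0 < low < high < fs / 2):
        raise PreprocessError(f"band {band} outside Nyquist for fs={fs}")
    sos_hp = butter_sos(order, low, None, "highpass", fs)
    sos_lp = butter_sos(order, high, None, "lowpass", fs)
    return np.vstack([sos_hp, sos_lp])


def bandpass_filter(
    samples: np.ndarray,
    fs: float,
    band: tuple[float, float] = (0.5, 40.0),
    order: int = 5,
    zero_phase: bool = True,
) -> np.ndarray:
    """Cascade of 5th-order Butterworth highpass then lowpass sections."""
    sos = _band_sos(fs, band, order)
    x = np.asarray(samples, float)
    if zero_phase:
        return signal.sosfiltfilt(sos, x)
    return signal.sosfilt(sos, x)


def normalize_block(block: np.ndarray) -> np.ndarray:
    """Scale a block to zero mean, unit (population) standard deviation.

    Raises :class:`DegenerateBlockError` on flatlines so the caller can
    exclude T4-like blocks.
    """
    x = np.asarray(block, dtype=float)
    if x.size < 2:
        raise PreprocessError("block must have at least 2 samples")
    sigma = x.std()          # population convention (ddof=0)
    if sigma == 0:
        raise DegenerateBlockError("zero-variance block")
    return (x - x.mean()) / sigma


@dataclass
class PreprocessedBlock:
    """All conditioning stages of one block, kept for feature extraction.

    Baseline-related indices need the signal *before* drift correction, and
    the plain statistical moments are taken on the filtered but
    unnormalized signal, so each stage is retained.
    """

    raw: np.ndarray = field(repr=False)
    baseline: np.ndarray = field(repr=False)       # estimated drift of raw
    filtered: np.ndarray = field(repr=False)       # drift-removed, notched, bandpassed
    normalized: np.ndarray = field(repr=False)     # filtered, then unit-variance
    fs: float = 200.0
    degenerate: bool = False


def preprocess_block(
    samples: np.ndarray,
    fs: float,
    config: PreprocessConfig | None = None,
) -> PreprocessedBlock:
    """Run the full conditioning chain on one block.

    Order: baseline removal -> notch -> bandpass -> normalization.  A
    flatline block yields ``degenerate=True`` with ``normalized`` set to
    zeros (callers decide whether to exclude or flag it).
    """
    cfg = config or PreprocessConfig()
    cfg.validate(fs)
    raw = np.asarray(samples, dtype=float)
    baseline = estimate_baseline(raw, fs, cfg.knot_window)
    x = raw - baseline
    x = remove_powerline(x, fs, cfg.notch_freq, cfg.notch_q)
    x = bandpass_filter(x, fs, cfg.band, cfg.butter_order)
    try:
        normalized = normalize_block(x)
        degenerate = False
    except DegenerateBlockError:
        normalized = np.zeros_like(x)
        degenerate = True
    return PreprocessedBlock(
        raw=raw,
        baseline=baseline,
        filtered=x,
        normalized=normalized,
        fs=fs,
        degenerate=degenerate,
    )
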