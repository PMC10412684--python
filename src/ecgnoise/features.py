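"""The 16 per-block signal-quality indices and the class-separability screen.

For each 5-s single-category block the extractor computes, in fixed order:

====  ==========================================================
x1    R-wave detection accuracy (agreement of two detectors)
x2    correlation-based periodicity at the RR lag
x3    baseline-wander check (baseline RMS / signal RMS)
x4    relative amplitude of high-frequency noise outside QRS
x5    mean
x6    standard deviation
x7    skewness
x8    kurtosis (Pearson, Gaussian -> 3)
x9    relative STD of the QRS windows
x10   spectral purity index (from spectral moments)
x11   sample entropy (m=2, r=0.2*sigma)
x12   relative power of the baseline-wander band (<1 Hz)
x13   relative power of the QRS band (5-15 Hz over 5-40 Hz)
x14   relative energy inside QRS windows
x15   central frequency (spectral centroid)
x16   modulation-spectrum quality index (energy at heart-rate
      harmonics of the spectrogram envelopes)
====  ==========================================================

Conventions that the literature leaves open are fixed here and exposed as
parameters: QRS windows are R +- 60 ms, detector matching tolerance is
150 ms, Welch uses 1-s Hann segments with 50% overlap, and the moments use
the population (divide-by-N) convention.  x5/x6 are computed on the filtered
but *not* block-normalized signal (after normalization they would be the
constants 0 and 1); x3 and x12 use the signal before baseline correction.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np
from scipy import signal, stats

from .preprocess import (
    DegenerateBlockError,
    PreprocessConfig,
    PreprocessedBlock,
    butter_sos,
    preprocess_block,
)

#: fallback heart rate (bpm) when no RR interval is detectable in a block
DEFAULT_HR_BPM = 70.0

#: half-width of a QRS window around each detected R peak, seconds
QRS_HALF_WINDOW = 0.060

#: tolerance for matching peaks between the two detectors, seconds
MATCH_TOL = 0.150


@dataclass(frozen=True)
class FeatureVector:
    """The 16 quality indices of one block, in stable x1..x16 order."""

    x1: float   # R-wave detection accuracy
    x2: float   # periodicity rho
    x3: float   # BW check
    x4: float   # relative HF-noise amplitude
    x5: float   # mean
    x6: float   # STD
    x7: float   # skewness
    x8: float   # kurtosis
    x9: float   # relative STD of QRS
    x10: float  # spectral purity index
    x11: float  # sample entropy
    x12: float  # relative BW power
    x13: float  # relative QRS power
    x14: float  # relative QRS energy
    x15: float  # central frequency
    x16: float  # modulation-spectrum quality index
    rr_fallback: bool = False  # True when no RR was detectable

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f"x{j}") for j in range(1, 17)])

    def __post_init__(self) -> None:
        v = self.as_array()
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite feature in {v}")


FEATURE_NAMES = tuple(f.name for f in dc_fields(FeatureVector))[:16]


# ---------------------------------------------------------------------------
# R-peak detection


def detect_r_peaks(block: np.ndarray, fs: float) -> np.ndarray:
    """Derivative-energy R detector (differentiate, square, integrate, threshold).

    Returns peak times in seconds; a 200 ms refractory period is enforced.
    An empty array is a valid result (flatline or unreadable signal).
    """
    x = np.asarray(block, dtype=float)
    if x.size < fs or np.ptp(x) == 0:
        return np.array([])
    sos = butter_sos(2, 5.0, 15.0, "bandpass", fs)
    xb = signal.sosfiltfilt(sos, x)
    energy = np.gradient(xb) ** 2
    win = max(1, int(0.150 * fs))
    integ = np.convolve(energy, np.ones(win) / win, mode="same")
    if integ.max() <= 0:
        return np.array([])
    locs, _ = signal.find_peaks(
        integ, distance=int(0.200 * fs), height=0.25 * integ.max()
    )
    if locs.size == 0:
        return np.array([])
    # refine each candidate to the largest |amplitude| nearby
    half = int(0.100 * fs)
    refined = []
    for i in locs:
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        refined.append(lo + int(np.argmax(np.abs(xb[lo:hi]))))
    refined = np.unique(refined)
    return refined / fs


def detect_r_peaks_amplitude(block: np.ndarray, fs: float) -> np.ndarray:
    """Second, independent detector: amplitude/prominence peak picking."""
    x = np.asarray(block, dtype=float)
    if x.size < fs or np.ptp(x) == 0:
        return np.array([])
    sos = butter_sos(2, 5.0, 15.0, "bandpass", fs)
    xb = np.abs(signal.sosfiltfilt(sos, x))
    if xb.max() <= 0:
        return np.array([])
    locs, _ = signal.find_peaks(
        xb, distance=int(0.200 * fs), height=0.45 * xb.max()
    )
    return locs / fs


def match_peaks(a: np.ndarray, b: np.ndarray, tol: float) -> int:
    """Count greedily matched pairs within ``tol`` seconds (each used once)."""
    a = np.sort(np.asarray(a, float))
    b = np.sort(np.asarray(b, float))
    i = j = matched = 0
    while i < a.size and j < b.size:
        d = a[i] - b[j]
        if abs(d) <= tol:
            matched += 1
            i += 1
            j += 1
        elif d > 0:
            j += 1
        else:
            i += 1
    return matched


def r_wave_detection_accuracy(block: np.ndarray, fs: float) -> float:
    """x1: agreement of the two detectors, matched within 150 ms.

    ``x1 = matched / max(n1, n2)``; 0 when either detector finds nothing.
    """
    p1 = detect_r_peaks(block, fs)
    p2 = detect_r_peaks_amplitude(block, fs)
    if p1.size == 0 or p2.size == 0:
        return 0.0
    return match_peaks(p1, p2, MATCH_TOL) / max(p1.size, p2.size)


def median_rr(r_peaks: np.ndarray) -> float | None:
    """Median RR interval (s) from detected peak times, or None if < 2 peaks."""
    r_peaks = np.asarray(r_peaks, float)
    if r_peaks.size < 2:
        return None
    return float(np.median(np.diff(np.sort(r_peaks))))


# ---------------------------------------------------------------------------
# Periodicity


def periodicity_rho(block: np.ndarray, fs: float, rr: float) -> float:
    """x2: correlation between the block and its circular shift by one RR lag.

    The shift is ``round(rr * fs)`` samples with wrap-around (modulo the block
    length); the result is the cosine similarity of the two vectors.
    """
    s = np.asarray(block, dtype=float)
    if not (0 < rr * fs):
        raise ValueError(f"rr {rr} must be positive")
    k = int(round(rr * fs)) % s.size
    s_shift = np.roll(s, k)
    denom = np.linalg.norm(s) * np.linalg.norm(s_shift)
    if denom == 0:
        return 0.0
    return float(np.dot(s, s_shift) / denom)


# ---------------------------------------------------------------------------
# Statistical features


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy with template length ``m`` and tolerance ``r`` (nats).

    ``r`` defaults to 0.2 sigma.  Pairs are counted with the Chebyshev
    distance over the N-m templates common to lengths m and m+1, excluding
    self-matches.  Degenerate counts are capped so the result stays finite:
    no m-matches at all -> 0 (regularity unmeasurable, the caller may flag);
    no (m+1)-matches -> ln(B), the value just beyond one observed match.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        raise ValueError(f"need at least {m + 2} samples, got {n}")
    sigma = x.std()
    if r is None:
        if sigma == 0:
            raise DegenerateBlockError("zero-variance signal in sample entropy")
        r = 0.2 * sigma
    d = np.abs(x[:, None] - x[None, :])
    n_templ = n - m
    cheb_m = d[:n_templ, :n_templ].copy()
    for k in range(1, m):
        np.maximum(cheb_m, d[k : n_templ + k, k : n_templ + k], out=cheb_m)
    cheb_m1 = np.maximum(cheb_m, d[m : n_templ + m, m : n_templ + m])
    # symmetric matrices: count off-diagonal pairs once
    b = (int(np.count_nonzero(cheb_m <= r)) - n_templ) // 2
    a = (int(np.count_nonzero(cheb_m1 <= r)) - n_templ) // 2
    if b == 0:
        return 0.0
    if a == 0:
        return float(np.log(b))
    return float(-np.log(a / b))


def statistical_features(block: np.ndarray) -> tuple[float, float, float, float, float]:
    """x5, x6, x7, x8, x11: mean, STD, skewness, kurtosis, sample entropy.

    Population moment convention; Pearson kurtosis (a Gaussian gives ~3).
    Computed on the filtered, *unnormalized* block.
    """
    x = np.asarray(block, dtype=float)
    sigma = float(x.std())
    if sigma == 0:
        raise DegenerateBlockError("zero-variance block")
    return (
        float(x.mean()),
        sigma,
        float(stats.skew(x)),
        float(stats.kurtosis(x, fisher=False)),
        sample_entropy(x, m=2, r=0.2 * sigma),
    )


# ---------------------------------------------------------------------------
# QRS-window time-domain features


def _qrs_mask(n: int, fs: float, r_peaks: np.ndarray) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    half = int(round(QRS_HALF_WINDOW * fs))
    for t in np.asarray(r_peaks, float):
        i = int(round(t * fs))
        mask[max(0, i - half) : min(n, i + half + 1)] = True
    return mask


def qrs_time_domain_features(
    pre: PreprocessedBlock, r_peaks: np.ndarray
) -> tuple[float, float, float, float]:
    """x3, x4, x9, x14 from the QRS windows (R +- 60 ms).

    x3 uses the baseline estimated on the pre-correction signal; x4 is the
    RMS of the >20 Hz residual outside QRS relative to the mean R amplitude.
    With no detected peaks the fallbacks are x4=1, x9=1, x14=0 (worst-case
    values for an unreadable block).
    """
    raw = pre.raw
    x = pre.filtered
    fs = pre.fs
    rms_raw = float(np.sqrt(np.mean(raw**2)))
    rms_base = float(np.sqrt(np.mean(pre.baseline**2)))
    x3 = rms_base / rms_raw if rms_raw > 0 else 0.0

    total_energy = float(np.sum(x**2))
    total_std = float(x.std())
    r_peaks = np.asarray(r_peaks, float)
    if r_peaks.size == 0 or total_energy == 0 or total_std == 0:
        return x3, 1.0, 1.0, 0.0

    mask = _qrs_mask(x.size, fs, r_peaks)
    sos = butter_sos(4, 20.0, None, "highpass", fs)
    hf = signal.sosfiltfilt(sos, x)
    outside = ~mask
    r_amp = float(np.mean(np.abs(x[np.clip((r_peaks * fs).round().astype(int), 0, x.size - 1)])))
    if outside.any() and r_amp > 0:
        x4 = float(np.sqrt(np.mean(hf[outside] ** 2))) / r_amp
    else:
        x4 = 1.0
    x9 = float(x[mask].std()) / total_std if mask.any() else 1.0
    x14 = float(np.sum(x[mask] ** 2)) / total_energy
    return x3, x4, x9, x14


# ---------------------------------------------------------------------------
# Spectral features


def welch_psd(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Welch periodogram with 1-s Hann segments at 50% overlap."""
    nperseg = min(int(round(fs)), len(x))
    return signal.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )


def spectral_purity_index(f: np.ndarray, p: np.ndarray) -> float:
    """SPI = w2^2 / (w0 * w4) from the spectral moments; 1 for a pure tone."""
    w0 = np.trapezoid(p, f)
    w2 = np.trapezoid(f**2 * p, f)
    w4 = np.trapezoid(f**4 * p, f)
    if w0 <= 0 or w4 <= 0:
        raise ValueError("zero total spectral power")
    return float(w2**2 / (w0 * w4))


def spectral_features(
    block: np.ndarray,
    fs: float,
    pre_correction: np.ndarray | None = None,
) -> tuple[float, float, float, float]:
    """x10 SPI, x12 relative BW power, x13 relative QRS power, x15 centroid.

    x12 is computed on ``pre_correction`` (the signal before baseline
    removal) when provided, otherwise on ``block`` itself.
    """
    x = np.asarray(block, dtype=float)
    f, p = welch_psd(x, fs)
    total = np.trapezoid(p, f)
    if total <= 0:
        raise ValueError("zero total spectral power")
    x15 = float(np.trapezoid(f * p, f) / total)
    x10 = spectral_purity_index(f, p)

    qrs_band = (f >= 5.0) & (f <= 15.0)
    wide_band = (f >= 5.0) & (f <= 40.0)
    denom13 = np.trapezoid(p[wide_band], f[wide_band]) if wide_band.sum() > 1 else 0.0
    x13 = (
        float(np.trapezoid(p[qrs_band], f[qrs_band]) / denom13)
        if denom13 > 0
        else 0.0
    )

    src = np.asarray(pre_correction, float) if pre_correction is not None else x
    f2, p2 = welch_psd(src, fs)
    total2 = np.trapezoid(p2, f2)
    bw = f2 <= 1.0
    x12 = float(np.trapezoid(p2[bw], f2[bw]) / total2) if total2 > 0 else 0.0
    return x10, x12, x13, x15


# ---------------------------------------------------------------------------
# Modulation-spectrum quality index


def ms_qi(block: np.ndarray, fs: float, heart_rate_hz: float | None = None) -> float:
    """x16: modulation energy at the heart-rate fundamental and 3 harmonics.

    The block's spectrogram (250 ms Hann windows, 50% overlap) gives one
    temporal envelope per acoustic-frequency band; the modulation spectrum is
    the power spectrum of those envelopes over time, averaged across bands.
    x16 is the energy within +-0.3125 Hz of the first four heart-rate
    harmonics divided by the remaining modulation energy up to 8 Hz (or the
    modulation Nyquist).  Flatlines score 0.
    """
    x = np.asarray(block, dtype=float)
    if np.ptp(x) == 0:
        return 0.0
    nperseg = max(8, int(round(0.25 * fs)))
    if x.size < 2 * nperseg:
        raise ValueError("block too short for the modulation spectrogram")
    f, t, sxx = signal.spectrogram(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    band = (f >= 0.5) & (f <= 40.0)
    env = np.sqrt(sxx[band])                      # magnitude envelopes per band
    env = env - env.mean(axis=1, keepdims=True)
    if env.shape[1] < 4:
        return 0.0
    frame_rate = 1.0 / (t[1] - t[0])
    mod = np.abs(np.fft.rfft(env, axis=1)) ** 2
    mod_f = np.fft.rfftfreq(env.shape[1], d=1.0 / frame_rate)
    mod_power = mod.mean(axis=0)

    if heart_rate_hz is None:
        # fall back to the strongest modulation peak in a plausible HR range
        cand = (mod_f >= 0.5) & (mod_f <= 3.0)
        if not cand.any() or mod_power[cand].max() <= 0:
            return 0.0
        heart_rate_hz = float(mod_f[cand][np.argmax(mod_power[cand])])

    tol = 0.3125
    nyq = mod_f[-1]
    harmonic = np.zeros_like(mod_f, dtype=bool)
    for k in range(1, 5):
        f0 = k * heart_rate_hz
        if f0 - tol > nyq:
            break
        harmonic |= np.abs(mod_f - f0) <= tol
    scope = (mod_f > 0) & (mod_f <= min(8.0, nyq))
    num = float(mod_power[harmonic & scope].sum())
    den = float(mod_power[scope & ~harmonic].sum())
    if den <= 0:
        return 0.0
    return num / den


# ---------------------------------------------------------------------------
# Full extraction


def extract_features(
    block: np.ndarray,
    fs: float,
    config: PreprocessConfig | None = None,
) -> FeatureVector:
    """Run the conditioning chain and assemble x1..x16 for one raw block.

    Deterministic; raises :class:`DegenerateBlockError` on flatline blocks so
    the caller can exclude them (T4-like segments).
    """
    pre = preprocess_block(block, fs, config)
    if pre.degenerate:
        raise DegenerateBlockError("flatline block")
    r_peaks = detect_r_peaks(pre.normalized, fs)
    x1 = r_wave_detection_accuracy(pre.normalized, fs)
    rr = median_rr(r_peaks)
    rr_fallback = rr is None or not (0 < rr < pre.normalized.size / fs)
    if rr_fallback:
        rr = 60.0 / DEFAULT_HR_BPM
    x2 = periodicity_rho(pre.normalized, fs, rr)
    x5, x6, x7, x8, x11 = statistical_features(pre.filtered)
    x3, x4, x9, x14 = qrs_time_domain_features(pre, r_peaks)
    x10, x12, x13, x15 = spectral_features(pre.filtered, fs, pre_correction=pre.raw)
    x16 = ms_qi(pre.normalized, fs, heart_rate_hz=1.0 / rr)
    return FeatureVector(
        x1=x1, x2=x2, x3=x3, x4=x4, x5=x5, x6=x6, x7=x7, x8=x8, x9=x9,
        x10=x10, x11=x11, x12=x12, x13=x13, x14=x14, x15=x15, x16=x16,
        rr_fallback=rr_fallback,
    )


# ---------------------------------------------------------------------------
# Separability screening


def feature_separability_screen(
    X: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> list[dict]:
    """Per-feature two-class screening.

    For each column: a chi-square goodness-of-fit test against a fitted
    normal decides normality; non-normal features get a Wilcoxon-Mann-Whitney
    U-test on class medians, normal ones a two-sample t-test on class means.
    Constant columns are reported as untestable.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}")
    out = []
    for j in range(X.shape[1]):
        col = X[:, j]
        name = f"x{j + 1}"
        if np.ptp(col) == 0:
            out.append(
                {"feature": name, "test": "untestable", "normal": None,
                 "p_value": None, "significant": False}
            )
            continue
        normal = _chi2_normality(col, alpha)
        a = col[y == classes[0]]
        b = col[y == classes[1]]
        if normal:
            p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            test = "t"
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
            test = "wmw"
        out.append(
            {"feature": name, "test": test, "normal": normal,
             "p_value": p, "significant": p < alpha}
        )
    return out


def _chi2_normality(x: np.ndarray, alpha: float, n_bins: int = 10) -> bool:
    """Chi-square goodness-of-fit of ``x`` against N(mean, std).

    Bins are equal-probability under the fitted normal; dof = bins - 1 - 2
    (two estimated parameters).  Returns True when normality is *not*
    rejected at ``alpha``.
    """
    x = np.asarray(x, float)
    mu, sd = x.mean(), x.std(ddof=1)
    if sd == 0:
        return False
    edges = stats.norm.ppf(np.linspace(0, 1, n_bins + 1)[1:-1], loc=mu, scale=sd)
    observed = np.histogram(x, bins=np.concatenate(([-np.inf], edges, [np.inf])))[0]
    expected = np.full(n_bins, x.size / n_bins)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    dof = n_bins - 1 - 2
    p = float(stats.chi2.sf(chi2, dof))
    return p >= alpha
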