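"""Fixed registry of 102 multi-domain features for 1-D PuPG signals.

Nine families, concatenated in a fixed, versioned order:

====================  =====  ==========================================
family                count  content
====================  =====  ==========================================
time domain              19  moments, crest/shape/impulse/margin factors,
                             energies, Shannon/log energy, jitter, ...
spectral                 17  spectral moments and descriptors, mean/median
                             frequency, SFDR, SINAD, THD
cepstral                  8  MFCC 1-4 and GFCC 1-4 (frame-averaged)
chroma                   12  12 pitch-class magnitudes (A440 reference)
sEMG-style               13  EMAV, EWL, WL, SSC, AAC, DASDV, log detector,
                             MMAV, MMAV2, myopulse rate, SSI, WAMP, MFL
moment descriptors        6  root-squared moments m0/m2/m4 (ln-scaled),
                             sparseness, irregularity, waveform-length ratio
Hjorth                    2  complexity, mobility
fractal / chaos           5  Higuchi FD, Katz FD, largest Lyapunov exponent,
                             approximate entropy, correlation dimension
LTP texture              20  upper+lower uniform-pattern histograms of the
                             1-D local ternary pattern
====================  =====  ==========================================

All features are deterministic.  Degenerate inputs (constant signals,
vanishing derivatives) produce a 0.0 sentinel with a warning instead of
NaN/Inf; ``extract_all`` guarantees a finite 102-vector for any valid
input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.fft import dct
from scipy.signal import decimate, find_peaks

from pupglearn.synth import Signal

__all__ = [
    "FEATURE_REGISTRY",
    "FEATURE_GROUPS",
    "FeatureVector",
    "FeatureParams",
    "time_domain_features",
    "spectral_features",
    "cepstral_features",
    "chroma_features",
    "semg_features",
    "moment_descriptor_features",
    "hjorth_features",
    "fractal_chaos_features",
    "ltp_features",
    "extract_all",
    "matrix_from_vectors",
    "save_feature_matrix",
    "load_feature_matrix",
]

SENTINEL = 0.0


def _ordinal(i: int) -> str:
    if 10 <= i % 100 <= 20:
        suffix = "th"
    else:
        suffix = {1: "st", 2: "nd", 3: "rd"}.get(i % 10, "th")
    return f"{i}{suffix}"


_TIME_NAMES = [
    "Mean", "Standard Deviation", "Skewness", "Kurtosis", "Peak to Peak Value",
    "Root Mean Square", "Crest Factor", "Shape Factor", "Impulse Factor",
    "Margin Factor", "Energy", "Peak to RMS Value", "Root Sum of Squares",
    "Shannon Energy", "Log Energy", "Mean Absolute Deviation",
    "Median Absolute Deviation", "Average Frequency", "Jitter",
]
_SPECTRAL_NAMES = [
    "Spectral Mean", "Spectral Standard Deviation", "Spectral Skewness",
    "Spectral Kurtosis", "Spectral Centroid", "Spectral Flux",
    "Spectral Roll-off", "Spectral Flatness", "Spectral Crest",
    "Spectral Decrease", "Spectral Slope", "Spectral Spread",
    "Mean Frequency", "Median Frequency", "Spurious-free Dynamic Range",
    "Signal to Noise Distortion", "Total Harmonic Distortions",
]
_CEPSTRAL_NAMES = [f"{_ordinal(i)} Coefficient of MFCC" for i in range(1, 5)] + [
    f"{_ordinal(i)} Coefficient of GFCC" for i in range(1, 5)
]
_CHROMA_NAMES = [f"{_ordinal(i)} Coefficient of Chroma Vector" for i in range(1, 13)]
_SEMG_NAMES = [
    "Enhanced Mean Absolute Value", "Enhanced Wavelength", "Wavelength",
    "Slope Sign Change", "Average Amplitude Change",
    "Difference Absolute Std. Dev.", "Log Detector",
    "Modified Mean Absolute Value", "Modified Mean Absolute Value 2",
    "Pulse Percentage Rate", "Simple Square Integral", "Willison Amplitude",
    "Maximum Fractal Length",
]
_MOMENT_NAMES = [
    "Root Squared Zero Order Moment", "Root Squared 2nd Order Moment",
    "Root Squared 4th Order Moment", "Sparseness", "Irregularity Factor",
    "Waveform Length Ratio",
]
_HJORTH_NAMES = ["Complexity", "Mobility"]
_FRACTAL_NAMES = [
    "Higuchi's Fractal Dimension", "Katz Fractal Dimension",
    "Lyapunov Exponent", "Approximate Entropy", "Correlation Dimension",
]
_LTP_NAMES = [f"{_ordinal(i)} Coefficient of LTP" for i in range(1, 21)]

FEATURE_GROUPS: dict[str, list[str]] = {
    "time": _TIME_NAMES,
    "spectral": _SPECTRAL_NAMES,
    "cepstral": _CEPSTRAL_NAMES,
    "chroma": _CHROMA_NAMES,
    "semg": _SEMG_NAMES,
    "moments": _MOMENT_NAMES,
    "hjorth": _HJORTH_NAMES,
    "fractal": _FRACTAL_NAMES,
    "ltp": _LTP_NAMES,
}

FEATURE_REGISTRY: list[str] = [n for names in FEATURE_GROUPS.values() for n in names]
assert len(FEATURE_REGISTRY) == 102 == len(set(FEATURE_REGISTRY))


@dataclass(frozen=True)
class FeatureParams:
    """Tunable constants of the extractor (defaults used throughout)."""

    semg_thresh: float = 0.01  # SSC / WAMP / myopulse amplitude threshold
    ltp_t: float = 0.01  # local-ternary-pattern dead zone
    rolloff_fraction: float = 0.95
    frame: int = 1024
    hop: int = 512
    n_filters: int = 20  # mel and gammatone channels
    n_harmonics: int = 5  # THD harmonics
    hfd_kmax: int = 10
    apen_m: int = 2
    apen_r_factor: float = 0.2
    embed_dim: int = 5  # Lyapunov / correlation-dimension embedding
    chaos_decimate: int = 10  # decimation factor before chaos features
    jitter_min_spacing_s: float = 0.4
    jitter_prominence_factor: float = 0.3


@dataclass
class FeatureVector:
    """102 named feature values for one signal."""

    values: np.ndarray
    signal_id: str = ""
    label: str = "unlabeled"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(FEATURE_REGISTRY):
            raise ValueError(f"expected {len(FEATURE_REGISTRY)} values")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=FEATURE_REGISTRY)


def _resolve(signal, fs: float | None) -> tuple[np.ndarray, float | None]:
    if isinstance(signal, Signal):
        return np.asarray(signal.samples, dtype=float), signal.fs
    return np.asarray(signal, dtype=float), fs


def _sentinel(name: str) -> float:
    warnings.warn(f"feature {name!r} undefined on this input; sentinel 0 used")
    return SENTINEL


# ---------------------------------------------------------------------------
# Time domain
# ---------------------------------------------------------------------------

def time_domain_features(signal, fs: float | None = None,
                         params: FeatureParams = FeatureParams()) -> pd.Series:
    x, fs = _resolve(signal, fs)
    if x.size < 2:
        raise ValueError("time-domain features need >= 2 samples")
    n = x.size
    absx = np.abs(x)
    mean = x.mean()
    std = x.std()
    rms = float(np.sqrt(np.mean(x**2)))
    mean_abs = absx.mean()
    xmax = x.max()

    if std > 0:
        skew = float(sstats.skew(x))
        kurt = float(sstats.kurtosis(x, fisher=False))
    else:
        skew = _sentinel("Skewness")
        kurt = _sentinel("Kurtosis")

    crest = xmax / rms if rms > 0 else _sentinel("Crest Factor")
    shape = rms / mean_abs if mean_abs > 0 else _sentinel("Shape Factor")
    impulse = xmax / mean_abs if mean_abs > 0 else _sentinel("Impulse Factor")
    sqrt_mean = np.mean(np.sqrt(absx)) ** 2
    margin = xmax / sqrt_mean if sqrt_mean > 0 else _sentinel("Margin Factor")
    energy = float(np.sum(x**2))
    peak_to_rms = absx.max() / rms if rms > 0 else _sentinel("Peak to RMS Value")

    x2 = x**2
    nz = x2 > 0
    shannon = float(-np.sum(x2[nz] * np.log(x2[nz])))
    log_energy = float(np.sum(np.log(np.maximum(x2, 1e-24))))

    sgn = np.sign(x)
    sgn = sgn[sgn != 0]
    crossings = int(np.sum(sgn[:-1] * sgn[1:] < 0)) if sgn.size > 1 else 0
    avg_freq = crossings / (n - 1)

    jitter = _jitter_ms(x, fs, params)

    vals = [
        mean, std, skew, kurt, float(x.max() - x.min()), rms, crest, shape,
        impulse, margin, energy, peak_to_rms, float(np.sqrt(energy)), shannon,
        log_energy, float(np.mean(np.abs(x - mean))),
        float(np.median(np.abs(x - np.median(x)))), avg_freq, jitter,
    ]
    return pd.Series(vals, index=_TIME_NAMES, dtype=float)


def _jitter_ms(x: np.ndarray, fs: float | None, params: FeatureParams) -> float:
    """Mean absolute successive difference of inter-peak intervals, in ms."""
    if fs is None or x.std() == 0:
        return _sentinel("Jitter")
    peaks, _ = find_peaks(
        x,
        distance=max(1, int(round(params.jitter_min_spacing_s * fs))),
        prominence=params.jitter_prominence_factor * x.std(),
    )
    if peaks.size < 3:
        return _sentinel("Jitter")
    ipi_ms = np.diff(peaks) / fs * 1000.0
    return float(np.mean(np.abs(np.diff(ipi_ms))))


# ---------------------------------------------------------------------------
# Spectral
# ---------------------------------------------------------------------------

def _frame_view(x: np.ndarray, frame: int, hop: int) -> np.ndarray:
    n_frames = 1 + (x.size - frame) // hop if x.size >= frame else 0
    if n_frames < 1:
        return np.empty((0, frame))
    idx = np.arange(frame)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def spectral_features(signal, fs: float | None = None,
                      params: FeatureParams = FeatureParams()) -> pd.Series:
    x, fs = _resolve(signal, fs)
    if fs is None:
        raise ValueError("spectral features require a sampling rate")
    if x.size < 64:
        raise ValueError("spectral features need >= 64 samples")
    if not np.any(x):
        raise ValueError("all-zero signal: spectrum undefined")

    mag = np.abs(np.fft.rfft(x))
    power = mag**2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)

    s_mean = float(mag.mean())
    s_std = float(mag.std())
    s_skew = float(sstats.skew(mag)) if s_std > 0 else _sentinel("Spectral Skewness")
    s_kurt = (
        float(sstats.kurtosis(mag, fisher=False))
        if s_std > 0 else _sentinel("Spectral Kurtosis")
    )

    wsum = mag.sum()
    centroid = float((freqs * mag).sum() / wsum)
    spread = float(np.sqrt(((freqs - centroid) ** 2 * mag).sum() / wsum))

    flux = _spectral_flux(x, fs)

    cum = np.cumsum(power)
    rolloff = float(freqs[np.searchsorted(cum, params.rolloff_fraction * cum[-1])])

    p_safe = power + 1e-30
    flatness = float(np.exp(np.mean(np.log(p_safe))) / np.mean(p_safe))
    s_crest = float(mag.max() / mag.sum())

    k = np.arange(1, mag.size)
    decrease = float(np.sum((mag[1:] - mag[0]) / k) / np.sum(mag[1:]))
    slope = float(np.polyfit(freqs, mag, 1)[0])

    psum = power.sum()
    mean_freq = float((freqs * power).sum() / psum)
    cump = np.cumsum(power)
    median_freq = float(freqs[np.searchsorted(cump, 0.5 * cump[-1])])

    sfdr, sinad, thd = _harmonic_metrics(mag, params.n_harmonics)

    vals = [
        s_mean, s_std, s_skew, s_kurt, centroid, flux, rolloff, flatness,
        s_crest, decrease, slope, spread, mean_freq, median_freq, sfdr,
        sinad, thd,
    ]
    return pd.Series(vals, index=_SPECTRAL_NAMES, dtype=float)


def _spectral_flux(x: np.ndarray, fs: float) -> float:
    """Mean L2 change between unit-normalized 1 s frame spectra (0.5 s hop)."""
    frame = int(round(fs))
    hop = max(1, frame // 2)
    frames = _frame_view(x, frame, hop)
    if frames.shape[0] < 2:
        return _sentinel("Spectral Flux")
    spec = np.abs(np.fft.rfft(frames, axis=1))
    norms = np.linalg.norm(spec, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    spec = spec / norms
    return float(np.mean(np.linalg.norm(np.diff(spec, axis=0), axis=1)))


def _harmonic_metrics(mag: np.ndarray, n_harmonics: int) -> tuple[float, float, float]:
    """SFDR, SINAD and THD (all dB) around the largest nonzero-frequency peak."""
    if mag.size < 4:
        return (_sentinel("Spurious-free Dynamic Range"),
                _sentinel("Signal to Noise Distortion"),
                _sentinel("Total Harmonic Distortions"))
    k0 = 1 + int(np.argmax(mag[1:]))
    guard = 2

    def band_power(center: int) -> float:
        lo = max(1, center - guard)
        hi = min(mag.size, center + guard + 1)
        return float(np.sum(mag[lo:hi] ** 2))

    p_fund = band_power(k0)

    spur = mag.copy()
    spur[:1] = 0.0
    spur[max(0, k0 - guard):k0 + guard + 1] = 0.0
    max_spur = spur.max()
    sfdr = (
        20 * np.log10(mag[k0] / max_spur)
        if max_spur > 0 else _sentinel("Spurious-free Dynamic Range")
    )

    p_total = float(np.sum(mag[1:] ** 2))
    p_rest = max(p_total - p_fund, 0.0)
    sinad = (
        10 * np.log10(p_fund / p_rest)
        if p_rest > 0 else _sentinel("Signal to Noise Distortion")
    )

    p_harm = 0.0
    for h in range(2, 2 + n_harmonics):
        kh = h * k0
        if kh >= mag.size - guard:
            break
        lo = kh - guard
        hi = kh + guard + 1
        p_harm += float(np.max(mag[lo:hi]) ** 2)
    thd = (
        10 * np.log10(p_harm / p_fund)
        if p_harm > 0 and p_fund > 0 else _sentinel("Total Harmonic Distortions")
    )
    return float(sfdr), float(sinad), float(thd)


# ---------------------------------------------------------------------------
# Cepstral (MFCC + GFCC) and chroma
# ---------------------------------------------------------------------------

def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int, n_fft: int, fs: float) -> np.ndarray:
    """Triangular mel filterbank (n_filters x n_fft//2+1), 0..fs/2 span."""
    edges_mel = np.linspace(_hz_to_mel(0.0), _hz_to_mel(fs / 2.0), n_filters + 2)
    edges_hz = _mel_to_hz(edges_mel)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    bank = np.zeros((n_filters, freqs.size))
    for i in range(n_filters):
        lo, ctr, hi = edges_hz[i], edges_hz[i + 1], edges_hz[i + 2]
        up = (freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - freqs) / max(hi - ctr, 1e-12)
        bank[i] = np.clip(np.minimum(up, down), 0.0, None)
    return bank


def _hz_to_erb(f):
    return 21.4 * np.log10(1.0 + 0.00437 * np.asarray(f))


def _erb_to_hz(e):
    return (10.0 ** (np.asarray(e) / 21.4) - 1.0) / 0.00437


def gammatone_filterbank(n_filters: int, n_fft: int, fs: float,
                         fmin: float = 10.0) -> np.ndarray:
    """Spectral-domain 4th-order gammatone magnitude weights, ERB-spaced."""
    centers = _erb_to_hz(np.linspace(_hz_to_erb(fmin), _hz_to_erb(fs / 2.0), n_filters))
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    bank = np.zeros((n_filters, freqs.size))
    for i, fc in enumerate(centers):
        b = 1.019 * 24.7 * (4.37 * fc / 1000.0 + 1.0)
        bank[i] = (1.0 + ((freqs - fc) / b) ** 2) ** -2.0
    return bank


def _framed_power_spectra(x: np.ndarray, params: FeatureParams) -> np.ndarray:
    frames = _frame_view(x, params.frame, params.hop)
    if frames.shape[0] == 0:
        raise ValueError(f"signal shorter than one frame ({params.frame} samples)")
    window = np.hanning(params.frame)
    return np.abs(np.fft.rfft(frames * window, axis=1)) ** 2


def cepstral_features(signal, fs: float | None = None,
                      params: FeatureParams = FeatureParams()) -> pd.Series:
    """Frame-averaged MFCC 1-4 (log-mel + DCT) and GFCC 1-4 (cubic-root
    gammatone + DCT)."""
    x, fs = _resolve(signal, fs)
    if fs is None:
        raise ValueError("cepstral features require a sampling rate")
    spectra = _framed_power_spectra(x, params)

    mel = mel_filterbank(params.n_filters, params.frame, fs)
    mel_energy = spectra @ mel.T
    mfcc = dct(np.log(np.maximum(mel_energy, 1e-24)), type=2, norm="ortho", axis=1)
    mfcc4 = mfcc[:, :4].mean(axis=0)

    gt = gammatone_filterbank(params.n_filters, params.frame, fs)
    gt_energy = spectra @ gt.T
    gfcc = dct(np.cbrt(np.maximum(gt_energy, 0.0)), type=2, norm="ortho", axis=1)
    gfcc4 = gfcc[:, :4].mean(axis=0)

    return pd.Series(np.concatenate([mfcc4, gfcc4]), index=_CEPSTRAL_NAMES)


def chroma_features(signal, fs: float | None = None,
                    params: FeatureParams = FeatureParams()) -> pd.Series:
    """Unnormalized 12-bin pitch-class magnitude profile (A440 = class 1)."""
    x, fs = _resolve(signal, fs)
    if fs is None:
        raise ValueError("chroma features require a sampling rate")
    frames = _frame_view(x, params.frame, params.hop)
    if frames.shape[0] == 0:
        raise ValueError(f"signal shorter than one frame ({params.frame} samples)")
    window = np.hanning(params.frame)
    mags = np.abs(np.fft.rfft(frames * window, axis=1))
    freqs = np.fft.rfftfreq(params.frame, d=1.0 / fs)
    valid = freqs > 0
    pitch_class = np.mod(
        np.round(12.0 * np.log2(freqs[valid] / 440.0)).astype(int), 12
    )
    chroma = np.zeros((mags.shape[0], 12))
    for c in range(12):
        sel = pitch_class == c
        if np.any(sel):
            chroma[:, c] = mags[:, valid][:, sel].sum(axis=1)
    return pd.Series(chroma.mean(axis=0), index=_CHROMA_NAMES)


# ---------------------------------------------------------------------------
# sEMG-style
# ---------------------------------------------------------------------------

def semg_features(signal, fs: float | None = None,
                  params: FeatureParams = FeatureParams()) -> pd.Series:
    x, fs = _resolve(signal, fs)
    if x.size < 3:
        raise ValueError("sEMG features need >= 3 samples")
    thresh = params.semg_thresh
    n = x.size
    absx = np.abs(x)
    dx = np.diff(x)
    absdx = np.abs(dx)

    # enhanced variants: exponent 0.75 in the central 60% window, 0.5 outside
    i = np.arange(n)
    p = np.where((i >= 0.2 * n) & (i < 0.8 * n), 0.75, 0.5)
    emav = float(np.mean(absx**p))
    i_d = np.arange(dx.size)
    p_d = np.where((i_d >= 0.2 * dx.size) & (i_d < 0.8 * dx.size), 0.75, 0.5)
    ewl = float(np.sum(absdx**p_d))

    wl = float(absdx.sum())
    ssc = int(np.sum((x[1:-1] - x[:-2]) * (x[1:-1] - x[2:]) > thresh**2))
    aac = wl / (n - 1)
    dasdv = float(np.sqrt(np.sum(dx**2) / (n - 1)))
    log_det = float(np.exp(np.mean(np.log(np.maximum(absx, 1e-12)))))

    w1 = np.where((i >= 0.25 * n) & (i < 0.75 * n), 1.0, 0.5)
    mmav = float(np.mean(w1 * absx))
    w2 = np.ones(n)
    lo = i < 0.25 * n
    hi = i >= 0.75 * n
    w2[lo] = 4.0 * i[lo] / n
    w2[hi] = 4.0 * (n - i[hi]) / n
    mmav2 = float(np.mean(w2 * absx))

    ppr = float(np.mean(absx > thresh))
    ssi = float(np.sum(x**2))
    wamp = int(np.sum(absdx > thresh))
    sum_dx2 = float(np.sum(dx**2))
    mfl = (
        float(np.log(np.sqrt(sum_dx2)))
        if sum_dx2 > 0 else _sentinel("Maximum Fractal Length")
    )

    vals = [emav, ewl, wl, ssc, aac, dasdv, log_det, mmav, mmav2, ppr, ssi,
            wamp, mfl]
    return pd.Series(vals, index=_SEMG_NAMES, dtype=float)


# ---------------------------------------------------------------------------
# Moment descriptors
# ---------------------------------------------------------------------------

def moment_descriptor_features(signal, fs: float | None = None,
                               params: FeatureParams = FeatureParams()) -> pd.Series:
    x, fs = _resolve(signal, fs)
    if x.size < 5:
        raise ValueError("moment descriptors need >= 5 samples")
    d1 = np.diff(x)
    d2 = np.diff(x, n=2)
    m0 = float(np.sqrt(np.sum(x**2)))
    m2 = float(np.sqrt(np.sum(d1**2)))
    m4 = float(np.sqrt(np.sum(d2**2)))

    def safe_log(v: float, name: str) -> float:
        return float(np.log(v)) if v > 0 else _sentinel(name)

    f_m0 = safe_log(m0, _MOMENT_NAMES[0])
    f_m2 = safe_log(m2, _MOMENT_NAMES[1])
    f_m4 = safe_log(m4, _MOMENT_NAMES[2])

    prod = (m0 - m2) * (m0 - m4)
    sparseness = (
        float(np.log(m0 / np.sqrt(prod))) if prod > 0 and m0 > 0
        else _sentinel("Sparseness")
    )
    irregularity = (
        float(np.log(m2 / np.sqrt(m0 * m4))) if m0 > 0 and m2 > 0 and m4 > 0
        else _sentinel("Irregularity Factor")
    )
    sum_d2 = float(np.sum(np.abs(d2)))
    sum_d1 = float(np.sum(np.abs(d1)))
    wlr = (
        float(np.log(sum_d1 / sum_d2)) if sum_d1 > 0 and sum_d2 > 0
        else _sentinel("Waveform Length Ratio")
    )

    vals = [f_m0, f_m2, f_m4, sparseness, irregularity, wlr]
    return pd.Series(vals, index=_MOMENT_NAMES, dtype=float)


# ---------------------------------------------------------------------------
# Hjorth
# ---------------------------------------------------------------------------

def _mobility(x: np.ndarray) -> float:
    v = np.var(x)
    if v == 0:
        raise ValueError("Hjorth parameters undefined for zero-variance input")
    return float(np.sqrt(np.var(np.diff(x)) / v))


def hjorth_features(signal, fs: float | None = None,
                    params: FeatureParams = FeatureParams()) -> pd.Series:
    """Hjorth mobility and complexity (registry order: complexity first)."""
    x, fs = _resolve(signal, fs)
    if x.size < 3:
        raise ValueError("Hjorth parameters need >= 3 samples")
    mob = _mobility(x)
    comp = _mobility(np.diff(x)) / mob
    return pd.Series([comp, mob], index=_HJORTH_NAMES, dtype=float)


# ---------------------------------------------------------------------------
# Fractal / chaos
# ---------------------------------------------------------------------------

def higuchi_fd(x: np.ndarray, kmax: int = 10) -> float:
    """Higuchi fractal dimension (slope of log mean curve length vs log 1/k)."""
    n = x.size
    lengths = []
    ks = np.arange(1, kmax + 1)
    for k in ks:
        lk = 0.0
        for m in range(k):
            seg = x[m::k]
            if seg.size < 2:
                continue
            norm = (n - 1) / (seg.size - 1) / k
            lk += np.sum(np.abs(np.diff(seg))) * norm / k
        lengths.append(lk / k if lk > 0 else np.nan)
    lengths = np.asarray(lengths)
    ok = np.isfinite(lengths) & (lengths > 0)
    if ok.sum() < 2:
        return _sentinel("Higuchi's Fractal Dimension")
    slope = np.polyfit(np.log(1.0 / ks[ok]), np.log(lengths[ok]), 1)[0]
    return float(slope)


def katz_fd(x: np.ndarray) -> float:
    """Katz fractal dimension of the waveform treated as a planar curve."""
    n = x.size - 1
    dy = np.diff(x)
    length = float(np.sum(np.sqrt(1.0 + dy**2)))
    d = float(np.max(np.sqrt(np.arange(x.size) ** 2 + (x - x[0]) ** 2)))
    if length <= 0 or d <= 0:
        return _sentinel("Katz Fractal Dimension")
    return float(np.log10(n) / (np.log10(n) + np.log10(d / length)))


def _autocorr_zero_delay(x: np.ndarray, max_lag: int | None = None) -> int:
    """First zero crossing of the autocorrelation; embedding delay."""
    x = x - x.mean()
    n = x.size
    max_lag = max_lag or n // 2
    ac = np.correlate(x, x, mode="full")[n - 1:n - 1 + max_lag]
    below = np.nonzero(ac <= 0)[0]
    return int(below[0]) if below.size else max(1, max_lag // 4)


def _embed(x: np.ndarray, dim: int, delay: int) -> np.ndarray:
    m = x.size - (dim - 1) * delay
    if m < 2:
        raise ValueError("signal too short for the requested embedding")
    return np.column_stack([x[i * delay:i * delay + m] for i in range(dim)])


def lyapunov_rosenstein(x: np.ndarray, fs: float, dim: int = 5,
                        fit_window_s: float = 1.0) -> float:
    """Largest Lyapunov exponent (per second) via nearest-neighbour divergence.

    Embedding delay = first autocorrelation zero crossing; temporal
    neighbours within one delay-window are excluded when picking each
    point's nearest neighbour; the exponent is the least-squares slope of
    the mean log-divergence over ``fit_window_s`` seconds.
    """
    delay = _autocorr_zero_delay(x)
    emb = _embed(x, dim, delay)
    m = emb.shape[0]
    theiler = (dim - 1) * delay
    d2 = np.sum((emb[:, None, :] - emb[None, :, :]) ** 2, axis=2)
    idx = np.arange(m)
    mask = np.abs(idx[:, None] - idx[None, :]) <= theiler
    d2[mask] = np.inf
    nn = np.argmin(d2, axis=1)

    k_max = min(int(round(fit_window_s * fs)), m // 2)
    if k_max < 2:
        return _sentinel("Lyapunov Exponent")
    log_div = np.full(k_max, np.nan)
    for k in range(k_max):
        valid = (idx + k < m) & (nn + k < m)
        if valid.sum() < 10:
            break
        dist = np.linalg.norm(emb[idx[valid] + k] - emb[nn[valid] + k], axis=1)
        dist = dist[dist > 0]
        if dist.size < 10:
            continue
        log_div[k] = np.mean(np.log(dist))
    ok = np.isfinite(log_div)
    if ok.sum() < 2:
        return _sentinel("Lyapunov Exponent")
    t = np.arange(k_max)[ok] / fs
    slope = np.polyfit(t, log_div[ok], 1)[0]
    return float(slope)


def approximate_entropy(x: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """ApEn(m, r = r_factor * std) with Chebyshev distance."""
    r = r_factor * x.std()
    if r == 0:
        return _sentinel("Approximate Entropy")

    def phi(mm: int) -> float:
        emb = _embed(x, mm, 1)
        # Chebyshev distance matrix
        d = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=2)
        c = np.mean(d <= r, axis=1)
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def correlation_dimension(x: np.ndarray, dim: int = 5) -> float:
    """Grassberger-Procaccia correlation dimension.

    Embedding delay from the autocorrelation zero crossing; slope of
    log C(r) vs log r over the middle decade of inter-point distances.
    """
    delay = _autocorr_zero_delay(x)
    emb = _embed(x, dim, delay)
    m = emb.shape[0]
    d2 = np.sum((emb[:, None, :] - emb[None, :, :]) ** 2, axis=2)
    iu = np.triu_indices(m, k=1)
    dists = np.sqrt(d2[iu])
    dists = dists[dists > 0]
    if dists.size < 100:
        return _sentinel("Correlation Dimension")
    lo, hi = np.percentile(dists, [5, 70])
    if lo <= 0 or hi <= lo:
        return _sentinel("Correlation Dimension")
    radii = np.geomspace(lo, hi, 12)
    c = np.array([np.mean(dists <= r) for r in radii])
    ok = c > 0
    if ok.sum() < 2:
        return _sentinel("Correlation Dimension")
    slope = np.polyfit(np.log(radii[ok]), np.log(c[ok]), 1)[0]
    return float(slope)


def fractal_chaos_features(signal, fs: float | None = None,
                           params: FeatureParams = FeatureParams()) -> pd.Series:
    """Higuchi/Katz fractal dimensions plus chaos descriptors.

    Higuchi and Katz run on the full signal.  The pairwise-distance based
    descriptors (Lyapunov, ApEn, correlation dimension) run on a
    ``chaos_decimate``-fold decimated copy to keep the O(N^2) pair counts
    tractable at 10 s / 1 kHz records.
    """
    x, fs = _resolve(signal, fs)
    if x.size < 100:
        raise ValueError("fractal/chaos features need >= 100 samples")
    if fs is None:
        raise ValueError("fractal/chaos features require a sampling rate")

    hfd = higuchi_fd(x, params.hfd_kmax)
    kfd = katz_fd(x)

    q = params.chaos_decimate
    if q > 1 and x.size // q >= 100:
        xd = decimate(x, q, zero_phase=True)
        fs_d = fs / q
    else:
        xd, fs_d = x, fs
    if xd.std() == 0:
        lya = _sentinel("Lyapunov Exponent")
        apen = _sentinel("Approximate Entropy")
        cdim = _sentinel("Correlation Dimension")
    else:
        lya = lyapunov_rosenstein(xd, fs_d, params.embed_dim)
        apen = approximate_entropy(xd, params.apen_m, params.apen_r_factor)
        cdim = correlation_dimension(xd, params.embed_dim)
    return pd.Series([hfd, kfd, lya, apen, cdim], index=_FRACTAL_NAMES, dtype=float)


# ---------------------------------------------------------------------------
# Local ternary patterns
# ---------------------------------------------------------------------------

def _uniform_class(bits: np.ndarray) -> np.ndarray:
    """Map 8-bit patterns (rows) to 10 rotation-invariant uniform classes.

    Patterns with at most 2 circular 0/1 transitions map to their number of
    set bits (classes 0..8); all others share the non-uniform class 9.
    """
    transitions = np.sum(bits != np.roll(bits, 1, axis=1), axis=1)
    ones = bits.sum(axis=1)
    return np.where(transitions <= 2, ones, 9)


def ltp_features(signal, fs: float | None = None,
                 params: FeatureParams = FeatureParams()) -> pd.Series:
    """1-D local ternary pattern histograms (upper 10 bins + lower 10 bins).

    Each sample is compared with its 8 neighbours (4 per side) against a
    dead zone of +-t around the centre value; the resulting upper and lower
    binary patterns are binned into 10-class uniform-pattern histograms of
    raw counts (each histogram sums to N - 8).
    """
    x, fs = _resolve(signal, fs)
    if x.size < 9:
        raise ValueError("LTP features need >= 9 samples")
    t = params.ltp_t
    center = x[4:-4]
    shifts = [-4, -3, -2, -1, 1, 2, 3, 4]
    neigh = np.column_stack([x[4 + s: x.size - 4 + s] for s in shifts])
    upper = neigh > (center[:, None] + t)
    lower = neigh < (center[:, None] - t)

    hist = []
    for bits in (upper, lower):
        classes = _uniform_class(bits)
        hist.append(np.bincount(classes, minlength=10)[:10])
    return pd.Series(np.concatenate(hist).astype(float), index=_LTP_NAMES)


# ---------------------------------------------------------------------------
# Full vector
# ---------------------------------------------------------------------------

_FAMILY_FUNCS = {
    "time": time_domain_features,
    "spectral": spectral_features,
    "cepstral": cepstral_features,
    "chroma": chroma_features,
    "semg": semg_features,
    "moments": moment_descriptor_features,
    "hjorth": hjorth_features,
    "fractal": fractal_chaos_features,
    "ltp": ltp_features,
}


def extract_all(signal, fs: float | None = None,
                params: FeatureParams = FeatureParams()) -> FeatureVector:
    """Compute the full 102-feature vector in registry order.

    Family-level failures on degenerate inputs (e.g. zero-variance Hjorth
    parameters) are replaced by the 0.0 sentinel with a warning; the
    result is always finite.
    """
    x, fs = _resolve(signal, fs)
    sig_id = signal.id if isinstance(signal, Signal) else ""
    label = signal.label if isinstance(signal, Signal) else "unlabeled"

    pieces = []
    for group, func in _FAMILY_FUNCS.items():
        names = FEATURE_GROUPS[group]
        try:
            vals = func(x, fs=fs, params=params).to_numpy()
        except ValueError as exc:
            warnings.warn(f"feature family {group!r} degenerate ({exc}); sentinels used")
            vals = np.full(len(names), SENTINEL)
        pieces.append(vals)
    values = np.concatenate(pieces)
    bad = ~np.isfinite(values)
    if np.any(bad):
        for name in np.asarray(FEATURE_REGISTRY)[bad]:
            warnings.warn(f"feature {name!r} non-finite; sentinel 0 substituted")
        values[bad] = SENTINEL
    return FeatureVector(values=values, signal_id=sig_id, label=label)


def matrix_from_vectors(vectors: list[FeatureVector]) -> pd.DataFrame:
    """Stack feature vectors into an N x 102 table with id/label columns."""
    df = pd.DataFrame(
        [v.values for v in vectors], columns=FEATURE_REGISTRY
    )
    df.insert(0, "id", [v.signal_id for v in vectors])
    df.insert(1, "label", [v.label for v in vectors])
    return df


def save_feature_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def load_feature_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("id", "label", *FEATURE_REGISTRY) if c not in df.columns]
    if missing:
        raise IOError(f"feature matrix lacks columns: {missing[:3]}...")
    return df
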