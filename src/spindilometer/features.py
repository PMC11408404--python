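"""Per-frame feature families: PSD band powers, CWT scalogram summaries,
a Gaussian-deviation score from normal probability plots (NGS), and a
bispectrum diagonal-slice band ratio (BGS).

All features are computed on a single 10-s, single-channel frame after mean
removal, so every feature is invariant to a constant offset.  A sleep
spindle raises sigma-band (11-16 Hz) power and sigma-scale wavelet energy,
deviates the amplitude distribution from the Gaussian background, and --
being an amplitude-modulated burst -- leaves a quadratic-phase-coupling
signature on the bispectrum diagonal.

The production PSD estimator is Welch (2-s Hann windows, 50% overlap); the
raw periodogram and the autocorrelation route (the Fourier transform of the
biased autocorrelation sequence, identical to the periodogram by the
Wiener-Khinchin theorem) are kept for exactness checks and for callers that
need an unsmoothed spectrum.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps
from scipy.stats import norm

__all__ = [
    "Spectrum",
    "Scalogram",
    "BispectrumSlice",
    "FeatureConfig",
    "FEATURE_NAMES",
    "BANDS",
    "autocorrelation",
    "power_spectral_density",
    "band_power",
    "relative_band_power",
    "peak_frequency",
    "cwt",
    "cwt_features",
    "ngs",
    "bispectrum_diagonal",
    "bgs",
    "assemble_features",
]

#: Canonical EEG band edges in Hz (half-open [lo, hi) integration).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 11.0),
    "sigma": (11.0, 16.0),
    "beta": (16.0, 30.0),
}

FEATURE_NAMES: tuple[str, ...] = (
    "psd_delta", "psd_theta", "psd_alpha", "psd_sigma", "psd_beta",
    "psd_rel_sigma", "psd_peak_hz",
    "cwt_sigma_mean", "cwt_sigma_max", "cwt_sigma_energy",
    "ngs", "bgs",
)

#: Complex Morlet with omega0 = 6: gaussian variance B = 2, center
#: frequency C = 6 / (2 pi) cycles per unit.
MORLET6 = "cmor2.0-0.9549296585513721"


@dataclass
class Spectrum:
    """One-sided power spectral density on a uniform frequency grid."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class Scalogram:
    """CWT coefficients: rows = scales (with Hz equivalents), cols = shifts."""

    scales: np.ndarray
    freqs_hz: np.ndarray
    shifts: np.ndarray
    coeffs: np.ndarray


@dataclass
class BispectrumSlice:
    """Diagonal slice magnitude P(w) = |B(w, w)| of the bispectrum."""

    freqs: np.ndarray
    P: np.ndarray


@dataclass
class FeatureConfig:
    """Knobs of the per-frame feature extractor."""

    psd_method: str = "welch"
    welch_window_s: float = 2.0
    sigma_band: tuple[float, float] = BANDS["sigma"]
    total_band: tuple[float, float] = (0.5, 30.0)
    peak_band: tuple[float, float] = (9.0, 18.0)
    wavelet: str = MORLET6
    n_scales: int = 32
    scale_band: tuple[float, float] = (2.0, 30.0)
    bgs_numerator: tuple[float, float] = BANDS["sigma"]
    bgs_denominator: tuple[float, float] = (0.5, 30.0)
    n_blocks: int = 8


def autocorrelation(x: np.ndarray) -> np.ndarray:
    """Biased autocorrelation A(xi) = (1/N) sum x_t x_{t+xi} of mean-removed x.

    Returned for lags 0..N-1; A(0) is the population-style sample variance.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("input must be finite")
    n = x.size
    xd = x - x.mean()
    # linear (not circular) correlation via zero-padded FFT
    nfft = 1 << int(np.ceil(np.log2(2 * n - 1)))
    spec = np.fft.rfft(xd, nfft)
    acf = np.fft.irfft(spec * np.conj(spec), nfft)[:n]
    return acf / n


def power_spectral_density(
    x: np.ndarray, fs: float, method: str = "welch", window_s: float = 2.0
) -> Spectrum:
    """One-sided PSD of a frame, in signal-units^2 per Hz.

    ``method``:

    - ``"welch"`` -- Welch average of Hann-windowed ``window_s``-second
      blocks with 50% overlap (default production estimator);
    - ``"periodogram"`` -- raw rectangular periodogram |DFT(x)|^2 / (N fs);
    - ``"acf"`` -- discrete Fourier transform of the biased autocorrelation
      sequence, bin-for-bin identical to the periodogram (Wiener-Khinchin).
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    x = np.asarray(x, dtype=float)
    if x.size < 16:
        raise ValueError("need at least 16 samples for a PSD")
    if method == "welch":
        nperseg = min(x.size, int(round(window_s * fs)))
        freqs, power = sps.welch(
            x, fs=fs, window="hann", nperseg=nperseg,
            noverlap=nperseg // 2, detrend="constant",
        )
    elif method == "periodogram":
        freqs, power = sps.periodogram(
            x, fs=fs, window="boxcar", detrend="constant"
        )
    elif method == "acf":
        n = x.size
        a = autocorrelation(x)
        # two-sided spectrum at the N-point DFT grid from symmetric ACF:
        # Phi_k = A(0) + 2 sum_{xi>=1} A(xi) cos(2 pi k xi / N)
        full = np.fft.fft(a)
        phi = (2.0 * np.real(full) - a[0]) / fs
        k = np.arange(n // 2 + 1)
        power = phi[k].copy()
        # one-sided doubling of interior bins, as for the periodogram
        last = n // 2 if n % 2 == 0 else n // 2 + 1
        power[1:last] *= 2.0
        power = np.clip(power, 0.0, None)
        freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    else:
        raise ValueError(f"unknown PSD method {method!r}")
    return Spectrum(freqs=freqs, power=np.asarray(power, dtype=float))


def band_power(spectrum: Spectrum, lo_hz: float, hi_hz: float) -> float:
    """Rectangular integral of the PSD over the half-open band [lo, hi)."""
    if lo_hz >= hi_hz:
        raise ValueError("band must satisfy lo < hi")
    mask = (spectrum.freqs >= lo_hz) & (spectrum.freqs < hi_hz)
    if not mask.any():
        raise ValueError(
            f"band [{lo_hz}, {hi_hz}) Hz contains no bins of the grid "
            f"[{spectrum.freqs[0]}, {spectrum.freqs[-1]}] Hz"
        )
    return float(spectrum.power[mask].sum() * spectrum.df)


def relative_band_power(
    spectrum: Spectrum,
    lo_hz: float,
    hi_hz: float,
    total: tuple[float, float] = (0.5, 30.0),
) -> float:
    """Band power as a fraction of the total (default 0.5-30 Hz) power."""
    tot = band_power(spectrum, *total)
    if tot <= 0:
        raise ValueError("total band power is zero; relative power undefined")
    return min(1.0, band_power(spectrum, lo_hz, hi_hz) / tot)


def peak_frequency(spectrum: Spectrum, lo_hz: float = 9.0, hi_hz: float = 18.0) -> float:
    """Frequency of the largest PSD bin within [lo, hi)."""
    mask = (spectrum.freqs >= lo_hz) & (spectrum.freqs < hi_hz)
    if not mask.any():
        raise ValueError("peak search band contains no bins")
    sub = np.flatnonzero(mask)
    return float(spectrum.freqs[sub[np.argmax(spectrum.power[sub])]])


def default_scales(
    fs: float, n_scales: int = 32, band: tuple[float, float] = (2.0, 30.0),
    wavelet: str = MORLET6,
) -> np.ndarray:
    """Log-spaced CWT scales whose equivalent frequencies span ``band``."""
    fc = pywt.central_frequency(wavelet)   # cycles per sample at scale 1
    freqs = np.geomspace(band[1], band[0], n_scales)
    return fc * fs / freqs


def cwt(
    x: np.ndarray,
    fs: float,
    scales: np.ndarray | None = None,
    wavelet: str = MORLET6,
) -> Scalogram:
    """Continuous wavelet transform with a complex Morlet mother wavelet.

    Coefficient(b, a) approximates (1/sqrt(a)) * integral of
    f(t) conj(psi)((t - b)/a) dt, discretized at sample resolution.  The
    default scale grid is 32 log-spaced scales spanning 2-30 Hz equivalents.
    """
    x = np.asarray(x, dtype=float)
    if scales is None:
        scales = default_scales(fs, wavelet=wavelet)
    scales = np.asarray(scales, dtype=float)
    if scales.size == 0 or np.any(scales <= 0):
        raise ValueError("scales must be non-empty and positive")
    coeffs, freqs = pywt.cwt(
        x - x.mean(), scales, wavelet, sampling_period=1.0 / fs, method="fft"
    )
    return Scalogram(
        scales=scales,
        freqs_hz=freqs,
        shifts=np.arange(x.size) / fs,
        coeffs=coeffs,
    )


def cwt_features(
    scalogram: Scalogram, sigma_band: tuple[float, float] = (11.0, 16.0)
) -> dict[str, float]:
    """Sigma-scale summaries of a scalogram.

    Returns mean and max |coefficient| over scales whose equivalent
    frequency lies in the sigma band, and the ratio of sigma-scale energy
    (sum |c|^2) to total scalogram energy.
    """
    mag = np.abs(scalogram.coeffs)
    in_sigma = (scalogram.freqs_hz >= sigma_band[0]) & (scalogram.freqs_hz < sigma_band[1])
    if not in_sigma.any():
        raise ValueError("no scales fall in the sigma band; widen the scale grid")
    total_energy = float((mag**2).sum())
    sigma_mag = mag[in_sigma]
    return {
        "cwt_sigma_mean": float(sigma_mag.mean()),
        "cwt_sigma_max": float(sigma_mag.max()),
        "cwt_sigma_energy": (
            float((sigma_mag**2).sum() / total_energy) if total_energy > 0 else 0.0
        ),
    }


def ngs(x: np.ndarray) -> float:
    """Gaussian-deviation score from the normal probability plot.

    With q the sorted standardized sample and p the matching normal
    quantiles at Blom plotting positions ((j - 0.375)/(N + 0.25)), the score
    is ``1 - sum (q_j - p_j)^2 / sum (q_j - mean(q))^2``.  Perfectly
    Gaussian-ordered data score 1; heavier departures score lower (the score
    is always <= 1 up to the plotting-position approximation).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 20:
        raise ValueError("need at least 20 samples")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance input: standardization undefined")
    q = np.sort((x - x.mean()) / sd)
    j = np.arange(1, n + 1)
    p = norm.ppf((j - 0.375) / (n + 0.25))
    denom = np.sum((q - q.mean()) ** 2)
    return float(1.0 - np.sum((q - p) ** 2) / denom)


def bispectrum_diagonal(
    x: np.ndarray, fs: float, n_blocks: int = 8
) -> BispectrumSlice:
    """Direct (block-averaged) estimate of the bispectrum diagonal slice.

    The frame is split into ``n_blocks`` non-overlapping Hann-windowed
    blocks; with X_k the block DFTs, B(w, w) = mean_k X_k(w)^2 conj(X_k(2w))
    and P(w) = |B(w, w)| is returned for w up to fs/4 (so that 2w stays on
    the grid).  Unlike the power spectrum, this third-order statistic
    retains Fourier phase and so responds to quadratic phase coupling.
    """
    x = np.asarray(x, dtype=float)
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    block = x.size // n_blocks
    if block < 64:
        raise ValueError(
            f"block length {block} < 64 samples; use fewer blocks or more data"
        )
    win = np.hanning(block)
    n_diag = block // 4 + 1
    acc = np.zeros(n_diag, dtype=complex)
    for k in range(n_blocks):
        seg = x[k * block : (k + 1) * block]
        seg = (seg - seg.mean()) * win
        X = np.fft.rfft(seg)
        w = np.arange(n_diag)
        acc += X[w] * X[w] * np.conj(X[2 * w])
    B = acc / n_blocks
    freqs = np.arange(n_diag) * fs / block
    return BispectrumSlice(freqs=freqs, P=np.abs(B))


def bgs(
    slice_: BispectrumSlice,
    numerator: tuple[float, float] = (11.0, 16.0),
    denominator: tuple[float, float] = (0.5, 30.0),
) -> float:
    """Ratio of bispectrum diagonal-slice integrals over two bands.

    Rectangular integrals of P(w) over the half-open numerator band (default
    sigma, 11-16 Hz) and denominator band (default 0.5-30 Hz).
    """
    def integral(band: tuple[float, float]) -> float:
        lo, hi = band
        mask = (slice_.freqs >= lo) & (slice_.freqs < hi)
        if not mask.any():
            raise ValueError(
                f"band [{lo}, {hi}) Hz outside the diagonal-slice grid "
                f"(max {slice_.freqs[-1]:.2f} Hz)"
            )
        return float(slice_.P[mask].sum())

    den = integral(denominator)
    if den == 0:
        raise ValueError("denominator band integral is zero; BGS undefined")
    return integral(numerator) / den


def assemble_features(
    values: np.ndarray, fs: float, config: FeatureConfig | None = None
) -> dict[str, float]:
    """All 12 per-frame features, in the fixed :data:`FEATURE_NAMES` order.

    Sub-operation failures are re-raised with the feature name attached.
    """
    cfg = config or FeatureConfig()
    x = np.asarray(values, dtype=float)
    x = x - x.mean()
    out: dict[str, float] = {}

    # NGS first: it owns the zero-variance diagnosis for degenerate frames
    try:
        out["ngs"] = ngs(x)
    except ValueError as exc:
        raise ValueError(f"feature 'ngs' failed: {exc}") from exc

    try:
        spec = power_spectral_density(x, fs, cfg.psd_method, cfg.welch_window_s)
        for name, band in BANDS.items():
            out[f"psd_{name}"] = band_power(spec, *band)
        out["psd_rel_sigma"] = relative_band_power(spec, *cfg.sigma_band, total=cfg.total_band)
        out["psd_peak_hz"] = peak_frequency(spec, *cfg.peak_band)
    except ValueError as exc:
        raise ValueError(f"PSD features failed: {exc}") from exc

    try:
        scal = cwt(x, fs, default_scales(fs, cfg.n_scales, cfg.scale_band, cfg.wavelet),
                   cfg.wavelet)
        out.update(cwt_features(scal, cfg.sigma_band))
    except ValueError as exc:
        raise ValueError(f"CWT features failed: {exc}") from exc

    try:
        sl = bispectrum_diagonal(x, fs, cfg.n_blocks)
        out["bgs"] = bgs(sl, cfg.bgs_numerator, cfg.bgs_denominator)
    except ValueError as exc:
        raise ValueError(f"feature 'bgs' failed: {exc}") from exc

    ordered = {name: out[name] for name in FEATURE_NAMES}
    bad = [k for k, v in ordered.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite features: {bad}")
    return ordered
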