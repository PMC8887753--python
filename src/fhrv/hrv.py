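"""Time- and spectral-domain fetal HRV parameters for one segment.

Nine parameters per analysed time series: mean RR, SDNN and RMSSD in the
beat domain; LF power (0.04–0.4 Hz), HF power (0.4–1.5 Hz) and their ratio
from the detrended 4 Hz tachogram under two estimators — a single
full-segment Hann periodogram (FFT path, no window overlap) and an
autoregressive spectrum of fixed order 24 fitted by Burg's method. Both
spectra are normalized so the integrated one-sided PSD equals the sample
variance of the segment; band powers are trapezoidal integrals with the
lower edge inclusive and the upper edge exclusive, so 0.4 Hz belongs to HF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .preprocessing import Tachogram

__all__ = [
    "SpectralConfig",
    "HRVMeasures",
    "PowerSpectrum",
    "time_domain",
    "psd_fft",
    "psd_ar",
    "band_power",
    "burg",
    "segment_measures",
]


@dataclass(frozen=True)
class SpectralConfig:
    resample_hz: float = 4.0
    ar_order: int = 24
    lf_band: tuple[float, float] = (0.04, 0.4)
    hf_band: tuple[float, float] = (0.4, 1.5)
    window: str = "hann"

    def __post_init__(self) -> None:
        if self.ar_order < 1:
            raise ValueError("ar_order must be >= 1")
        if not (self.lf_band[0] < self.lf_band[1] <= self.hf_band[0] < self.hf_band[1]):
            raise ValueError("bands must be ordered and non-overlapping")
        if self.hf_band[1] > self.resample_hz / 2:
            raise ValueError("HF upper edge must not exceed Nyquist")


@dataclass(frozen=True)
class HRVMeasures:
    """The nine per-segment FHRV parameters (ms, ms, ms, then ms² and ratios)."""

    mean_rr_ms: float
    sdnn_ms: float
    rmssd_ms: float
    lf_fft_ms2: float
    hf_fft_ms2: float
    lfhf_fft: float
    lf_ar_ms2: float
    hf_ar_ms2: float
    lfhf_ar: float

    _FIELDS = (
        "mean_rr_ms", "sdnn_ms", "rmssd_ms",
        "lf_fft_ms2", "hf_fft_ms2", "lfhf_fft",
        "lf_ar_ms2", "hf_ar_ms2", "lfhf_ar",
    )

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self._FIELDS}


@dataclass(frozen=True)
class PowerSpectrum:
    freq_hz: np.ndarray
    psd_ms2_per_hz: np.ndarray


def time_domain(rr_ms: np.ndarray, rr_for_mean_ms: np.ndarray | None = None):
    """Mean RR, SDNN, RMSSD of a beat-domain segment.

    ``rr_ms`` is the (by default detrended) series used for SDNN/RMSSD;
    ``rr_for_mean_ms`` the un-detrended corrected values for mean RR
    (defaults to ``rr_ms``). SDNN uses the N−1 denominator.
    """
    rr = np.asarray(rr_ms, dtype=float)
    if rr.size < 3:
        raise ValueError("need at least 3 intervals")
    base = rr if rr_for_mean_ms is None else np.asarray(rr_for_mean_ms, dtype=float)
    mean_rr = float(base.mean())
    sdnn = float(rr.std(ddof=1))
    diffs = np.diff(rr)
    rmssd = float(np.sqrt(np.mean(diffs**2)))
    return mean_rr, sdnn, rmssd


def psd_fft(tachogram: Tachogram, config: SpectralConfig = SpectralConfig()) -> PowerSpectrum:
    """Single Hann-tapered periodogram of the full segment (no overlap).

    Zero-padded to at least 4x the segment length (next power of two);
    density scaling with window-power compensation, so the trapezoidal
    integral over (0, fs/2] equals the segment's sample variance.
    """
    x = np.asarray(tachogram.rr_ms, dtype=float)
    if x.size < 16:
        raise ValueError("segment too short for spectral analysis")
    fs = tachogram.sample_hz
    nfft = 1 << int(np.ceil(np.log2(4 * x.size)))
    freqs, psd = signal.periodogram(
        x, fs=fs, window=config.window, nfft=nfft, detrend="constant",
        scaling="density",
    )
    var = float(x.var(ddof=0))
    total = np.trapezoid(psd, freqs)
    if total > 0 and var > 0:
        psd = psd * (var / total)
    return PowerSpectrum(freq_hz=freqs, psd_ms2_per_hz=psd)


def burg(x: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """Burg's method: AR coefficients ``a`` (a[0]=1) and prediction variance.

    Minimizes the sum of forward and backward prediction errors at each
    order with the Levinson recursion; guarantees a stable model.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if order >= n:
        raise ValueError("order must be < number of samples")
    f = x.copy()
    b = x.copy()
    a = np.ones(1)
    e = float(np.mean(x**2))
    for m in range(order):
        ff = f[m + 1:]
        bb = b[m:-1]
        denom = float(np.dot(ff, ff) + np.dot(bb, bb))
        k = 0.0 if denom == 0.0 else -2.0 * float(np.dot(ff, bb)) / denom
        a = np.concatenate([a, [0.0]]) + k * np.concatenate([[0.0], a[::-1]])
        f_new = ff + k * bb
        b_new = bb + k * ff
        f[m + 1:] = f_new
        b[m + 1:] = b_new
        e *= 1.0 - k * k
    return a, e


def psd_ar(
    tachogram: Tachogram,
    config: SpectralConfig = SpectralConfig(),
    n_freq: int = 4096,
) -> PowerSpectrum:
    """AR spectrum at fixed order (default 24) fitted by Burg's method.

    One-sided PSD = 2 sigma² / (fs |A(e^{j2πf/fs})|²), rescaled so the
    trapezoidal integral over (0, fs/2] equals the segment variance — the
    sharp AR peaks then carry exactly the power they represent.
    """
    x = np.asarray(tachogram.rr_ms, dtype=float)
    if x.size <= 2 * config.ar_order:
        raise ValueError("segment must exceed twice the AR order")
    fs = tachogram.sample_hz
    xc = x - x.mean()
    a, _sig2 = burg(xc, config.ar_order)
    freqs = np.linspace(0.0, fs / 2.0, n_freq)
    _, h = signal.freqz(1.0, a, worN=freqs, fs=fs)
    # shape-only spectrum 1/|A|^2, then scale its integral to the variance;
    # the prediction-variance prefactor cancels under this normalization and
    # would underflow for noise-free (perfectly predictable) inputs
    shape = np.abs(h) ** 2
    if not np.all(np.isfinite(shape)):  # pole lands on a grid frequency
        cap = np.nanmax(shape[np.isfinite(shape)])
        shape = np.nan_to_num(shape, nan=cap, posinf=cap)
    var = float(xc.var(ddof=0))
    total = np.trapezoid(shape, freqs)
    psd = shape * (var / total) if total > 0 else np.zeros_like(shape)
    return PowerSpectrum(freq_hz=freqs, psd_ms2_per_hz=psd)


def band_power(spectrum: PowerSpectrum, band: tuple[float, float]) -> float:
    """Trapezoidal integral of the PSD over [low, high)."""
    lo, hi = band
    f, p = spectrum.freq_hz, spectrum.psd_ms2_per_hz
    if lo < f[0] - 1e-12 or hi > f[-1] + 1e-12:
        raise ValueError("band outside PSD support")
    # resample band edges onto the grid by interpolation for exact edges
    grid = f[(f > lo) & (f < hi)]
    fb = np.concatenate([[lo], grid, [hi]])
    pb = np.interp(fb, f, p)
    # upper edge exclusive: the integral is over the half-open interval,
    # which for a continuous integral coincides with the closed one
    return float(np.trapezoid(pb, fb))


def segment_measures(
    rr_detrended_ms: np.ndarray,
    rr_corrected_ms: np.ndarray,
    tachogram_detrended: Tachogram,
    config: SpectralConfig = SpectralConfig(),
) -> HRVMeasures:
    """All nine parameters for one segment."""
    mean_rr, sdnn, rmssd = time_domain(rr_detrended_ms, rr_corrected_ms)
    sp_fft = psd_fft(tachogram_detrended, config)
    sp_ar = psd_ar(tachogram_detrended, config)
    lf_f = band_power(sp_fft, config.lf_band)
    hf_f = band_power(sp_fft, config.hf_band)
    lf_a = band_power(sp_ar, config.lf_band)
    hf_a = band_power(sp_ar, config.hf_band)
    return HRVMeasures(
        mean_rr_ms=mean_rr,
        sdnn_ms=sdnn,
        rmssd_ms=rmssd,
        lf_fft_ms2=lf_f,
        hf_fft_ms2=hf_f,
        lfhf_fft=lf_f / hf_f if hf_f > 0 else float("nan"),
        lf_ar_ms2=lf_a,
        hf_ar_ms2=hf_a,
        lfhf_ar=lf_a / hf_a if hf_a > 0 else float("nan"),
    )
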