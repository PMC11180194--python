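"""Whitening: removal of the 1/f^α aperiodic trend.

Frequency-domain whitening multiplies each PSD bin by f^α, where α is the
site's fitted aperiodic exponent — an exactly invertible, linear operation.
Time-domain whitening applies the same scaling to the FFT magnitudes of the
Hann-windowed signal (phases preserved) and transforms back, after which the
PSD is re-estimated with Welch; for the time-domain path α is fitted on the
magnitude spectrum itself.  Magnitudes outside the 3–70 Hz analysis band are
zeroed so every site is treated identically.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .spectral import SitePSD, band_slice, welch_psd
from .specparam import FitSettings, fit_spectrum

__all__ = ["whiten_frequency", "whiten_time", "magnitude_exponent"]

ANALYSIS_BAND = (3.0, 70.0)


def whiten_frequency(psd: SitePSD, alpha: float,
                     band: tuple[float, float] = ANALYSIS_BAND) -> SitePSD:
    """p_w(f) = p_o(f) · f^α on the analysis band."""
    mask = band_slice(psd.freqs, *band)
    freqs = psd.freqs[mask]
    power = psd.power[mask] * freqs ** alpha
    out = psd.copy_with(freqs=freqs, power=power, norm_state="whitened")
    out.meta["alpha_used"] = float(alpha)
    out.meta["whiten_method"] = "frequency_domain"
    return out


def magnitude_exponent(series: np.ndarray, fs: float,
                       settings: FitSettings = FitSettings()) -> float:
    """Aperiodic exponent fitted to the FFT magnitude spectrum of the
    Hann-windowed signal (the α used by time-domain whitening)."""
    series = np.asarray(series, float)
    windowed = series * sps.windows.hann(series.size, sym=True)
    mag = np.abs(np.fft.rfft(windowed))
    freqs = np.fft.rfftfreq(series.size, 1 / fs)
    lo, hi = settings.fit_range
    mask = (freqs >= lo) & (freqs <= hi) & (mag > 0)
    return fit_spectrum(freqs[mask], mag[mask], settings).exponent


def whiten_time(series: np.ndarray, fs: float, alpha: float,
                band: tuple[float, float] = ANALYSIS_BAND,
                psd_window_s: float = 2.0
                ) -> tuple[np.ndarray, SitePSD]:
    """Whiten a signal in the time domain and return (signal, Welch PSD).

    The signal is Hann-windowed, transformed, magnitudes on ``band`` scaled
    by f^α with phases preserved, magnitudes outside the band zeroed, and
    transformed back.  No window-amplitude compensation is applied before
    the Welch re-estimate.
    """
    series = np.asarray(series, float)
    n = series.size
    windowed = series * sps.windows.hann(n, sym=True)
    spec = np.fft.rfft(windowed)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    scale = np.zeros_like(freqs)
    in_band = band_slice(freqs, *band) & (freqs > 0)  # DC never scaled
    scale[in_band] = freqs[in_band] ** alpha
    whitened = np.fft.irfft(spec * scale, n=n)
    psd = welch_psd(whitened, fs, window_s=psd_window_s, fmax=band[1])
    psd.norm_state = "whitened"
    psd.meta["alpha_used"] = float(alpha)
    psd.meta["whiten_method"] = "time_domain"
    mask = band_slice(psd.freqs, *band)
    psd.freqs = psd.freqs[mask]
    psd.power = psd.power[mask]
    return whitened, psd
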