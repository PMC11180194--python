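"""Spectral parameterization: aperiodic 1/f^α background plus Gaussian
periodic peaks, fitted in log10-power space.

The model over the fit range (3–70 Hz by default) is::

    log10 P(f) = b − α·log10 f + Σ_k  h_k · exp(−(f − c_k)² / (2 σ_k²))

with aperiodic offset ``b`` and exponent ``α`` (fixed mode: no knee), and up
to ``max_n_peaks`` Gaussian peaks with center ``c_k`` (Hz), height ``h_k``
(log10-power) and SD ``σ_k``.  The reported peak bandwidth is ``2 σ_k``.

The fitting procedure is the standard iterative one: a robust initial
aperiodic fit, peak extraction tallest-first from the flattened spectrum,
joint Gaussian refinement, and a final aperiodic refit on the peak-removed
spectrum.  One extension is supported: frequency-proportional peak-width
bounds (``peak_width_limits_per``), which raise the lower width bound for
high-frequency peaks to avoid overfitting narrow high-frequency wiggles —
the effective lower bandwidth bound at center ``c`` is
``max(peak_width_limits[0], peak_width_limits_per[0] · c)``; a zero second
element disables the proportional upper bound.

Goodness of fit is R² and mean absolute error (MAE), both in log10-power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["FitSettings", "AperiodicFit", "fit_spectrum", "model_spectrum",
           "goodness_surface"]


@dataclass(frozen=True)
class FitSettings:
    """Fit settings (defaults follow the study's configuration)."""

    peak_width_limits: tuple[float, float] = (0.8, 12.0)
    peak_width_limits_per: tuple[float, float] = (0.02, 0.0)
    max_n_peaks: int = 6
    min_peak_height: float = 0.05
    peak_threshold: float = 2.0
    aperiodic_mode: str = "fixed"
    fit_range: tuple[float, float] = (3.0, 70.0)

    def __post_init__(self) -> None:
        if self.aperiodic_mode != "fixed":
            raise ValueError("only the fixed (no-knee) aperiodic mode is "
                             "implemented")
        if self.peak_width_limits[0] <= 0 or self.peak_width_limits[1] <= 0:
            raise ValueError("peak_width_limits must be positive")

    def bandwidth_bounds(self, center: float) -> tuple[float, float]:
        """Effective (lower, upper) bandwidth bounds at a peak center."""
        lo = max(self.peak_width_limits[0],
                 self.peak_width_limits_per[0] * center)
        hi = self.peak_width_limits[1]
        if self.peak_width_limits_per[1] > 0:
            hi = min(hi, self.peak_width_limits_per[1] * center)
        return lo, max(hi, lo * (1 + 1e-9))


@dataclass
class AperiodicFit:
    """Result of one spectral-parameterization fit."""

    offset: float
    exponent: float
    peaks: list[tuple[float, float, float]]  # (center Hz, height, bandwidth Hz)
    r_squared: float
    mae: float
    converged: bool = True
    freqs: np.ndarray | None = None

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)


def _aperiodic(logf: np.ndarray, offset: float, exponent: float) -> np.ndarray:
    return offset - exponent * logf


def _gaussians(freqs: np.ndarray, params: np.ndarray) -> np.ndarray:
    """Sum of Gaussians; params is a flat (center, height, std) × k vector."""
    out = np.zeros_like(freqs, dtype=float)
    for c, h, s in params.reshape(-1, 3):
        out += h * np.exp(-((freqs - c) ** 2) / (2 * s ** 2))
    return out


def _simple_ap_fit(logf: np.ndarray, y: np.ndarray
                   ) -> tuple[np.ndarray, bool]:
    span = logf[-1] - logf[0]
    guess_exp = (y[0] - y[-1]) / span if span > 0 else 0.0
    p0 = [float(y[0] + guess_exp * logf[0]), float(guess_exp)]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_aperiodic, logf, y, p0=p0, maxfev=5000)
        return popt, True
    except RuntimeError:
        return np.array(p0), False


def _robust_ap_fit(logf: np.ndarray, y: np.ndarray
                   ) -> tuple[np.ndarray, bool]:
    """Refit the aperiodic component on the points least affected by peaks
    (flattened values at or below their 2.5th percentile)."""
    popt, ok = _simple_ap_fit(logf, y)
    flat = y - _aperiodic(logf, *popt)
    flat[flat < 0] = 0
    thresh = np.percentile(flat, 2.5)
    mask = flat <= thresh
    if mask.sum() >= 2:
        popt2, ok2 = _simple_ap_fit(logf[mask], y[mask])
        if ok2:
            return popt2, ok
    return popt, ok


def _guess_peaks(freqs: np.ndarray, flatspec: np.ndarray,
                 settings: FitSettings) -> list[list[float]]:
    flat = flatspec.copy()
    df = np.median(np.diff(freqs))
    guesses: list[list[float]] = []
    while len(guesses) < settings.max_n_peaks:
        i = int(np.argmax(flat))
        height = flat[i]
        if height <= settings.peak_threshold * np.std(flat):
            break
        if height < settings.min_peak_height:
            break
        center = float(freqs[i])
        # width from half-height crossings around the maximum
        half = height / 2
        li = i
        while li > 0 and flat[li] > half:
            li -= 1
        ri = i
        while ri < flat.size - 1 and flat[ri] > half:
            ri += 1
        fwhm = max((ri - li) * df, df)
        std = fwhm / 2.355
        bw_lo, bw_hi = settings.bandwidth_bounds(center)
        std = float(np.clip(std, bw_lo / 2, bw_hi / 2))
        flat = flat - height * np.exp(-((freqs - center) ** 2) / (2 * std ** 2))
        guesses.append([center, float(height), std])
    return guesses


def _fit_peaks(freqs: np.ndarray, flatspec: np.ndarray,
               guesses: list[list[float]], settings: FitSettings
               ) -> tuple[np.ndarray, bool]:
    if not guesses:
        return np.empty(0), True
    p0, lo, hi = [], [], []
    fmin, fmax = freqs[0], freqs[-1]
    for c, h, s in guesses:
        bw_lo, bw_hi = settings.bandwidth_bounds(c)
        p0 += [c, h, s]
        lo += [max(fmin, c - 2 * s), 0.0, bw_lo / 2]
        hi += [min(fmax, c + 2 * s), np.inf, bw_hi / 2]
        # keep bounds consistent if the guess sits at the range edge
        if lo[-3] >= hi[-3]:
            lo[-3], hi[-3] = fmin, fmax
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                lambda f, *p: _gaussians(f, np.asarray(p)),
                freqs, flatspec, p0=p0, bounds=(lo, hi), maxfev=5000)
        return np.asarray(popt), True
    except (RuntimeError, ValueError):
        return np.asarray(p0, float), False


def fit_spectrum(freqs: np.ndarray, power: np.ndarray,
                 settings: FitSettings = FitSettings()) -> AperiodicFit:
    """Fit the aperiodic + periodic model to a power spectrum.

    ``power`` is linear power; the fit runs on ``log10(power)`` restricted
    to ``settings.fit_range``.  Non-positive power inside the fit range is
    an error.  A failed optimizer is reported through ``converged=False``
    (with the best-available parameters), never silently.
    """
    freqs = np.asarray(freqs, float)
    power = np.asarray(power, float)
    lo, hi = settings.fit_range
    mask = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    f = freqs[mask]
    p = power[mask]
    if f.size < 5:
        raise ValueError("too few bins inside the fit range")
    if np.any(p <= 0):
        raise ValueError("power must be strictly positive on the fit range")
    y = np.log10(p)
    logf = np.log10(f)

    converged = True
    ap, ok = _robust_ap_fit(logf, y)
    converged &= ok

    flatspec = y - _aperiodic(logf, *ap)
    guesses = _guess_peaks(f, flatspec, settings)
    peak_params, ok = _fit_peaks(f, flatspec, guesses, settings)
    converged &= ok

    peak_model = _gaussians(f, peak_params) if peak_params.size else 0.0
    ap_final, ok = _simple_ap_fit(logf, y - peak_model)
    converged &= ok

    model = _aperiodic(logf, *ap_final) + peak_model
    resid = y - model
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = float(1 - np.sum(resid ** 2) / ss_tot) if ss_tot > 0 else float("nan")
    mae = float(np.mean(np.abs(resid)))

    peaks = [(float(c), float(h), float(2 * s))
             for c, h, s in peak_params.reshape(-1, 3)] if peak_params.size \
        else []
    peaks = [pk for pk in peaks if pk[1] >= settings.min_peak_height]
    peaks.sort(key=lambda pk: pk[0])
    return AperiodicFit(offset=float(ap_final[0]),
                        exponent=float(ap_final[1]),
                        peaks=peaks, r_squared=r2, mae=mae,
                        converged=converged, freqs=f)


def model_spectrum(fit: AperiodicFit, freqs: np.ndarray) -> np.ndarray:
    """Linear-power spectrum implied by a fit (for self-consistency checks)."""
    freqs = np.asarray(freqs, float)
    y = _aperiodic(np.log10(freqs), fit.offset, fit.exponent)
    for c, h, bw in fit.peaks:
        y = y + h * np.exp(-((freqs - c) ** 2) / (2 * (bw / 2) ** 2))
    return 10.0 ** y


def goodness_surface(cells: list[dict],
                     settings: FitSettings = FitSettings()):
    """Fit every simulated spectrum and tabulate goodness of fit per cell.

    R² is averaged on the inverse-hyperbolic-tangent scale and
    back-transformed with tanh (values clipped just below 1 first); MAE is
    averaged directly.  Returns a pandas DataFrame with one row per
    (exponent, target_mae, with_peaks) cell.
    """
    import pandas as pd

    rows = []
    for cell in cells:
        r2s, maes = [], []
        for spec in cell["spectra"]:
            fit = fit_spectrum(cell["freqs"], spec, settings)
            if np.isfinite(fit.r_squared):
                r2s.append(min(fit.r_squared, 1 - 1e-12))
            maes.append(fit.mae)
        if len(r2s) >= 2:
            z = np.arctanh(np.clip(r2s, -1 + 1e-12, 1 - 1e-12))
            r2_mean = float(np.tanh(z.mean()))
            r2_sd = float(np.tanh(z.std(ddof=1)))
        else:
            r2_mean = r2_sd = float("nan")
        rows.append({
            "exponent": cell["exponent"],
            "target_mae": cell["target_mae"],
            "with_peaks": bool(cell["peaks"]),
            "r2_mean": r2_mean, "r2_sd": r2_sd,
            "mae_mean": float(np.mean(maes)),
            "mae_sd": float(np.std(maes, ddof=1)) if len(maes) > 1 else 0.0,
            "n": len(cell["spectra"]),
        })
    return pd.DataFrame(rows)
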