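"""Beta-band features: center-frequency detection (13–33 Hz), alignment of
spectra to the beta center frequency (βCF), LFP→SPK downshift statistics,
and peak bandwidth measurement at half, quarter and three-quarter
prominence heights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import peak_prominences
from scipy.stats import wilcoxon

from .spectral import SitePSD, band_slice

__all__ = ["BetaPeak", "BandwidthRecord", "DownshiftSummary",
           "detect_beta_cf", "align_to_cf", "measure_bandwidth",
           "summarize_downshift", "BETA_BAND"]

BETA_BAND = (13.0, 33.0)


@dataclass
class BetaPeak:
    beta_cf: float | None      # None when no local maximum exists in band
    peak_power: float | None
    level: str = "site"        # site | trajectory | population
    stream: str = ""

    @property
    def found(self) -> bool:
        return self.beta_cf is not None


@dataclass
class BandwidthRecord:
    half_band_width: float
    left_half_side: float
    right_half_side: float
    quarter_band_width: float | None = None
    three_quarter_band_width: float | None = None
    reference_height: float | None = None
    censored: bool = False


@dataclass
class DownshiftSummary:
    n_pairs: int
    fraction_down: float
    fraction_up: float
    fraction_equal: float
    statistic: float | None
    p_value: float | None


def detect_beta_cf(freqs: np.ndarray, power: np.ndarray,
                   band: tuple[float, float] = BETA_BAND,
                   level: str = "site", stream: str = "") -> BetaPeak:
    """βCF = frequency of the highest local peak in the beta band.

    A local peak is a bin strictly greater than both neighbors (neighbors
    may lie just outside the band edge).  No qualifying local maximum is a
    valid no-peak outcome, not an error.
    """
    freqs = np.asarray(freqs, float)
    power = np.asarray(power, float)
    mask = band_slice(freqs, *band)
    idx = np.flatnonzero(mask)
    best_i = None
    for i in idx:
        if i == 0 or i == power.size - 1:
            continue
        if power[i] > power[i - 1] and power[i] > power[i + 1]:
            if best_i is None or power[i] > power[best_i]:
                best_i = i
    if best_i is None:
        return BetaPeak(None, None, level=level, stream=stream)
    return BetaPeak(float(freqs[best_i]), float(power[best_i]),
                    level=level, stream=stream)


def align_to_cf(freqs: np.ndarray, beta_cf: float) -> np.ndarray:
    """Translate the frequency axis so ΔFrequency = 0 marks the beta peak."""
    return np.asarray(freqs, float) - beta_cf


def _crossing(freqs: np.ndarray, power: np.ndarray, i_peak: int,
              ref: float, direction: int) -> tuple[float, bool]:
    """Walk from the peak in ``direction`` to the first crossing of ``ref``;
    linear interpolation between the bracketing bins.  Returns (frequency,
    censored-at-edge flag)."""
    i = i_peak
    while 0 < i < power.size - 1:
        j = i + direction
        if power[j] <= ref:
            # interpolate between i (above) and j (at/below)
            f0, f1 = freqs[i], freqs[j]
            p0, p1 = power[i], power[j]
            if p0 == p1:
                return float(f1), False
            frac = (p0 - ref) / (p0 - p1)
            return float(f0 + frac * (f1 - f0)), False
        i = j
    return float(freqs[i]), True


def measure_bandwidth(freqs: np.ndarray, power: np.ndarray,
                      beta_cf: float | None = None,
                      band: tuple[float, float] = BETA_BAND,
                      prominence_band: tuple[float, float] = (3.0, 70.0)
                      ) -> BandwidthRecord | None:
    """Width of the beta peak at half (and quarter / three-quarter) of its
    topographic prominence.

    The reference height is ``peak − prominence/2``; flank crossings are
    located by linear interpolation between the two bracketing bins, and
    the half-side widths are the distances from the crossings to the peak.
    Prominence is evaluated within the full 3–70 Hz spectrum so shoulders
    are handled.  Returns ``None`` when no beta peak exists.
    """
    freqs = np.asarray(freqs, float)
    power = np.asarray(power, float)
    pmask = band_slice(freqs, *prominence_band)
    f = freqs[pmask]
    p = power[pmask]
    if beta_cf is None:
        peak = detect_beta_cf(f, p, band=band)
        if not peak.found:
            return None
        beta_cf = peak.beta_cf
    i_peak = int(np.argmin(np.abs(f - beta_cf)))
    prom = peak_prominences(p, [i_peak])[0][0]
    if prom <= 0:
        # peak at a plateau or series edge: fall back to height above the
        # in-band minimum so a width is still defined
        prom = p[i_peak] - p[band_slice(f, *band)].min()
        if prom <= 0:
            return None

    def width_at(fraction: float) -> tuple[float, float, float, bool]:
        ref = p[i_peak] - fraction * prom
        f_left, cl = _crossing(f, p, i_peak, ref, -1)
        f_right, cr = _crossing(f, p, i_peak, ref, +1)
        return (f[i_peak] - f_left, f_right - f[i_peak],
                f_right - f_left, cl or cr)

    left, right, half_bw, censored = width_at(0.5)
    _, _, quarter_bw, c2 = width_at(0.75)   # 1/4 height = 3/4 down
    _, _, tq_bw, c3 = width_at(0.25)        # 3/4 height = 1/4 down
    return BandwidthRecord(
        half_band_width=half_bw, left_half_side=left, right_half_side=right,
        quarter_band_width=quarter_bw, three_quarter_band_width=tq_bw,
        reference_height=float(p[i_peak] - prom / 2),
        censored=censored or c2 or c3)


def summarize_downshift(lfp_cfs: np.ndarray, spk_cfs: np.ndarray,
                        equal_tol: float = 0.5) -> DownshiftSummary:
    """Fractions of pairs with SPK βCF below/above/equal to the LFP βCF,
    plus a two-tailed Wilcoxon signed-rank test on the paired βCFs.

    "Equal" means |Δ| < ``equal_tol`` (one 0.5 Hz bin).  With fewer than
    two pairs, or all-zero differences, only the fractions are reported.
    """
    lfp_cfs = np.asarray(lfp_cfs, float)
    spk_cfs = np.asarray(spk_cfs, float)
    if lfp_cfs.shape != spk_cfs.shape:
        raise ValueError("paired βCF arrays must have equal length")
    n = lfp_cfs.size
    if n == 0:
        return DownshiftSummary(0, np.nan, np.nan, np.nan, None, None)
    delta = spk_cfs - lfp_cfs
    down = float(np.mean(delta < -equal_tol + 1e-12))
    up = float(np.mean(delta > equal_tol - 1e-12))
    equal = 1.0 - down - up
    stat = p = None
    if n >= 2 and np.any(delta != 0):
        res = wilcoxon(lfp_cfs, spk_cfs, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    return DownshiftSummary(n_pairs=n, fraction_down=down, fraction_up=up,
                            fraction_equal=equal, statistic=stat, p_value=p)
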