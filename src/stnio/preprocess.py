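"""Stream splitting, RMS normalization and RMS-based outlier removal.

The wide-band recording is split into the LFP band (3–200 Hz) and the
spiking band (300–6000 Hz by default) with zero-phase Butterworth filters;
the spiking stream is full-wave rectified and mean-subtracted so its
low-frequency content reflects the population discharge rate.  Site
amplitudes are summarized as RMS, normalized per trajectory against the
first ten (pre-STN, white-matter) sites, and flagged as outliers by the
3 × IQR fence.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

__all__ = ["split_streams", "rms", "normalize_rms", "flag_outliers"]


def _bandpass_sos(band: tuple[float, float], fs: float, order: int = 4):
    lo, hi = band
    nyq = fs / 2
    if not 0 < lo < nyq:
        raise ValueError(f"band edge {lo} Hz outside (0, {nyq}) Hz")
    if not lo < hi < nyq:
        raise ValueError(f"band edge {hi} Hz outside ({lo}, {nyq}) Hz")
    # order counts poles of the band-pass; scipy's N is per-band-edge
    return sps.butter(order // 2, band, btype="bandpass", fs=fs, output="sos")


def split_streams(signal: np.ndarray, fs: float,
                  lfp_band: tuple[float, float] = (3.0, 200.0),
                  spk_band: tuple[float, float] = (300.0, 6000.0),
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Split a wide-band recording into (lfp, spk) streams.

    Both filters are 4-pole zero-phase (forward-backward) band-pass
    Butterworth; the spiking stream is additionally rectified by the
    absolute operator and mean-subtracted.
    """
    signal = np.asarray(signal, float)
    lfp = sps.sosfiltfilt(_bandpass_sos(lfp_band, fs), signal)
    spk = sps.sosfiltfilt(_bandpass_sos(spk_band, fs), signal)
    spk = np.abs(spk)
    spk = spk - spk.mean()
    return lfp, spk


def rms(series: np.ndarray) -> float:
    """Root-mean-square amplitude of a series."""
    series = np.asarray(series, float)
    if series.size == 0:
        raise ValueError("cannot compute RMS of an empty series")
    return float(np.sqrt(np.mean(series ** 2)))


def normalize_rms(site_rms: np.ndarray, n_baseline: int = 10,
                  baseline_mask: np.ndarray | None = None) -> np.ndarray:
    """NRMS: divide each site RMS by the mean RMS of the first ``n_baseline``
    sites of the trajectory.

    ``baseline_mask`` optionally marks sites eligible for the baseline (so
    outliers falling in the first ten sites can be excluded from the
    baseline mean while still being normalized themselves).
    """
    site_rms = np.asarray(site_rms, float)
    if site_rms.size < n_baseline:
        raise ValueError(
            f"need at least {n_baseline} sites, got {site_rms.size}")
    head = site_rms[:n_baseline]
    if baseline_mask is not None:
        keep = np.asarray(baseline_mask, bool)[:n_baseline]
        if not keep.any():
            raise ValueError("no baseline sites left after masking")
        head = head[keep]
    baseline = head.mean()
    if baseline <= 0:
        raise ValueError("baseline mean RMS must be positive")
    return site_rms / baseline


def flag_outliers(values: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Tukey-style fence: flag values beyond ``k`` interquartile ranges
    above Q3 or below Q1 (linear-interpolation quartiles)."""
    values = np.asarray(values, float)
    if values.size < 4:
        raise ValueError("need at least 4 sites to define quartiles")
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values > q3 + k * iqr) | (values < q1 - k * iqr)
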