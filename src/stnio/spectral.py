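"""Welch spectral estimation, line-noise repair, normalizations, coherence
and distance-resolved spectrograms.

All site spectra live on a 0.5 Hz grid (2-s Hamming windows, 50% overlap).
Two normalizations are used downstream: by frequency (each bin divided by
the total 3–200 Hz power, giving % of total power) and by frequency and
distance (per-bin z-score against the first ten pre-STN depths of the
trajectory).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = ["SitePSD", "TrajectorySpectrogram", "welch_psd",
           "repair_line_noise", "normalize_by_frequency",
           "normalize_by_distance", "coherence", "build_spectrogram",
           "band_slice"]


@dataclass
class SitePSD:
    """Power spectrum of one site/stream with its normalization state."""

    freqs: np.ndarray
    power: np.ndarray
    norm_state: str = "raw"           # raw | freq_norm | freq_dist_norm | whitened
    stream: str = ""                  # LFP | SPK
    meta: dict = field(default_factory=dict)
    excluded: bool = False
    flags: list = field(default_factory=list)

    def copy_with(self, **kw) -> "SitePSD":
        out = replace(self, **kw)
        out.meta = dict(self.meta)
        out.flags = list(self.flags)
        return out


@dataclass
class TrajectorySpectrogram:
    """Power as a function of normalized distance (STN entry = 0, exit = 1;
    pre-STN negative) and frequency."""

    nd: np.ndarray          # strictly increasing normalized distance
    freqs: np.ndarray
    power: np.ndarray       # shape (n_freqs, n_sites)
    stream: str = ""


def band_slice(freqs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Boolean mask for lo <= f <= hi (half-bin tolerance at the edges)."""
    return (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)


def welch_psd(series: np.ndarray, fs: float, window_s: float = 2.0,
              overlap: float = 0.5, fmax: float = 200.0,
              detrend: str = "none",
              stream: str = "", meta: dict | None = None) -> SitePSD:
    """Welch PSD with Hamming windows of ``window_s`` seconds (0.5 Hz grid
    at the 2-s default).

    Segments are not detrended by default (``detrend='constant'`` removes
    the per-segment mean instead).  Sites shorter than 1.5 × the window are
    marked ``excluded`` rather than raising, mirroring the study's duration
    criterion.
    """
    series = np.asarray(series, float)
    if fs < 2 * fmax:
        raise ValueError(f"fs = {fs} Hz cannot resolve fmax = {fmax} Hz")
    nperseg = int(round(window_s * fs))
    if series.size < 1.5 * nperseg:
        return SitePSD(freqs=np.array([]), power=np.array([]),
                       stream=stream, meta=meta or {}, excluded=True,
                       flags=["too_short"])
    freqs, power = sps.welch(series, fs=fs, window="hamming",
                             nperseg=nperseg,
                             noverlap=int(nperseg * overlap),
                             detrend=False if detrend == "none" else detrend)
    keep = freqs <= fmax + 1e-9
    return SitePSD(freqs=freqs[keep], power=power[keep], norm_state="raw",
                   stream=stream, meta=meta or {})


def repair_line_noise(psd: SitePSD, mains: float = 50.0,
                      half_width: float = 2.0) -> SitePSD:
    """Replace bins within ``half_width`` Hz of the mains frequency and its
    harmonics by the mean of the closest unaffected bin on each side.

    Idempotent: repaired bins take a value derived only from bins outside
    the notch bands.
    """
    if psd.excluded:
        return psd
    freqs, power = psd.freqs, psd.power.copy()
    fmax = freqs[-1]
    affected = np.zeros(freqs.size, bool)
    h = mains
    while h <= fmax + half_width:
        affected |= np.abs(freqs - h) <= half_width + 1e-9
        h += mains
    if affected.any():
        idx = np.flatnonzero(affected)
        # process each contiguous affected band
        splits = np.flatnonzero(np.diff(idx) > 1) + 1
        for band in np.split(idx, splits):
            left = band[0] - 1
            right = band[-1] + 1
            neighbors = []
            if left >= 0 and not affected[left]:
                neighbors.append(power[left])
            if right < power.size and not affected[right]:
                neighbors.append(power[right])
            if neighbors:
                power[band] = np.mean(neighbors)
    out = psd.copy_with(power=power)
    return out


def normalize_by_frequency(psd: SitePSD, total_band: tuple[float, float]
                           = (3.0, 200.0)) -> SitePSD:
    """Divide each bin by the total power in ``total_band`` (NPSD, % of
    total power); invariant under rescaling of the input."""
    if psd.excluded:
        return psd
    mask = band_slice(psd.freqs, *total_band)
    total = psd.power[mask].sum()
    if total <= 0:
        raise ValueError("total power in the normalization band is zero")
    return psd.copy_with(power=psd.power / total, norm_state="freq_norm")


def normalize_by_distance(trajectory_psds: list[SitePSD],
                          baseline_psds: list[SitePSD] | None = None,
                          n_baseline: int = 10) -> list[SitePSD]:
    """Per-bin z-score of each NPSD against the first ``n_baseline``
    pre-STN depths of the trajectory.

    ``baseline_psds`` defaults to the first ``n_baseline`` entries of
    ``trajectory_psds`` (which must be depth-ordered with pre-STN first).
    Bins with zero baseline SD are set to 0 and flagged.
    """
    usable = [p for p in trajectory_psds if not p.excluded]
    if baseline_psds is None:
        baseline_psds = usable[:n_baseline]
    if len(baseline_psds) < n_baseline:
        raise ValueError(f"need {n_baseline} baseline sites")
    base = np.stack([p.power for p in baseline_psds])
    mu = base.mean(axis=0)
    sd = base.std(axis=0, ddof=0)
    zero_sd = sd == 0
    sd_safe = np.where(zero_sd, 1.0, sd)
    out = []
    for p in trajectory_psds:
        if p.excluded:
            out.append(p)
            continue
        z = (p.power - mu) / sd_safe
        z[zero_sd] = 0.0
        q = p.copy_with(power=z, norm_state="freq_dist_norm")
        if zero_sd.any():
            q.flags.append("zero_baseline_sd_bins")
        out.append(q)
    return out


def coherence(lfp: np.ndarray, spk: np.ndarray, fs: float,
              window_s: float = 2.0, overlap: float = 0.5,
              band: tuple[float, float] = (3.0, 70.0)
              ) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude-squared coherence of simultaneous LFP/SPK series on the
    beta-analysis band (2-s Hamming windows, 50% overlap)."""
    lfp = np.asarray(lfp, float)
    spk = np.asarray(spk, float)
    if lfp.shape != spk.shape:
        raise ValueError("coherence requires equal-length simultaneous series")
    nperseg = int(round(window_s * fs))
    if lfp.size < 1.5 * nperseg:
        raise ValueError("series shorter than 1.5 windows; site excluded")
    freqs, coh = sps.coherence(lfp, spk, fs=fs, window="hamming",
                               nperseg=nperseg,
                               noverlap=int(nperseg * overlap))
    mask = band_slice(freqs, *band)
    return freqs[mask], coh[mask]


def build_spectrogram(trajectory_psds: list[SitePSD], depths_mm: np.ndarray,
                      entry_mm: float, exit_mm: float,
                      stream: str = "") -> TrajectorySpectrogram:
    """Stack site PSDs over normalized distance.

    ND = (depth − entry) / (exit − entry); pre-STN sites map to negative ND.
    Excluded sites are dropped.
    """
    if exit_mm <= entry_mm:
        raise ValueError("STN exit depth must exceed entry depth")
    depths_mm = np.asarray(depths_mm, float)
    keep = [i for i, p in enumerate(trajectory_psds) if not p.excluded]
    if not keep:
        raise ValueError("no retained sites for the spectrogram")
    nd = (depths_mm[keep] - entry_mm) / (exit_mm - entry_mm)
    order = np.argsort(nd)
    nd = nd[order]
    cols = [trajectory_psds[keep[i]] for i in order]
    freqs = cols[0].freqs
    power = np.column_stack([c.power for c in cols])
    return TrajectorySpectrogram(nd=nd, freqs=freqs, power=power,
                                 stream=stream)
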