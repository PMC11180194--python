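"""Synthetic signal generators for the subthalamic input-output analyses.

Three generators live here:

* :func:`simulate_brown_beta` — Brown noise (random-walk, exponent α = 2)
  carrying a 20 Hz beta sine, plus its full-wave-rectified variant.  This is
  the "simulated LFP" used to show that rectification does not move the beta
  center frequency.
* :func:`simulate_spiking` — the same Brown + high-amplitude beta "membrane
  potential" with Poisson spikes riding on the beta peaks, band-passed to the
  spiking band and rectified.  Rectification demodulates the discharge-rate
  beta oscillation back into the low-frequency range.
* :func:`simulate_test_spectra` — log-log-linear spectra (with optional
  Gaussian peaks and calibrated additive noise) used to map the goodness of
  fit of the spectral parameterization across exponent / noise levels.

All generators are deterministic given ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "SimSignalConfig",
    "SpectrumSimConfig",
    "PAPER_TEST_PEAKS",
    "simulate_brown_beta",
    "simulate_spiking",
    "simulate_test_spectra",
    "colored_noise",
    "averaged_periodogram",
]

#: Gaussian periodic triplets (center Hz, SD Hz, amplitude log10-power) used in
#: the goodness-of-fit simulation.
PAPER_TEST_PEAKS: tuple[tuple[float, float, float], ...] = (
    (18.0, 5.0, 1.5),
    (25.0, 8.0, 3.0),
    (35.0, 5.0, 2.0),
)


@dataclass(frozen=True)
class SimSignalConfig:
    """Settings for the time-domain Brown-noise / beta / spiking simulations.

    Parameters
    ----------
    n_samples
        Pre-trim length; the middle half is retained after high-pass
        filtering (8192 samples ≙ 2 s at 4096 Hz, retaining 1 s).
    fs
        Sampling rate in Hz.
    beta_freq
        Frequency of the beta sine, Hz.
    beta_amp_factor
        Amplitude of the low-amplitude beta sine, as a multiple of the SD of
        the Brown noise (the "simulated LFP" modulation).
    beta_amp_factor_high
        Amplitude of the high-amplitude beta sine used for the membrane
        potential in the spiking simulation.
    spike_rate_mean
        Mean of the Poisson spike count per supra-threshold beta peak.
    spike_threshold_pct
        Percentile of the high-amplitude beta sine defining the spiking
        threshold.
    spike_amp_factor
        Spike amplitude, as a multiple of the maximum of the high-amplitude
        beta sine.
    hp_cutoff
        High-pass cutoff (Hz) of the 2nd-order Butterworth filter applied to
        the Brown noise (mimicking the acquisition hardware).
    spk_band
        Band-pass (Hz) applied to the spiking signal before rectification.
    """

    n_samples: int = 8192
    fs: float = 4096.0
    beta_freq: float = 20.0
    beta_amp_factor: float = 0.5
    beta_amp_factor_high: float = 1.2
    spike_rate_mean: float = 6.0
    spike_threshold_pct: float = 60.0
    spike_amp_factor: float = 3.0
    hp_cutoff: float = 0.1
    spk_band: tuple[float, float] = (300.0, 2000.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.fs <= 2 * self.beta_freq:
            raise ValueError("fs must exceed twice the beta frequency")
        if self.n_samples < 8:
            raise ValueError("n_samples too small to trim filter edges")
        for name in ("beta_amp_factor", "beta_amp_factor_high",
                     "spike_amp_factor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.hp_cutoff >= self.fs / 2:
            raise ValueError(
                f"hp_cutoff {self.hp_cutoff} Hz is at or above Nyquist "
                f"({self.fs / 2} Hz); cannot design the high-pass filter")


def _trim(x: np.ndarray, n_samples: int) -> np.ndarray:
    """Drop the first and last quarter, keeping the middle half."""
    q = n_samples // 4
    return x[q:n_samples - q]


def _brown(cfg: SimSignalConfig, rng: np.random.Generator) -> np.ndarray:
    """High-pass-filtered random walk, edge-trimmed to the middle half."""
    steps = rng.standard_normal(cfg.n_samples)
    walk = np.cumsum(steps)
    sos = sps.butter(2, cfg.hp_cutoff, btype="highpass", fs=cfg.fs,
                     output="sos")
    filtered = sps.sosfilt(sos, walk)  # causal, as in the acquisition chain
    return _trim(filtered, cfg.n_samples)


def _beta_sine(cfg: SimSignalConfig, amplitude: float) -> np.ndarray:
    """Beta sine generated at full pre-trim length, then trimmed.

    Generating before trimming keeps the sine phase locked to the retained
    noise window regardless of the trim offset.
    """
    t = np.arange(cfg.n_samples) / cfg.fs
    return _trim(amplitude * np.sin(2 * np.pi * cfg.beta_freq * t),
                 cfg.n_samples)


def simulate_brown_beta(cfg: SimSignalConfig) -> dict[str, np.ndarray]:
    """Simulate the beta-modulated Brown-noise LFP and its rectified form.

    Returns
    -------
    dict with keys ``brown``, ``beta``, ``beta_modulated`` and
    ``rectified_beta_modulated`` (absolute value, mean-subtracted), each of
    length ``n_samples // 2``.
    """
    rng = np.random.default_rng(cfg.seed)
    brown = _brown(cfg, rng)
    beta = _beta_sine(cfg, cfg.beta_amp_factor * np.std(brown))
    modulated = brown + beta
    rectified = np.abs(modulated)
    rectified = rectified - rectified.mean()
    return {
        "brown": brown,
        "beta": beta,
        "beta_modulated": modulated,
        "rectified_beta_modulated": rectified,
    }


def simulate_spiking(cfg: SimSignalConfig) -> dict[str, object]:
    """Simulate beta-locked multi-unit spiking and its rectified envelope.

    The membrane potential is Brown noise plus a high-amplitude beta sine.
    Wherever the membrane exceeds the spiking threshold (a percentile of the
    beta sine itself, so spikes ride on beta peaks), a Poisson-distributed
    number of spikes is placed uniformly within the supra-threshold segment.
    The summed signal is band-passed to the spiking band and rectified, which
    demodulates the beta-rhythmic discharge rate back below 70 Hz.

    Returns
    -------
    dict with keys ``membrane``, ``spike_train`` (0/1 indicator),
    ``bandpassed``, ``rectified_spk`` and metadata ``n_spikes``,
    ``n_segments``, ``empty_spike_train``.
    """
    rng = np.random.default_rng(cfg.seed)
    brown = _brown(cfg, rng)
    beta_hi = _beta_sine(cfg, cfg.beta_amp_factor_high * np.std(brown))
    membrane = brown + beta_hi

    threshold = np.percentile(beta_hi, cfg.spike_threshold_pct)
    supra = membrane > threshold
    spike_train = np.zeros_like(membrane)
    n_segments = 0
    # One Poisson draw per beta cycle: the supra-threshold samples within
    # each beta period form that peak's spiking region; spike times are
    # uniform within the region, without replacement on the sample grid.
    period = cfg.fs / cfg.beta_freq
    edges = np.round(np.arange(0.0, membrane.size + period / 2,
                               period)).astype(int)
    edges = np.unique(np.clip(edges, 0, membrane.size))
    for lo, hi in zip(edges[:-1], edges[1:]):
        region = lo + np.flatnonzero(supra[lo:hi])
        if region.size == 0:
            continue
        n_segments += 1
        k = min(rng.poisson(cfg.spike_rate_mean), region.size)
        if k:
            spike_train[rng.choice(region, size=k, replace=False)] = 1.0

    spike_amp = cfg.spike_amp_factor * np.max(beta_hi) if beta_hi.size else 0.0
    with_spikes = membrane + spike_amp * spike_train  # wide-band signal

    lo, hi = cfg.spk_band
    if hi >= cfg.fs / 2:
        raise ValueError(
            f"spiking band edge {hi} Hz is at or above Nyquist ({cfg.fs / 2})")
    sos = sps.butter(3, [lo, hi], btype="bandpass", fs=cfg.fs, output="sos")
    bandpassed = sps.sosfiltfilt(sos, with_spikes)
    rectified = np.abs(bandpassed)

    return {
        "membrane": membrane,
        "spike_train": spike_train,
        "with_spikes": with_spikes,
        "bandpassed": bandpassed,
        "rectified_spk": rectified,
        "n_spikes": int(spike_train.sum()),
        "n_segments": n_segments,
        "empty_spike_train": not bool(spike_train.any()),
    }


@dataclass(frozen=True)
class SpectrumSimConfig:
    """Grid settings for the goodness-of-fit spectrum simulation."""

    exponent_grid: tuple[float, ...] = tuple(np.arange(-0.25, 2.26, 0.25))
    peaks: tuple[tuple[float, float, float], ...] | None = None
    noise_mae_grid: tuple[float, ...] = tuple(np.linspace(0.005, 0.145, 8))
    n_repeats: int = 20
    freq_range: tuple[float, float] = (3.0, 70.0)
    freq_step: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.exponent_grid:
            raise ValueError("exponent_grid must be non-empty")
        lo, hi = self.freq_range
        if self.peaks:
            for c, _, _ in self.peaks:
                if not lo <= c <= hi:
                    raise ValueError(f"peak center {c} outside freq_range")


def _calibrate_noise_sd(target_mae: float, unit_noise: np.ndarray,
                        rel_tol: float = 0.05, n_iter: int = 25) -> float:
    """Bisection on the noise SD so the empirical MAE hits ``target_mae``."""
    if target_mae <= 0:
        return 0.0
    unit_mae = np.mean(np.abs(unit_noise))
    if unit_mae == 0:
        return 0.0
    lo, hi = 0.0, 10.0 * target_mae / unit_mae
    sd = hi
    for _ in range(n_iter):
        sd = 0.5 * (lo + hi)
        mae = sd * unit_mae
        if abs(mae - target_mae) <= rel_tol * target_mae:
            break
        if mae < target_mae:
            lo = sd
        else:
            hi = sd
    return sd


def simulate_test_spectra(cfg: SpectrumSimConfig) -> list[dict]:
    """Simulate log-log-linear spectra across the (α, noise) grid.

    Each spectrum is ``log10 P(f) = b − α·log10 f`` with offset ``b = α``
    (mirroring the empirical offset-exponent correlation), plus optional
    Gaussian peaks in log-power, plus Gaussian noise whose SD is calibrated
    by bisection so the realized mean absolute deviation matches the
    requested target.

    Returns a list of cells; each cell carries the frequency grid, the
    ``n_repeats`` noisy spectra (linear power), the truth parameters, and
    the achieved MAE per repeat.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.freq_range
    freqs = np.arange(lo, hi + cfg.freq_step / 2, cfg.freq_step)
    logf = np.log10(freqs)

    peak_term = np.zeros_like(freqs)
    if cfg.peaks:
        for c, sd, amp in cfg.peaks:
            peak_term += amp * np.exp(-((freqs - c) ** 2) / (2 * sd ** 2))

    cells = []
    for alpha in cfg.exponent_grid:
        clean = alpha - alpha * logf + peak_term
        for target_mae in cfg.noise_mae_grid:
            spectra = np.empty((cfg.n_repeats, freqs.size))
            achieved = np.empty(cfg.n_repeats)
            for r in range(cfg.n_repeats):
                unit = rng.standard_normal(freqs.size)
                sd = _calibrate_noise_sd(target_mae, unit)
                noisy = clean + sd * unit
                achieved[r] = np.mean(np.abs(noisy - clean))
                spectra[r] = 10.0 ** noisy
            cells.append({
                "freqs": freqs,
                "spectra": spectra,
                "offset": float(alpha),
                "exponent": float(alpha),
                "peaks": tuple(cfg.peaks) if cfg.peaks else (),
                "target_mae": float(target_mae),
                "achieved_mae": achieved,
            })
    return cells


def colored_noise(n: int, exponent: float, rng: np.random.Generator,
                  sd: float = 1.0) -> np.ndarray:
    """Gaussian noise with power spectrum ∝ 1/f^exponent (FFT shaping).

    The zero-frequency bin is nulled; the output is rescaled to standard
    deviation ``sd``.  ``exponent = 0`` gives white noise, ``2`` Brown-like.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n=n)
    x_sd = np.std(x)
    if x_sd > 0:
        x *= sd / x_sd
    return x


def averaged_periodogram(realizations: Sequence[np.ndarray], fs: float,
                         nfft: int = 4096) -> tuple[np.ndarray, np.ndarray]:
    """Average of log10 periodograms across realizations.

    Each realization is windowed with a Hamming window of its own length
    (1 s at the default simulation settings) and transformed with ``nfft``
    points, giving a 1 Hz grid at fs = 4096.  Returns ``(freqs,
    mean_log10_power)`` with the zero bin dropped.
    """
    acc = None
    count = 0
    freqs = None
    for x in realizations:
        f, p = sps.periodogram(x, fs=fs, window="hamming", nfft=nfft,
                               detrend=False)
        logp = np.log10(np.maximum(p[1:], 1e-300))
        acc = logp if acc is None else acc + logp
        freqs = f[1:]
        count += 1
    if count == 0:
        raise ValueError("no realizations supplied")
    return freqs, acc / count
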