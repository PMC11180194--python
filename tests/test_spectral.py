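"""Welch estimation, line-noise repair, normalizations, coherence and
normalized-distance spectrograms."""

import numpy as np
import pytest

from stnio import spectral
from stnio.spectral import SitePSD

FS = 4096.0


def _psd_of(x, **kw):
    return spectral.welch_psd(x, FS, **kw)


class TestWelch:
    def test_grid_spacing_is_half_hz(self, rng):
        psd = _psd_of(rng.standard_normal(int(4 * FS)))
        np.testing.assert_allclose(np.diff(psd.freqs), 0.5)

    def test_white_noise_is_flat(self, rng):
        # average 50 four-second draws to shrink estimator variance
        powers = [_psd_of(rng.standard_normal(int(4 * FS))).power
                  for _ in range(50)]
        p = np.mean(powers, axis=0)[20:]  # skip the DC edge bins
        # ~150 averaged segments -> per-bin SE ~ mean/sqrt(150)
        z = (p - p.mean()) / (p.mean() / np.sqrt(150))
        assert np.abs(z).max() < 5.0

    def test_sine_argmax_at_tone(self):
        t = np.arange(int(4 * FS)) / FS
        psd = _psd_of(np.sin(2 * np.pi * 20 * t))
        assert psd.freqs[np.argmax(psd.power)] == 20.0

    def test_parseval_sine_power(self):
        t = np.arange(int(4 * FS)) / FS
        for amp in (1.0, 3.0):
            psd = _psd_of(amp * np.sin(2 * np.pi * 40 * t))
            total = np.sum(psd.power) * 0.5  # density x bin width
            assert total == pytest.approx(amp ** 2 / 2, rel=0.05)

    def test_short_site_marked_excluded(self):
        psd = _psd_of(np.zeros(int(2.5 * FS)))
        assert psd.excluded and "too_short" in psd.flags

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError, match="fmax"):
            spectral.welch_psd(np.zeros(4096), 256.0, fmax=200.0)


class TestLineNoiseRepair:
    def _flat_with_spike(self):
        freqs = np.arange(0, 200.5, 0.5)
        power = np.ones_like(freqs)
        power[freqs == 50.0] = 100.0
        return SitePSD(freqs=freqs, power=power)

    def test_spike_replaced_by_neighbors(self):
        out = spectral.repair_line_noise(self._flat_with_spike())
        assert out.power[out.freqs == 50.0][0] == pytest.approx(1.0)

    def test_flat_spectrum_unchanged(self):
        freqs = np.arange(0, 200.5, 0.5)
        psd = SitePSD(freqs=freqs, power=np.full_like(freqs, 2.0))
        out = spectral.repair_line_noise(psd)
        np.testing.assert_allclose(out.power, 2.0)

    def test_all_harmonics_up_to_fmax_repaired(self):
        freqs = np.arange(0, 200.5, 0.5)
        power = np.ones_like(freqs)
        for h in (50, 100, 150, 200):
            power[np.abs(freqs - h) <= 2.0] = 77.0
        out = spectral.repair_line_noise(SitePSD(freqs=freqs, power=power))
        assert out.power.max() == pytest.approx(1.0)

    def test_idempotent(self):
        once = spectral.repair_line_noise(self._flat_with_spike())
        twice = spectral.repair_line_noise(once)
        np.testing.assert_array_equal(once.power, twice.power)


class TestNormalizeByFrequency:
    def test_two_bin_toy(self):
        psd = SitePSD(freqs=np.array([10.0, 20.0]), power=np.array([3.0, 1.0]))
        out = spectral.normalize_by_frequency(psd)
        np.testing.assert_allclose(out.power, [0.75, 0.25])

    def test_sums_to_one_and_scale_invariant(self, rng):
        psd = _psd_of(rng.standard_normal(int(4 * FS)))
        out1 = spectral.normalize_by_frequency(psd)
        out2 = spectral.normalize_by_frequency(psd.copy_with(power=psd.power * 7.3))
        mask = spectral.band_slice(out1.freqs, 3, 200)
        assert out1.power[mask].sum() == pytest.approx(1.0)
        np.testing.assert_allclose(out1.power, out2.power)


class TestNormalizeByDistance:
    def _traj(self, rng, n=14):
        freqs = np.arange(3, 70.5, 0.5)
        return [SitePSD(freqs=freqs,
                        power=2.0 + rng.standard_normal(freqs.size))
                for _ in range(n)]

    def test_site_at_baseline_mean_maps_to_zero(self, rng):
        psds = self._traj(rng)
        base = np.mean([p.power for p in psds[:10]], axis=0)
        psds.append(SitePSD(freqs=psds[0].freqs, power=base))
        out = spectral.normalize_by_distance(psds)
        np.testing.assert_allclose(out[-1].power, 0.0, atol=1e-12)

    def test_known_zscore(self):
        freqs = np.array([10.0])
        base = [SitePSD(freqs=freqs, power=np.array([v]))
                for v in [1.0, 3.0] * 5]  # mean 2, SD 1
        site = SitePSD(freqs=freqs, power=np.array([5.0]))
        out = spectral.normalize_by_distance(base + [site])
        assert out[-1].power[0] == pytest.approx(3.0)

    def test_baseline_self_normalizes_to_zero_mean(self, rng):
        out = spectral.normalize_by_distance(self._traj(rng))
        mean_z = np.mean([p.power for p in out[:10]], axis=0)
        np.testing.assert_allclose(mean_z, 0.0, atol=1e-10)


class TestCoherence:
    def test_identical_signals_fully_coherent(self, rng):
        x = rng.standard_normal(int(4 * FS))
        _, coh = spectral.coherence(x, x, FS)
        np.testing.assert_allclose(coh, 1.0)

    def test_independent_noise_bias_matches_estimator(self, rng):
        """Mean coherence of independent noises equals the Welch-estimator
        bias for three 50%-overlapped Hamming segments (~0.348, frozen from
        a Monte-Carlo of the estimator)."""
        means = [spectral.coherence(rng.standard_normal(int(4 * FS)),
                                    rng.standard_normal(int(4 * FS)),
                                    FS)[1].mean() for _ in range(100)]
        assert np.mean(means) == pytest.approx(0.348, abs=0.015)

    def test_shared_tone_peaks_at_tone(self, rng):
        t = np.arange(int(4 * FS)) / FS
        tone = np.sin(2 * np.pi * 20 * t)
        f, coh = spectral.coherence(tone + rng.standard_normal(t.size),
                                    tone + rng.standard_normal(t.size), FS)
        assert f[np.argmax(coh)] == 20.0

    def test_invariant_to_rescaling(self, rng):
        x = rng.standard_normal(int(4 * FS))
        y = rng.standard_normal(int(4 * FS))
        _, c1 = spectral.coherence(x, y, FS)
        _, c2 = spectral.coherence(5 * x, 0.1 * y, FS)
        np.testing.assert_allclose(c1, c2, atol=1e-12)


class TestSpectrogram:
    def test_normalized_distance_mapping(self):
        freqs = np.arange(3, 70.5, 0.5)
        psds = [SitePSD(freqs=freqs, power=np.ones_like(freqs))
                for _ in range(3)]
        sg = spectral.build_spectrogram(
            psds, depths_mm=np.array([-1.0, 0.0, 2.5]),
            entry_mm=0.0, exit_mm=5.0)
        np.testing.assert_allclose(sg.nd, [-0.2, 0.0, 0.5])

    def test_exit_before_entry_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            spectral.build_spectrogram([], np.array([]), 5.0, 2.0)
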