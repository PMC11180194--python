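#!/usr/bin/env python
"""Brown-noise / beta / spiking simulations and their averaged spectra.

Reproduces the signal-level findings: the Brown-noise exponent (~2), the
white-noise exponent (~0), the preservation of the 20 Hz beta center
frequency under full-wave rectification, and the reinstatement of the
20 Hz discharge-rate peak after band-passing (300-2000 Hz) and rectifying
the spiking simulation.  Writes results/signal_simulations.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from stnio import betafeat, specparam, synthsig
from stnio.synthsig import SimSignalConfig

FS = 4096.0


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n", type=int, default=1000)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    rng = np.random.default_rng(args.seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=args.n)

    rows = []

    brown, rect_lfp = [], []
    for s in seeds:
        out = synthsig.simulate_brown_beta(SimSignalConfig(seed=int(s)))
        brown.append(out["brown"])
        rect_lfp.append(out["rectified_beta_modulated"])
    f, logp = synthsig.averaged_periodogram(brown, FS)
    fit = specparam.fit_spectrum(f, 10 ** logp)
    rows.append(("brown_noise_exponent", fit.exponent))

    white = [rng.standard_normal(4096) for _ in range(args.n)]
    f, logp = synthsig.averaged_periodogram(white, FS)
    rows.append(("white_noise_exponent",
                 specparam.fit_spectrum(f, 10 ** logp).exponent))

    f, logp = synthsig.averaged_periodogram(rect_lfp, FS)
    rows.append(("rectified_lfp_beta_cf_hz",
                 betafeat.detect_beta_cf(f, logp).beta_cf))

    rect_spk, bandpassed = [], []
    for s in seeds:
        sp = synthsig.simulate_spiking(SimSignalConfig(seed=int(s)))
        rect_spk.append(sp["rectified_spk"])
        bandpassed.append(sp["bandpassed"])
    f, logp = synthsig.averaged_periodogram(rect_spk, FS)
    band = (f >= 3) & (f <= 70)
    rows.append(("rectified_spk_peak_hz", f[band][np.argmax(logp[band])]))
    _, logp_bp = synthsig.averaged_periodogram(bandpassed, FS)
    rows.append(("bandpassed_20hz_excess_log10",
                 logp_bp[f == 20.0][0] - np.median(logp_bp[band])))

    df = pd.DataFrame(rows, columns=["quantity", "value"])
    args.out.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out / "signal_simulations.csv", index=False)
    print(df.to_string(index=False))
    print("\nThe Brown/white exponents bracket the LFP/SPK aperiodic "
          "regimes; rectification reinstates the 20 Hz rate oscillation "
          "that band-passing removed.")


if __name__ == "__main__":
    main()
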