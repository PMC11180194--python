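#!/usr/bin/env python
"""Goodness-of-fit of the spectral parameterization across exponent and
noise levels.

Simulates log-log-linear spectra (exponent -0.25..2.25, offset = exponent,
noise calibrated to MAE targets 0.005..0.145, 20 repeats per cell), with
and without the three standard Gaussian peaks, fits every spectrum, and
tabulates atanh-averaged R2 and mean MAE per cell.  Writes
results/goodness_surface.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from stnio import specparam, synthsig


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=50)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    frames = []
    for peaks, label in ((None, "peak_free"),
                         (synthsig.PAPER_TEST_PEAKS, "with_peaks")):
        cfg = synthsig.SpectrumSimConfig(seed=args.seed, peaks=peaks)
        surf = specparam.goodness_surface(synthsig.simulate_test_spectra(cfg))
        surf["variant"] = label
        frames.append(surf)
    surf = pd.concat(frames, ignore_index=True)
    args.out.mkdir(parents=True, exist_ok=True)
    surf.to_csv(args.out / "goodness_surface.csv", index=False)

    free = frames[0]
    mid = free[free.target_mae.between(0.06, 0.07)]
    print("Peak-free mean R2 by exponent (noise ~0.065):")
    print(mid[["exponent", "r2_mean", "mae_mean"]].to_string(index=False))
    a0 = free[free.exponent == 0].r2_mean.mean()
    a0p = frames[1][frames[1].exponent == 0].r2_mean.mean()
    print(f"\nR2 at exponent 0: {a0:.2f} peak-free vs {a0p:.2f} with peaks "
          "- periodic structure rescues the fit where the aperiodic slope "
          "carries no variance; MAE stays at the injected noise level "
          "throughout.")


if __name__ == "__main__":
    main()
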