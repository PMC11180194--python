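#!/usr/bin/env python
"""Generate the synthetic study cohort.

Writes the recordings container (HDF5), manifest, clinical table and
ground-truth sidecar under scratch/study/.  The generator draws one LFP and
one SPK aperiodic exponent per trajectory (around 2.20 and 0.11), one LFP
beta center frequency in the high-beta range and a downshifted SPK beta
center frequency, and builds 4-s sites along each trajectory (10 pre-STN
sites at 400 um steps, then 100 um steps through the STN motor and
non-motor subregions).
"""

import argparse
from pathlib import Path

from stnio import cohort


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=2024)
    ap.add_argument("--patients", type=int, default=30)
    ap.add_argument("--out", type=Path, default=Path("scratch/study"))
    args = ap.parse_args()

    cfg = cohort.SyntheticStudyConfig(n_patients=args.patients,
                                      seed=args.seed)
    sites, clinical, truth = cohort.simulate_study(cfg)
    paths = cohort.save_study(args.out, sites, clinical, truth)

    n_traj = len(truth["trajectories"])
    print(f"wrote {len(sites)} sites across {n_traj} trajectories "
          f"({args.patients} patients) to {args.out}")
    print(f"clinical table: {len(clinical)} patients -> {paths['clinical']}")
    print(f"ground truth sidecar: {paths['truth']}")


if __name__ == "__main__":
    main()
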