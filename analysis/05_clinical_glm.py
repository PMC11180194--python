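#!/usr/bin/env python
"""Predictor-family GLMs of clinical burden and treatment response.

Joins the patient-level neuronal features from the pipeline with the
clinical table, derives the LFP-SPK difference predictors, and fits every
available predictor family at zeroth, first and higher interaction order
against every response, reporting R2, AIC and model p-values.  Writes
results/glm_results.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from stnio import clinstats
from stnio.cohort import RESPONSE_COLUMNS


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--clinical", type=Path,
                    default=Path("scratch/study/clinical.csv"))
    ap.add_argument("--features", type=Path,
                    default=Path("results/pipeline/features.csv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    clinical = pd.read_csv(args.clinical)
    clinical["patient"] = [f"P{i:03d}" for i in range(len(clinical))]
    features = pd.read_csv(args.features)
    table = clinical.merge(features, on="patient", how="inner")
    table = clinstats.derive_difference_columns(table)

    rows = []
    for family, members in clinstats.FAMILIES.items():
        if any(m not in table.columns for m in members):
            continue
        for response in RESPONSE_COLUMNS:
            for order in ("zeroth", "first", "higher"):
                try:
                    res = clinstats.fit_family(table, family, response, order)
                except ValueError:
                    continue
                rows.append({
                    "family": family, "response": response, "order": order,
                    "r2": res.r_squared, "aic": res.aic,
                    "model_p": res.model_p, "n_obs": res.n_obs,
                })
    out = pd.DataFrame(rows)
    args.out.mkdir(parents=True, exist_ok=True)
    out.to_csv(args.out / "glm_results.csv", index=False)

    best = out.loc[out.groupby("response")["aic"].idxmin()]
    print("Lowest-AIC model per response:")
    print(best[["response", "family", "order", "r2", "aic"]]
          .round(3).to_string(index=False))
    print(f"\n{len(out)} fits -> {args.out / 'glm_results.csv'}")


if __name__ == "__main__":
    main()
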