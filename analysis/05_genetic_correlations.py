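#!/usr/bin/env python
"""Genetic and phenotypic correlations for the simulated cohort.

Continuous trait pairs are fitted with the bivariate REML animal
model; any pair involving a manual (ordinal) score falls back to the
Pearson correlation of liability-scale and trait-scale EBVs — exactly
the split used for the published correlation table.  A representative
subset of pairs keeps the run short; edit PAIRS to fit more.
Run 01_simulate_cohort.py and 04_genetic_parameters.py first
(the EBV file feeds the fallback).
Output: results/correlations_table5.csv
"""

from pathlib import Path

import numpy as np
import pandas as pd

from shrimpqg import study_params as sp_
from shrimpqg.linear_mixed_model import EBVSet, fit_bivariate, read_phenotype_csv
from shrimpqg.pedigree import read_pedigree_csv
from shrimpqg.threshold_model import ebv_correlation

SIM = Path("results/simulated")
OUT = Path("results")

#: trait pairs to estimate (ordinal-involved pairs use the EBV fallback)
PAIRS = [
    ("manual_uncooked", "manual_cooked"),
    ("manual_uncooked", "L_uncooked"),
    ("manual_cooked", "a_cooked"),
    ("L_uncooked", "L_cooked"),
    ("b_uncooked", "L_uncooked"),
    ("a_uncooked", "a_cooked"),
    ("body_weight", "body_length"),
    ("body_weight", "L_cooked"),
]


def main() -> None:
    ped = read_pedigree_csv(SIM / "pedigree.csv")
    phenos = read_phenotype_csv(SIM / "phenotypes.csv")
    ebv_df = pd.read_csv(OUT / "ebv.csv")
    ebvs = {
        t: EBVSet(t, dict(zip(ebv_df["animal"].astype(str), ebv_df[t])))
        for t in ebv_df.columns
        if t != "animal"
    }
    rows = []
    for tx, ty in PAIRS:
        true_rg = sp_.genetic_correlation(tx, ty)
        if tx in sp_.ORDINAL_TRAITS or ty in sp_.ORDINAL_TRAITS:
            rg = ebv_correlation(ebvs[tx], ebvs[ty])
            method, rp, se = "ebv_pearson", np.nan, np.nan
        else:
            ce = fit_bivariate(phenos, (tx, ty), ped)
            rg, rp, se, method = ce.rg, ce.rp, ce.se_rg, "bivariate_reml"
        rows.append(
            dict(trait_x=tx, trait_y=ty, method=method, rg=round(rg, 2),
                 se_rg=round(se, 2) if np.isfinite(se) else "", rp=round(rp, 2)
                 if np.isfinite(rp) else "", true_rg=true_rg)
        )
        print(f"{tx:>16} x {ty:<16} {method:>14}: rg = {rg:+.2f}  "
              f"[generating value {true_rg:+.2f}]")
    pd.DataFrame(rows).to_csv(OUT / "correlations_table5.csv", index=False)
    print(f"\nEBV-based estimates are attenuated toward zero relative to the")
    print(f"generating rg (limited EBV reliability at h2 ~ 0.12); the")
    print(f"bivariate-REML estimates are approximately unbiased.")
    print(f"written to {OUT}/correlations_table5.csv")


if __name__ == "__main__":
    main()
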