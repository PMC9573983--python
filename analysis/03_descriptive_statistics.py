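#!/usr/bin/env python
"""Descriptive statistics of the simulated cohort.

Per-trait n / mean / SD / CV% / min / max for the continuous traits and
the category distribution (overall and per pond) for the two manual
colour scores.  Run 01_simulate_cohort.py first.
Outputs: results/summary_table1.csv, results/score_distribution_table2.csv
"""

from pathlib import Path

from shrimpqg import study_params as sp_
from shrimpqg.cli_pipeline import score_distribution
from shrimpqg.linear_mixed_model import read_phenotype_csv, summarize_table1

import pandas as pd

SIM = Path("results/simulated")
OUT = Path("results")


def main() -> None:
    phenos = read_phenotype_csv(SIM / "phenotypes.csv")
    continuous = [t for t in sp_.TRAITS if t not in sp_.ORDINAL_TRAITS]
    t1 = summarize_table1(phenos, continuous)
    t1["cv_pct"] = t1["cv_pct"].round(1)
    t1.to_csv(OUT / "summary_table1.csv", index=False, float_format="%.6g")
    print(t1.to_string(index=False))

    parts = [
        score_distribution(phenos, t, c) for t, c in sp_.ORDINAL_TRAITS.items()
    ]
    t2 = pd.concat(parts, ignore_index=True)
    t2.to_csv(OUT / "score_distribution_table2.csv", index=False, float_format="%.6g")
    overall = t2[t2["pond"] == "all"]
    print("\nscore distribution (all ponds):")
    print(overall.to_string(index=False))
    print(f"\nwritten to {OUT}/summary_table1.csv and {OUT}/score_distribution_table2.csv")


if __name__ == "__main__":
    main()
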