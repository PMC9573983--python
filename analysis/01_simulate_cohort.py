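#!/usr/bin/env python
"""Simulate the study cohort and write it out.

Generates a pedigree with 55 sires x 52 dams, 67 full-/half-sib
families and 838 progeny in 7 ponds, then draws breeding values,
pond effects and phenotypes for the ten traits (two ordinal colour
scores, six colorimetric traits, body weight and length) under the
published variance components and correlations.
Outputs: results/simulated/{pedigree,phenotypes,true_breeding_values}.csv
"""

from pathlib import Path

from shrimpqg.linear_mixed_model import write_phenotype_csv
from shrimpqg.pedigree import write_pedigree_csv
from shrimpqg.synthetic_data import default_config, simulate_dataset

SEED = 20220838
OUT = Path("results/simulated")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = default_config(seed=SEED)
    ds = simulate_dataset(cfg)
    write_pedigree_csv(ds.pedigree, OUT / "pedigree.csv")
    write_phenotype_csv(ds.phenotypes, OUT / "phenotypes.csv")
    ds.true_breeding_values.reset_index().to_csv(
        OUT / "true_breeding_values.csv", index=False, float_format="%.6g"
    )
    s = ds.pedigree.summary()
    print(
        f"simulated cohort: {s['n_animals']} animals "
        f"({s['n_sires']} sires, {s['n_dams']} dams, {s['n_progeny']} progeny)"
    )
    print(f"phenotyped progeny: {len(ds.phenotypes)} across "
          f"{ds.phenotypes['pond'].nunique()} ponds")
    print(f"written to {OUT}/")


if __name__ == "__main__":
    main()
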