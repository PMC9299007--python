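"""Compute regional recyclable stable-manure-carbon budgets.

Reads results/synthetic/manure.csv and converts each region's unapplied
manure-N surplus into a stable carbon supply (C:N 10, humification 0.5);
this supply caps the organic-fertilization measure in the upscaling step.
"""

from pathlib import Path

import pandas as pd

from socpotential.manure_budget import budget_table
from socpotential.pipeline import FLOAT_FORMAT

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    manure = pd.read_csv(ROOT / "synthetic" / "manure.csv")
    budgets = budget_table(manure)
    budgets.to_csv(ROOT / "budgets.csv", index=False, float_format=FLOAT_FORMAT)

    excreted_tg = manure["n_excreted"].sum() / 1e9
    surplus_tg = budgets["n_surplus_kg"].sum() / 1e9
    stable_mton = budgets["stable_c_supply_mton"].sum()
    print(f"excretion {excreted_tg:.1f} Tg N/yr; surplus {surplus_tg:.2f} Tg N/yr "
          f"({100 * surplus_tg / excreted_tg:.1f}% unrecycled)")
    print(f"stable manure-C supply {stable_mton:.1f} Mton C/yr across {len(budgets)} regions")
    print(f"wrote {ROOT / 'budgets.csv'}")


if __name__ == "__main__":
    main()
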