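"""Stratify the synthetic cropland and tabulate per-measure eligible areas.

Reads results/synthetic/cells.csv, classifies cells into management-climate
strata (keeping region for the later manure cap), writes the stratum table
and composition shares, and prints the area eligible for each measure.
"""

import json
from pathlib import Path

import pandas as pd

from socpotential.meta_harmonize import MEASURES
from socpotential.pipeline import FLOAT_FORMAT
from socpotential.strata import classify_cells, eligible_area, summarize_shares

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cells = pd.read_csv(ROOT / "synthetic" / "cells.csv")
    strata = classify_cells(cells, by=("region_id",))
    strata.to_csv(ROOT / "strata.csv", index=False, float_format=FLOAT_FORMAT)
    shares = summarize_shares(strata)
    (ROOT / "shares.json").write_text(json.dumps(shares, indent=2, sort_keys=True))

    total = strata["area_ha"].sum()
    print(f"{len(strata)} strata; total area {total / 1e6:,.1f} Mha (conserved)")
    for m in MEASURES:
        area = eligible_area(strata, m)
        print(f"  {m}: eligible {area['area_ha'].sum() / 1e6:,.1f} Mha "
              f"via {sorted(set(area['intervention']))}")
    print(f"wrote {ROOT / 'strata.csv'} and shares.json")


if __name__ == "__main__":
    main()
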