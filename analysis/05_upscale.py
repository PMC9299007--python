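"""Upscale pooled effects over eligible areas with Monte-Carlo uncertainty.

Combines the pooled effect table (02), the stratum table (03) and the
manure budgets (04) into per-measure, per-zone sequestration potentials
with 0.01/0.99 Monte-Carlo bounds (n = 1000), caps organic fertilization
by the regional manure budget (M2 -> M2cor), and combines the five
measures under both complementarity rules.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from socpotential.meta_harmonize import MEASURES
from socpotential.pipeline import FLOAT_FORMAT, _scenario_dict
from socpotential.strata import eligible_area
from socpotential.upscale import (
    combine_max_complementarity,
    combine_rank_weighted,
    global_potentials,
    monte_carlo_potential,
)

SEED = 42
ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    strata = pd.read_csv(ROOT / "strata.csv")
    effects = pd.read_csv(ROOT / "effects.csv")
    budgets = pd.read_csv(ROOT / "budgets.csv")

    ss = np.random.SeedSequence(SEED)
    streams = dict(zip([*MEASURES, "M2cor"], ss.spawn(len(MEASURES) + 1)))
    tables = []
    m2_area = None
    for m in MEASURES:
        area = eligible_area(strata, m, by=("region_id", "climate"))
        if m == "M2":
            m2_area = area
        tables.append(
            monte_carlo_potential(
                area, effects, seed=np.random.default_rng(streams[m]), measure=m
            )
        )
    tables.append(
        monte_carlo_potential(
            m2_area, effects, seed=np.random.default_rng(streams["M2cor"]),
            cap_budget=budgets, measure="M2cor",
        )
    )
    potentials = pd.concat(tables, ignore_index=True)
    potentials.to_csv(ROOT / "potentials.csv", index=False, float_format=FLOAT_FORMAT)

    gp = global_potentials(potentials)
    scenarios = {
        "max_complementarity": _scenario_dict(combine_max_complementarity(gp)),
        "rank_weighted": _scenario_dict(combine_rank_weighted(gp)),
    }
    (ROOT / "scenarios.json").write_text(json.dumps(scenarios, indent=2, sort_keys=True))

    print("global potentials (Mton C/yr, mean [q01-q99]):")
    for m, row in gp.iterrows():
        print(f"  {m}: {row['mean_mton']:.0f} [{row['q01_mton']:.0f}-{row['q99_mton']:.0f}]")
    for rule, s in scenarios.items():
        print(f"  {rule}: {s['total_mton']:.0f} [{s['low_mton']:.0f}-{s['high_mton']:.0f}]")
    print(f"wrote {ROOT / 'potentials.csv'} and scenarios.json")


if __name__ == "__main__":
    main()
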