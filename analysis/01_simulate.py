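"""Generate the synthetic cropland world used by the downstream analyses.

Writes cells, manure and effect-record CSVs (plus the effect truth table)
under results/synthetic/ and reports the realized composition against the
configured global marginals (45% HT tillage, 8% NT, 25% residue burning,
72% rotations without catch crops, climate split 30/19/30/21).
"""

from pathlib import Path

from socpotential.pipeline import FLOAT_FORMAT
from socpotential.strata import classify_cells, summarize_shares
from socpotential.synthetic_data import (
    EffectGeneratorConfig,
    GeneratorConfig,
    ManureGeneratorConfig,
    generate_cells,
    generate_effect_records,
    generate_manure_records,
)

SEED = 42
OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cells = generate_cells(GeneratorConfig(n_cells=10_000, seed=SEED))
    manure = generate_manure_records(ManureGeneratorConfig(seed=SEED))
    records, truth = generate_effect_records(EffectGeneratorConfig(seed=SEED))

    for name, df in [
        ("cells.csv", cells),
        ("manure.csv", manure),
        ("effect_records.csv", records),
        ("effect_truth.csv", truth),
    ]:
        df.to_csv(OUT / name, index=False, float_format=FLOAT_FORMAT)

    total_mha = cells["area_ha"].sum() / 1e6
    print(f"generated {len(cells)} cells covering {total_mha:,.1f} Mha")
    shares = summarize_shares(classify_cells(cells))
    for dim, target in [
        (("tillage", "HT"), 0.45),
        (("tillage", "NT"), 0.08),
        (("residue_fate", "burned"), 0.25),
        (("rotation", "without_catch_crops"), 0.72),
        (("climate", "tropical"), 0.30),
        (("climate", "temperate"), 0.19),
    ]:
        got = shares[dim[0]][dim[1]]
        print(f"  {dim[0]}={dim[1]}: realized {got:.3f} (target {target:.2f})")
    print(f"wrote synthetic inputs to {OUT}")


if __name__ == "__main__":
    main()
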