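"""Regional budget of recyclable animal-manure carbon.

Applying manure that is already recycled onto cropland moves carbon around
rather than sequestering it, so the organic-fertilization measure is capped
by the supply of manure that is *not* yet applied anywhere.  The surplus N
per region is excretion minus application on cropland and on grassland
(including grazing deposits); manure burned as fuel or wasted is part of
the surplus.  Surplus N converts to stable carbon input via a C:N ratio of
the organic fraction (default 10, between slurry ~8 and solid manure ~15)
and a humification coefficient (default 0.5) — the fraction of applied
organic C not decomposed within one year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AlignmentError

DEFAULT_CN_RATIO = 10.0
DEFAULT_HUMIFICATION = 0.5
#: 1 Mton = 1e6 tonnes = 1e9 kg
KG_PER_MTON = 1e9


@dataclass(frozen=True)
class ManureBudget:
    """Recyclable stable-manure-carbon supply of one region (kg yr^-1)."""

    region_id: str
    n_surplus: float
    c_surplus: float
    stable_c_supply: float
    cn_ratio: float = DEFAULT_CN_RATIO
    humification_coefficient: float = DEFAULT_HUMIFICATION


def recyclable_manure_c(
    record,
    cn_ratio: float = DEFAULT_CN_RATIO,
    hc: float = DEFAULT_HUMIFICATION,
) -> ManureBudget:
    """Budget for one region record with fields n_excreted,
    n_applied_cropland, n_applied_grassland (kg N yr^-1).

    The N surplus is clamped at zero: a region applying more than it
    excretes (e.g. manure imports) supplies no additional carbon.
    """
    if cn_ratio <= 0:
        raise ValueError(f"cn_ratio must be positive, got {cn_ratio}")
    if not 0 < hc <= 1:
        raise ValueError(f"humification coefficient must be in (0, 1], got {hc}")
    excreted = float(record["n_excreted"])
    cropland = float(record["n_applied_cropland"])
    grassland = float(record["n_applied_grassland"])
    if min(excreted, cropland, grassland) < 0:
        raise ValueError("manure N quantities must be non-negative")
    n_surplus = max(0.0, excreted - cropland - grassland)
    c_surplus = n_surplus * cn_ratio
    return ManureBudget(
        region_id=str(record.get("region_id", "")),
        n_surplus=n_surplus,
        c_surplus=c_surplus,
        stable_c_supply=c_surplus * hc,
        cn_ratio=cn_ratio,
        humification_coefficient=hc,
    )


def budget_table(
    records: pd.DataFrame,
    cn_ratio: float = DEFAULT_CN_RATIO,
    hc: float = DEFAULT_HUMIFICATION,
) -> pd.DataFrame:
    """Vectorized :func:`recyclable_manure_c` over a region table.

    Input columns: region_id, n_excreted, n_applied_cropland,
    n_applied_grassland (kg N yr^-1).  Output adds n_surplus_kg,
    c_surplus_kg, stable_c_supply_kg and stable_c_supply_mton.
    """
    budgets = [
        recyclable_manure_c(row, cn_ratio, hc) for _, row in records.iterrows()
    ]
    return pd.DataFrame(
        {
            "region_id": [b.region_id for b in budgets],
            "n_surplus_kg": [b.n_surplus for b in budgets],
            "c_surplus_kg": [b.c_surplus for b in budgets],
            "stable_c_supply_kg": [b.stable_c_supply for b in budgets],
            "stable_c_supply_mton": [b.stable_c_supply / KG_PER_MTON for b in budgets],
        }
    )


def cap_measure_potential(raw_potential, budget):
    """Cap a raw sequestration potential by the stable-manure-C supply.

    Scalar form: ``min(raw, budget)`` with both in Mton C yr^-1.

    Table form: ``raw_potential`` is a DataFrame with columns
    (region_id[, climate], potential_mton) and ``budget`` a DataFrame with
    (region_id, stable_c_supply_mton).  The cap is applied per region —
    capping after zone aggregation would double-count surplus across
    regions — scaling each region's climate sub-potentials proportionally
    when the regional total exceeds its budget.
    """
    if np.isscalar(raw_potential):
        if raw_potential < 0:
            raise ValueError("raw potential must be non-negative")
        return min(float(raw_potential), float(budget))

    raw = raw_potential.copy()
    bud = budget.set_index("region_id")["stable_c_supply_mton"]
    regions = raw["region_id"].unique()
    missing = set(regions) - set(bud.index)
    if missing:
        raise AlignmentError(f"regions without a manure budget: {sorted(missing)}")
    totals = raw.groupby("region_id")["potential_mton"].sum()
    scale = pd.Series(1.0, index=totals.index)
    over = totals > 0
    scale[over] = np.minimum(1.0, bud.reindex(totals.index)[over] / totals[over])
    raw["potential_mton"] = raw["potential_mton"] * raw["region_id"].map(scale).astype(float)
    return raw
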