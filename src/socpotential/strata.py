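"""Classify cropland cells into management-climate strata and derive eligible areas.

A cropland "cell" is a tabular unit of area carrying its climate zone and
current management: inorganic-N fertilization rate, applied manure-N rate,
tillage intensity, rotation type and crop-residue fate.  Cells are
classified into strata (fertilization class x manure class x the categorical
attributes), and each management measure is mapped to the area where its
intervention could still be adopted — e.g. only high-intensity-tillage area
is eligible for conversion to no-till.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import NoDataError

logger = logging.getLogger(__name__)

TILLAGE_CLASSES = ("NT", "IT", "HT")
ROTATION_CLASSES = ("with_catch_crops", "without_catch_crops")
RESIDUE_CLASSES = ("incorporated", "burned", "removed")
FERT_CLASSES = ("none", "medium", "high")
MANURE_CLASSES = ("low", "high")

CELL_COLUMNS = [
    "region_id",
    "climate",
    "area_ha",
    "n_fert_rate",
    "n_manure_rate",
    "tillage",
    "rotation",
    "residue_fate",
]

STRATUM_KEYS = ["climate", "fert_class", "manure_class", "tillage", "rotation", "residue_fate"]


@dataclass(frozen=True)
class ClassThresholds:
    """N-input cut-offs (kg N ha^-1 yr^-1) separating management classes.

    Unfertilized cropland is defined by total mineral-N input below 40; the
    40-100 band is "medium" and above 100 "high".  Manure input below 40
    marks the low-manure class.  Lower class edges are inclusive.
    """

    fert_none_max: float = 40.0  # none: [0, 40)
    fert_medium_max: float = 100.0  # medium: [40, 100]; high: (100, inf)
    manure_high_min: float = 40.0  # high manure: >= 40


DEFAULT_THRESHOLDS = ClassThresholds()


def classify_cell(cell, thresholds: ClassThresholds = DEFAULT_THRESHOLDS) -> tuple[str, str]:
    """Return (fert_class, manure_class) for one cell (mapping or Series)."""
    fert = float(cell["n_fert_rate"])
    manure = float(cell["n_manure_rate"])
    if fert < 0 or manure < 0:
        raise ValueError("N input rates must be non-negative")
    if fert < thresholds.fert_none_max:
        fert_class = "none"
    elif fert <= thresholds.fert_medium_max:
        fert_class = "medium"
    else:
        fert_class = "high"
    manure_class = "high" if manure >= thresholds.manure_high_min else "low"
    return fert_class, manure_class


def classify_cells(
    cells: pd.DataFrame,
    thresholds: ClassThresholds = DEFAULT_THRESHOLDS,
    by: Sequence[str] = (),
) -> pd.DataFrame:
    """Partition cells into strata and aggregate area.

    Every cell maps to exactly one stratum, so the stratum areas sum to the
    cell areas exactly.  Cells with missing attributes are dropped with a
    logged count rather than imputed.

    Parameters
    ----------
    by:
        Extra grouping columns retained in the stratum table (e.g.
        ``("region_id",)`` for region-level manure capping).
    """
    missing_cols = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing_cols:
        raise ValueError(f"cell table missing columns: {missing_cols}")
    df = cells.copy()
    complete = df[CELL_COLUMNS].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("dropping %d cells with missing attributes", n_dropped)
        df = df[complete]
    if (df["area_ha"] < 0).any():
        raise ValueError("area_ha must be non-negative")
    for col, allowed in [
        ("climate", ("temperate", "subtropical", "tropical", "other")),
        ("tillage", TILLAGE_CLASSES),
        ("rotation", ROTATION_CLASSES),
        ("residue_fate", RESIDUE_CLASSES),
    ]:
        bad = set(df[col]) - set(allowed)
        if bad:
            raise ValueError(f"unknown {col} labels: {sorted(bad)}")

    classes = df.apply(classify_cell, axis=1, args=(thresholds,), result_type="expand")
    df = df.assign(fert_class=classes[0], manure_class=classes[1])
    keys = list(by) + STRATUM_KEYS
    strata = df.groupby(keys, as_index=False, sort=True, observed=True)["area_ha"].sum()
    return strata


# measure -> (stratum predicate column rules, intervention) assignments
_MEASURE_RULES = {
    "M1": [({"fert_class": ("none",)}, "IF-NF")],
    "M2": [
        ({"fert_class": ("none",)}, "OF-NF"),
        ({"fert_class": ("medium", "high"), "manure_class": ("low",)}, "OF-IF"),
    ],
    "M3": [
        ({"tillage": ("HT",)}, "NT-HT"),
        ({"tillage": ("IT",)}, "NT-IT"),
    ],
    "M4": [({"rotation": ("without_catch_crops",)}, "CC")],
    "M5": [({"residue_fate": ("burned", "removed")}, "CRES")],
}


def eligible_area(
    strata: pd.DataFrame, measure: str, by: Sequence[str] = ("climate",)
) -> pd.DataFrame:
    """Area where a measure's intervention can still be adopted.

    Returns a table with columns ``by + (intervention, area_ha)``.  The rules
    follow the adoption logic: inorganic fertilization on currently
    unfertilized land (IF-NF), organic fertilization on unfertilized (OF-NF)
    or fertilized low-manure land (OF-IF), no-till on current high- (NT-HT)
    and intermediate-intensity (NT-IT) tillage, catch crops on rotations
    without them (CC), and residue incorporation where residues are burned
    or removed (CRES).  The returned rows partition the eligible subset.
    """
    if measure not in _MEASURE_RULES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {sorted(_MEASURE_RULES)}")
    pieces = []
    for rule, intervention in _MEASURE_RULES[measure]:
        mask = pd.Series(True, index=strata.index)
        for col, allowed in rule.items():
            mask &= strata[col].isin(allowed)
        sub = strata[mask]
        if sub.empty:
            continue
        agg = sub.groupby(list(by), as_index=False, observed=True)["area_ha"].sum()
        agg.insert(len(by), "intervention", intervention)
        pieces.append(agg)
    if not pieces:
        return pd.DataFrame(columns=[*by, "intervention", "area_ha"])
    return pd.concat(pieces, ignore_index=True)


SHARE_DIMENSIONS = ("climate", "tillage", "rotation", "residue_fate", "fert_class", "manure_class")


def summarize_shares(strata: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Area-weighted composition along each classification dimension.

    Returns ``{dimension: {label: fraction}}``; fractions along each
    dimension sum to one.
    """
    total = float(strata["area_ha"].sum())
    if not total > 0:
        raise NoDataError("total stratum area is zero; shares are undefined")
    report = {}
    for dim in SHARE_DIMENSIONS:
        if dim not in strata.columns:
            continue
        shares = strata.groupby(dim, observed=True)["area_ha"].sum() / total
        report[dim] = {str(k): float(v) for k, v in shares.items()}
    return report
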