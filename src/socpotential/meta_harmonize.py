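"""Harmonize meta-analytical SOC effect sizes and pool them per intervention and climate.

Meta-studies report soil-organic-carbon (SOC) responses to improved cropland
management in heterogeneous metrics: total or annual stock changes
(t C ha^-1, t C ha^-1 yr^-1) and total or annual concentration changes
(g C kg^-1, g C kg^-1 yr^-1), with variation given as SD, SE or a 95% CI —
or not at all.  This module converts every record to an annual stock change
with a standard error and combines records that cover the same
intervention x climate cell with fixed-effect inverse-variance weighting.

Conventions
-----------
* Concentration changes are converted to stocks as
  ``depth (m) x bulk density (kg m^-3) x dSOC (g kg^-1)`` giving g C m^-2,
  and 1 g C m^-2 = 0.01 t C ha^-1.
* Total changes are normalized to annual rates by dividing by a reference
  duration of 20 years (the median duration across meta-studies); SOC
  accumulation is assumed linear over that horizon.
* Missing variation is imputed from an SD equal to 1.25 times the average
  coefficient of variation of the record's intervention x climate group.
* The "other" climate entry of the pooled table is the inverse-variance
  combination of the zone-level pooled effects; it serves as the fallback
  when a climate zone has no data of its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ImputationUnavailableError, NoDataError

#: default topsoil bulk density (kg m^-3) used when no site value is known
DEFAULT_BULK_DENSITY = 1400.0
#: default sampling depth (m) of the harmonized topsoil layer
DEFAULT_DEPTH_M = 0.3
#: reference duration (yr) used to annualize total stock changes
REFERENCE_DURATION_YR = 20.0
#: full width of a symmetric normal 95% interval in SE units (2 x 1.96)
CI95_WIDTH_IN_SE = 3.92
#: inflation applied to the group-average CV when imputing a missing SD
CV_INFLATION = 1.25

MEASURES = ("M1", "M2", "M3", "M4", "M5")

#: intervention (treatment minus control contrast) -> management measure
INTERVENTION_MEASURE: Mapping[str, str] = {
    "IF-NF": "M1",
    "OF-NF": "M2",
    "OF-IF": "M2",
    "COF-NF": "M2",
    "COF-IF": "M2",
    "CRF-NF": "M2",
    "IT-HT": "M3",
    "NT-HT": "M3",
    "NT-IT": "M3",
    "C": "M4",
    "CC": "M4",
    "CCP": "M4",
    "CRES": "M5",
}

CLIMATE_ZONES = ("temperate", "subtropical", "tropical")
CLIMATES = CLIMATE_ZONES + ("other",)

METRICS = ("stock_total", "stock_annual", "conc_total", "conc_annual")
VARIATION_KINDS = ("SD", "SE", "CI95")

#: callable (record row -> bulk density kg m^-3); site lookups plug in here
BulkDensityProvider = Callable[[pd.Series], float]


def constant_bulk_density(value: float = DEFAULT_BULK_DENSITY) -> BulkDensityProvider:
    """Return a provider that assigns one bulk density to every record."""
    if value <= 0:
        raise ValueError(f"bulk density must be positive, got {value}")
    return lambda _record: value


@dataclass(frozen=True)
class PooledEffect:
    """Inverse-variance combined annual SOC stock change for one cell."""

    intervention: str
    climate: str
    mean: float  # t C ha^-1 yr^-1
    se: float  # t C ha^-1 yr^-1
    k_studies: int


def concentration_to_stock(
    delta_conc: float, bulk_density: float = DEFAULT_BULK_DENSITY, depth: float = DEFAULT_DEPTH_M
) -> float:
    """Convert a SOC concentration change (g C kg^-1) to a stock change (t C ha^-1).

    depth (m) x bulk density (kg m^-3) x concentration (g kg^-1) gives
    g C m^-2; one g C m^-2 equals 0.01 t C ha^-1.  Sign is preserved.
    """
    bulk_density = float(bulk_density)
    depth = float(depth)
    if bulk_density <= 0:
        raise ValueError(f"bulk density must be positive, got {bulk_density}")
    if depth <= 0:
        raise ValueError(f"depth must be positive, got {depth}")
    return depth * bulk_density * float(delta_conc) * 0.01


def annualize(total_change: float, duration: float = REFERENCE_DURATION_YR) -> float:
    """Convert a total stock change to an annual rate by linear division."""
    duration = float(duration)
    if duration <= 0:
        raise ValueError(f"duration must be positive, got {duration}")
    return float(total_change) / duration


def se_from_sd(sd: float, n_pairs: int) -> float:
    """Standard error from a standard deviation: SE = SD / sqrt(n)."""
    if n_pairs < 1:
        raise ValueError(f"n_pairs must be >= 1, got {n_pairs}")
    if sd < 0:
        raise ValueError(f"sd must be non-negative, got {sd}")
    return float(sd) / math.sqrt(n_pairs)


def se_from_ci(lower: float, upper: float) -> float:
    """Standard error from a symmetric normal 95% CI: SE = width / 3.92."""
    if upper < lower:
        raise ValueError(f"upper CI bound {upper} below lower bound {lower}")
    return (float(upper) - float(lower)) / CI95_WIDTH_IN_SE


def impute_sd(mean: float, avg_cv_of_group: float, inflation: float = CV_INFLATION) -> float:
    """Impute a missing SD as ``inflation x group-average CV x |mean|``."""
    if avg_cv_of_group < 0:
        raise ValueError(f"average CV must be non-negative, got {avg_cv_of_group}")
    return inflation * float(avg_cv_of_group) * abs(float(mean))


def pool_effects(
    means: Sequence[float],
    ses: Sequence[float],
    intervention: str = "",
    climate: str = "",
) -> PooledEffect:
    """Fixed-effect inverse-variance pooling of annual stock changes.

    Weights are w_i = 1 / SE_i^2; the pooled mean is sum(w_i x_i) / sum(w_i)
    and the pooled SE is sqrt(1 / sum(w_i)).  A single record passes through
    unchanged.  Zero SEs are rejected (infinite weight).
    """
    means = np.asarray(means, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if means.size == 0:
        raise NoDataError("cannot pool an empty set of records")
    if means.shape != ses.shape:
        raise ValueError("means and ses must have the same length")
    if np.any(ses <= 0):
        raise ValueError("all standard errors must be strictly positive for pooling")
    w = 1.0 / ses**2
    mean = float(np.sum(w * means) / np.sum(w))
    se = float(math.sqrt(1.0 / np.sum(w)))
    return PooledEffect(intervention, climate, mean, se, k_studies=int(means.size))


RECORD_COLUMNS = [
    "source_id",
    "measure",
    "intervention",
    "climate",
    "metric",
    "value",
    "variation_kind",
    "variation_value",
    "variation_value2",
    "n_pairs",
    "depth_m",
    "duration_yr",
]


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"effect-size records missing columns: {missing}")
    df = records.copy()
    bad_iv = set(df["intervention"]) - set(INTERVENTION_MEASURE)
    if bad_iv:
        raise ValueError(f"unknown interventions: {sorted(bad_iv)}")
    bad_cl = set(df["climate"]) - set(CLIMATES)
    if bad_cl:
        raise ValueError(f"unknown climates: {sorted(bad_cl)}")
    bad_me = set(df["metric"]) - set(METRICS)
    if bad_me:
        raise ValueError(f"unknown metrics: {sorted(bad_me)}")
    mismatch = df["measure"] != df["intervention"].map(INTERVENTION_MEASURE)
    if mismatch.any():
        rows = df.index[mismatch].tolist()
        raise ValueError(f"intervention inconsistent with measure at rows {rows}")
    if (df["depth_m"] <= 0).any():
        raise ValueError("depth_m must be positive for every record")
    is_total = df["metric"].isin(["stock_total", "conc_total"])
    dur = pd.to_numeric(df["duration_yr"], errors="coerce")
    if (is_total & ~(dur > 0)).any():
        raise ValueError("duration_yr must be positive when the metric is a total")
    return df


def _annualization_factor(
    row: pd.Series, bd_provider: BulkDensityProvider, reference_duration: float
) -> float:
    """Multiplier taking the record's reported units to t C ha^-1 yr^-1."""
    f = 1.0
    if row["metric"].startswith("conc"):
        f *= concentration_to_stock(1.0, bd_provider(row), row["depth_m"])
    if row["metric"].endswith("_total"):
        f /= reference_duration
    return f


def harmonize_records(
    records: pd.DataFrame,
    bd_provider: BulkDensityProvider | None = None,
    reference_duration: float = REFERENCE_DURATION_YR,
    cv_inflation: float = CV_INFLATION,
    allow_global_cv: bool = False,
) -> pd.DataFrame:
    """Convert raw effect-size records to annual stock changes with SEs.

    Returns one row per input record with columns
    (source_id, measure, intervention, climate, mean, se, n_pairs), where
    mean and se are in t C ha^-1 yr^-1.  The SE route follows, in order:
    SD with n (SE = SD/sqrt(n)), reported SE, 95% CI (width / 3.92), and
    finally CV-based imputation for records without reported variation.

    Parameters
    ----------
    allow_global_cv:
        When an intervention x climate group has no reported-variation record
        at all, fall back to the global average CV instead of raising
        :class:`ImputationUnavailableError`.
    """
    if bd_provider is None:
        bd_provider = constant_bulk_density()
    df = _validate_records(records)
    if df.empty:
        raise NoDataError("no effect-size records to harmonize")

    factors = df.apply(
        _annualization_factor, axis=1, args=(bd_provider, reference_duration)
    ).astype(float)
    mean = df["value"].astype(float) * factors
    n = pd.to_numeric(df["n_pairs"], errors="coerce")

    se = pd.Series(np.nan, index=df.index, dtype=float)
    for idx, row in df.iterrows():
        kind = row["variation_kind"]
        if pd.isna(kind) or kind == "":
            continue
        if kind not in VARIATION_KINDS:
            raise ValueError(f"unknown variation kind {kind!r} at row {idx}")
        f = factors.loc[idx]
        v1 = float(row["variation_value"])
        if kind == "SD":
            # SD route takes precedence whenever SD and n are both reported
            n_i = n.loc[idx]
            if not n_i >= 1:
                raise ValueError(f"SD variation requires n_pairs >= 1 at row {idx}")
            se.loc[idx] = se_from_sd(v1, int(n_i)) * f
        elif kind == "SE":
            if v1 < 0:
                raise ValueError(f"negative SE at row {idx}")
            se.loc[idx] = v1 * f
        else:  # CI95: variation_value = lower, variation_value2 = upper
            se.loc[idx] = se_from_ci(v1, float(row["variation_value2"])) * f

    # CV imputation for records without any reported variation.  CV is
    # scale-invariant, so it is computed on the harmonized annual scale.
    reported = se.notna()
    if not reported.all():
        n_eff = n.fillna(1).clip(lower=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = (se * np.sqrt(n_eff) / mean).abs()
        cv[mean == 0] = np.nan  # CV undefined at zero mean
        group_cv = cv.groupby([df["intervention"], df["climate"]]).transform("mean")
        global_cv = cv.mean()
        for idx in df.index[~reported]:
            avg_cv = group_cv.loc[idx]
            if pd.isna(avg_cv):
                if allow_global_cv and not pd.isna(global_cv):
                    avg_cv = global_cv
                else:
                    key = (df.loc[idx, "intervention"], df.loc[idx, "climate"])
                    raise ImputationUnavailableError(
                        f"no reported-variation records in group {key}; "
                        "cannot impute SD (set allow_global_cv=True to fall back)"
                    )
            sd_imputed = impute_sd(mean.loc[idx], avg_cv, cv_inflation)
            se.loc[idx] = se_from_sd(sd_imputed, int(n_eff.loc[idx]))

    return pd.DataFrame(
        {
            "source_id": df["source_id"],
            "measure": df["measure"],
            "intervention": df["intervention"],
            "climate": df["climate"],
            "mean": mean,
            "se": se,
            "n_pairs": n,
        }
    )


def build_effect_table(
    records: pd.DataFrame,
    bd_provider: BulkDensityProvider | None = None,
    reference_duration: float = REFERENCE_DURATION_YR,
    allow_global_cv: bool = False,
) -> pd.DataFrame:
    """End-to-end harmonization and pooling into the effect table.

    Runs unit conversion, annualization, SE harmonization and imputation,
    then pools records per intervention x climate.  An "other"-climate row
    per intervention combines the zone-level pooled effects (and any records
    reported directly for "other") by inverse variance; it is the fallback
    effect for zones without data.

    Returns a table with columns
    (measure, intervention, climate, mean_tC_ha_yr, se_tC_ha_yr, k_studies).
    """
    annual = harmonize_records(
        records, bd_provider, reference_duration, allow_global_cv=allow_global_cv
    )
    rows: list[PooledEffect] = []
    for (iv, cl), grp in annual.groupby(["intervention", "climate"], sort=False):
        rows.append(pool_effects(grp["mean"].values, grp["se"].values, iv, cl))

    # "other" = inverse-variance combination across the pooled climate cells
    by_iv: dict[str, list[PooledEffect]] = {}
    for pe in rows:
        by_iv.setdefault(pe.intervention, []).append(pe)
    combined: list[PooledEffect] = []
    for iv, cells in by_iv.items():
        non_other = [pe for pe in cells if pe.climate != "other"]
        direct_other = [pe for pe in cells if pe.climate == "other"]
        pool_inputs = non_other + direct_other
        pooled = pool_effects(
            [pe.mean for pe in pool_inputs], [pe.se for pe in pool_inputs], iv, "other"
        )
        combined.append(
            PooledEffect(iv, "other", pooled.mean, pooled.se, sum(pe.k_studies for pe in pool_inputs))
        )
    rows = [pe for pe in rows if pe.climate != "other"] + combined

    out = pd.DataFrame(
        {
            "measure": [INTERVENTION_MEASURE[pe.intervention] for pe in rows],
            "intervention": [pe.intervention for pe in rows],
            "climate": [pe.climate for pe in rows],
            "mean_tC_ha_yr": [pe.mean for pe in rows],
            "se_tC_ha_yr": [pe.se for pe in rows],
            "k_studies": [pe.k_studies for pe in rows],
        }
    )
    climate_order = {c: i for i, c in enumerate(CLIMATES)}
    return (
        out.sort_values(
            ["measure", "intervention", "climate"],
            key=lambda s: s.map(climate_order) if s.name == "climate" else s,
        )
        .reset_index(drop=True)
    )


def load_table2_effects() -> pd.DataFrame:
    """Packaged pooled effect table (t C ha^-1 yr^-1 with SEs) per cell.

    These are the published weighted group means for the top 20-30 cm over a
    20-year horizon; the "other" rows are the across-zone combinations used
    as fallback for zones without data.
    """
    with resources.files("socpotential.fixtures").joinpath("table2_effects.csv").open() as fh:
        return pd.read_csv(fh)
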