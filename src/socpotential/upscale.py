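"""Upscale pooled effect sizes over eligible areas with Monte-Carlo uncertainty.

A measure's sequestration potential in a climate zone is the sum over
eligible strata of ``area (ha) x effect (t C ha^-1 yr^-1)``, reported in
Mton C yr^-1 (1 Mton = 1e6 t).  Uncertainty in the pooled effects is
propagated by Monte Carlo (default n = 1000): every effect cell is drawn
from Normal(mean, SE) and the potential recomputed; the 0.01 and 0.99
quantiles of the draws bound the estimate.  Measure totals are combined
across measures either by plain summation (maximum complementarity) or by
a 1/rank weighting that discounts measures in decreasing order of impact.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import NoEffectError
from .manure_budget import cap_measure_potential

#: t C yr^-1 -> Mton C yr^-1
T_TO_MTON = 1e-6
DEFAULT_N_MC = 1000
DEFAULT_SEED = 20211112
MC_QUANTILES = (0.01, 0.99)

#: canonical measure ordering used to break ties ("M2cor" sits in M2's slot)
_MEASURE_SLOT = {"M1": 1, "M2": 2, "M2cor": 2, "M3": 3, "M4": 4, "M5": 5}


@dataclass(frozen=True)
class PotentialEstimate:
    """Per-zone sequestration potential with Monte-Carlo bounds (Mton C yr^-1)."""

    measure: str
    climate: str
    mean: float
    q01: float
    q99: float
    draws: np.ndarray | None = None


@dataclass(frozen=True)
class ScenarioResult:
    """Combined five-measure potential under a complementarity rule."""

    rule: str
    total: float
    low: float
    high: float
    ranks: tuple[str, ...]
    weights: Mapping[str, float]


def _effect_maps(effects: pd.DataFrame):
    mean = {}
    se = {}
    for _, row in effects.iterrows():
        key = (row["intervention"], row["climate"])
        mean[key] = float(row["mean_tC_ha_yr"])
        se[key] = float(row.get("se_tC_ha_yr", 0.0))
    return mean, se


def _resolve_cells(area_table: pd.DataFrame, effects: pd.DataFrame) -> pd.DataFrame:
    """Attach the effect cell used by each area row, falling back to "other".

    Zones without their own pooled effect (e.g. tillage contrasts in the
    tropics) use the across-zone "other" combination.
    """
    mean_map, se_map = _effect_maps(effects)
    rows = []
    for _, row in area_table.iterrows():
        iv, cl = row["intervention"], row["climate"]
        key = (iv, cl)
        if key not in mean_map or np.isnan(mean_map[key]):
            key = (iv, "other")
            if key not in mean_map or np.isnan(mean_map[key]):
                raise NoEffectError(
                    f"no pooled effect for ({iv}, {cl}) and no 'other' fallback"
                )
        out = dict(row)
        out["effect_mean"] = mean_map[key]
        out["effect_se"] = se_map[key]
        out["effect_key"] = key
        rows.append(out)
    return pd.DataFrame(rows)


def measure_potential(
    area_table: pd.DataFrame,
    effects: pd.DataFrame,
    by: Sequence[str] = ("climate",),
) -> pd.DataFrame:
    """Deterministic mean potential per group (Mton C yr^-1).

    ``area_table`` carries (climate, intervention, area_ha) rows — the
    output of stratum eligibility — and ``effects`` the pooled effect table.
    """
    if area_table.empty:
        return pd.DataFrame(columns=[*by, "potential_mton"])
    resolved = _resolve_cells(area_table, effects)
    resolved["potential_mton"] = (
        resolved["area_ha"] * resolved["effect_mean"] * T_TO_MTON
    )
    return resolved.groupby(list(by), as_index=False, observed=True)["potential_mton"].sum()


def monte_carlo_potential(
    area_table: pd.DataFrame,
    effects: pd.DataFrame,
    n_mc: int = DEFAULT_N_MC,
    seed: int | np.random.Generator = DEFAULT_SEED,
    cap_budget: pd.DataFrame | None = None,
    all_bounds: str = "draws",
    keep_draws: bool = False,
    measure: str = "",
) -> pd.DataFrame:
    """Monte-Carlo uncertainty bounds of the per-zone potential.

    Each draw samples every effect cell independently from
    Normal(mean, SE) and recomputes the zone potentials; q01/q99 are the
    0.01/0.99 quantiles (linear interpolation between order statistics).
    The reported mean is the deterministic :func:`measure_potential`.

    Parameters
    ----------
    cap_budget:
        Optional manure budget table (region_id, stable_c_supply_mton); when
        given, ``area_table`` must carry region_id and the cap is applied per
        region within every draw before zone aggregation.
    all_bounds:
        "draws": the "all" row's bounds are quantiles of the summed zone
        draws (default); "sum_zone_quantiles": sums of the zone quantiles.
    """
    if n_mc < 2:
        raise ValueError(f"n_mc must be >= 2, got {n_mc}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    resolved = _resolve_cells(area_table, effects)
    if (resolved["effect_se"] < 0).any():
        raise ValueError("effect SEs must be non-negative")

    cells = sorted(set(resolved["effect_key"]))
    cell_idx = {k: i for i, k in enumerate(cells)}
    mean_by_cell = dict(zip(resolved["effect_key"], resolved["effect_mean"]))
    se_by_cell = dict(zip(resolved["effect_key"], resolved["effect_se"]))
    mu = np.array([mean_by_cell[c] for c in cells])
    sd = np.array([se_by_cell[c] for c in cells])
    draws = rng.normal(mu, sd, size=(n_mc, len(cells)))  # (n_mc, n_cells)

    coeff = (resolved["area_ha"] * T_TO_MTON).to_numpy()
    row_cell = resolved["effect_key"].map(cell_idx).to_numpy()
    contrib = coeff[None, :] * draws[:, row_cell]  # (n_mc, n_rows)

    if cap_budget is not None:
        if "region_id" not in resolved.columns:
            raise ValueError("cap_budget requires a region_id column in the area table")
        bud = cap_budget.set_index("region_id")["stable_c_supply_mton"]
        region_codes, regions = pd.factorize(resolved["region_id"])
        reg_tot = np.zeros((n_mc, len(regions)))
        np.add.at(reg_tot.T, region_codes, contrib.T)
        caps = bud.reindex(regions).to_numpy()
        if np.isnan(caps).any():
            missing = [r for r, c in zip(regions, caps) if np.isnan(c)]
            raise NoEffectError(f"regions without a manure budget: {missing}")
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(reg_tot > 0, np.minimum(1.0, caps[None, :] / reg_tot), 1.0)
        contrib = contrib * scale[:, region_codes]

    climates, zone_labels = pd.factorize(resolved["climate"])
    zone_draws = np.zeros((n_mc, len(zone_labels)))
    np.add.at(zone_draws.T, climates, contrib.T)
    all_draws = zone_draws.sum(axis=1)

    if cap_budget is None:
        det = measure_potential(area_table, effects).set_index("climate")["potential_mton"]
    else:
        raw = measure_potential(area_table, effects, by=("region_id", "climate"))
        capped = cap_measure_potential(raw, cap_budget)
        det = capped.groupby("climate")["potential_mton"].sum()

    rows = []
    for j, cl in enumerate(zone_labels):
        q01, q99 = np.quantile(zone_draws[:, j], MC_QUANTILES)
        rows.append((cl, float(det.get(cl, 0.0)), float(q01), float(q99)))
    if all_bounds == "draws":
        q01_all, q99_all = map(float, np.quantile(all_draws, MC_QUANTILES))
    elif all_bounds == "sum_zone_quantiles":
        q01_all = sum(r[2] for r in rows)
        q99_all = sum(r[3] for r in rows)
    else:
        raise ValueError(f"unknown all_bounds rule {all_bounds!r}")
    rows.append(("all", float(det.sum()), q01_all, q99_all))

    out = pd.DataFrame(rows, columns=["climate", "mean_mton", "q01_mton", "q99_mton"])
    if measure:
        out.insert(0, "measure", measure)
    if keep_draws:
        out.attrs["draws"] = {cl: zone_draws[:, j] for j, cl in enumerate(zone_labels)}
        out.attrs["draws"]["all"] = all_draws
    return out


def _check_five_measures(potentials: pd.DataFrame) -> pd.DataFrame:
    if potentials.index.has_duplicates:
        raise ValueError("duplicate measures in potentials table")
    slots = sorted(_MEASURE_SLOT.get(m, -1) for m in potentials.index)
    if len(potentials) != 5 or slots != [1, 2, 3, 4, 5]:
        raise ValueError(
            "exactly one potential per measure M1..M5 required "
            f"(got {sorted(potentials.index)})"
        )
    return potentials


def _ranked(potentials: pd.DataFrame) -> list[str]:
    # sort by descending mean; ties broken by the fixed M1 < M2 < ... order
    return sorted(
        potentials.index, key=lambda m: (-potentials.loc[m, "mean_mton"], _MEASURE_SLOT[m])
    )


def combine_max_complementarity(potentials: pd.DataFrame) -> ScenarioResult:
    """Plain sum of the five measure potentials (means and printed bounds).

    ``potentials`` is indexed by measure (M1, M2 or M2cor, M3, M4, M5) with
    columns mean_mton, q01_mton, q99_mton for the global ("all") zone.
    Assumes the measures are fully complementary; the bounds are the sums
    of the per-measure bounds.
    """
    potentials = _check_five_measures(potentials)
    ranks = _ranked(potentials)
    return ScenarioResult(
        rule="max_complementarity",
        total=float(potentials["mean_mton"].sum()),
        low=float(potentials["q01_mton"].sum()),
        high=float(potentials["q99_mton"].sum()),
        ranks=tuple(ranks),
        weights={m: 1.0 for m in ranks},
    )


def combine_rank_weighted(potentials: pd.DataFrame) -> ScenarioResult:
    """Discounted combination: the k-th largest measure contributes 1/k of
    its potential.

    Measures are ranked by their mean potential (descending); the same
    mean-derived ranks are applied to the q01/q99 bounds.  This tempers the
    assumption of full complementarity between measures.
    """
    potentials = _check_five_measures(potentials)
    ranks = _ranked(potentials)
    weights = {m: 1.0 / (k + 1) for k, m in enumerate(ranks)}
    total = sum(potentials.loc[m, "mean_mton"] * w for m, w in weights.items())
    low = sum(potentials.loc[m, "q01_mton"] * w for m, w in weights.items())
    high = sum(potentials.loc[m, "q99_mton"] * w for m, w in weights.items())
    return ScenarioResult(
        rule="rank_weighted",
        total=float(total),
        low=float(low),
        high=float(high),
        ranks=tuple(ranks),
        weights=weights,
    )


def load_table3_potentials() -> pd.DataFrame:
    """Packaged per-measure, per-zone potential table (Mton C yr^-1).

    Columns: measure, climate (four zones plus "all"), mean_mton, q01_mton,
    q99_mton.  M2 is the uncapped organic-fertilization potential; M2cor is
    the same measure capped by the recyclable-manure carbon budget.
    """
    with resources.files("socpotential.fixtures").joinpath("table3_potentials.csv").open() as fh:
        return pd.read_csv(fh)


def global_potentials(
    table: pd.DataFrame, measures: Sequence[str] = ("M1", "M2cor", "M3", "M4", "M5")
) -> pd.DataFrame:
    """Extract the global ("all") row per measure, indexed by measure."""
    sub = table[(table["climate"] == "all") & table["measure"].isin(measures)]
    return sub.set_index("measure")[["mean_mton", "q01_mton", "q99_mton"]]
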