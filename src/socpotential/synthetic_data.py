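"""Seeded generators for synthetic cropland cells, effect records and manure tables.

The generators emulate the marginal composition of global cropland that the
upscaling assumes — total area 1,416,912 kha split 30/19/30/21% across
tropical/temperate/subtropical/other climates, 45% high-intensity tillage
vs 8% no-till, 25% residue burning, 72% of rotations without catch crops
and 13% of land under high inorganic *and* high manure fertilization — so
every pipeline stage can be exercised and parameter recovery tested without
any external spatial layers.  They do not emulate spatial autocorrelation,
real coordinates or country borders.

All randomness flows from a single integer seed through a dedicated
sub-stream per table, so tables are reproducible independently of the order
in which they are generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .meta_harmonize import (
    DEFAULT_BULK_DENSITY,
    REFERENCE_DURATION_YR,
    concentration_to_stock,
    load_table2_effects,
)

_TABLE_STREAMS = {"cells": 1, "effects": 2, "manure": 3}


def _rng(seed: int, table: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_TABLE_STREAMS[table],)))


def _truncated_lognormal(
    rng: np.random.Generator, n: int, median: float, sigma: float, lo: float, hi: float
) -> np.ndarray:
    """Draw from a lognormal conditioned on the interval [lo, hi)."""
    dist = stats.lognorm(s=sigma, scale=median)
    a, b = dist.cdf(lo), dist.cdf(hi)
    if not b > a:
        raise ConfigError(f"empty truncation interval [{lo}, {hi}) for lognormal draws")
    u = rng.uniform(a, b, size=n)
    return np.clip(dist.ppf(u), lo, np.nextafter(hi, lo))


@dataclass(frozen=True)
class GeneratorConfig:
    """Stated-world parameters of the synthetic cropland generator.

    Shares are area-marginal targets; N rates are drawn from truncated
    lognormals inside each fertilization/manure class interval so that the
    induced class shares match the configured marginals exactly.
    """

    n_cells: int = 10_000
    total_area_kha: float = 1_416_912.0
    climate_shares: dict = field(
        default_factory=lambda: {
            "tropical": 0.30,
            "temperate": 0.19,
            "subtropical": 0.30,
            "other": 0.21,
        }
    )
    tillage_shares: dict = field(
        default_factory=lambda: {"HT": 0.45, "NT": 0.08, "IT": 0.47}
    )
    residue_shares: dict = field(
        default_factory=lambda: {"burned": 0.25, "removed": 0.15, "incorporated": 0.60}
    )
    no_catch_crop_share: float = 0.72
    fert_class_shares: dict = field(
        default_factory=lambda: {"none": 0.20, "medium": 0.55, "high": 0.25}
    )
    manure_high_share: float = 0.18
    high_high_fert_share: float = 0.13
    # class intervals in kg N ha^-1 yr^-1; upper edge of "high" caps the draw
    fert_class_bounds: dict = field(
        default_factory=lambda: {"none": (0.0, 40.0), "medium": (40.0, 100.0), "high": (100.5, 400.0)}
    )
    manure_class_bounds: dict = field(
        default_factory=lambda: {"low": (0.0, 40.0), "high": (40.0, 300.0)}
    )
    rate_median: float = 60.0
    rate_sigma: float = 0.8
    n_regions: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ConfigError("n_cells must be >= 1")
        if not self.total_area_kha > 0:
            raise ConfigError("total_area_kha must be positive")
        for name, shares in [
            ("climate_shares", self.climate_shares),
            ("tillage_shares", self.tillage_shares),
            ("residue_shares", self.residue_shares),
            ("fert_class_shares", self.fert_class_shares),
        ]:
            if any(v < 0 for v in shares.values()) or abs(sum(shares.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must be non-negative and sum to 1")
        if not 0 <= self.no_catch_crop_share <= 1:
            raise ConfigError("no_catch_crop_share must be in [0, 1]")
        if not 0 <= self.manure_high_share <= 1:
            raise ConfigError("manure_high_share must be in [0, 1]")
        self.fert_manure_joint()  # raises on infeasible combinations

    def fert_manure_joint(self) -> dict[tuple[str, str], float]:
        """Joint (fert_class, manure_class) cell probabilities.

        The high-high cell is pinned to ``high_high_fert_share``; the rest
        of the manure-high mass is spread over none/medium proportionally to
        their fertilizer shares.
        """
        p_hh = self.high_high_fert_share
        fs = self.fert_class_shares
        if p_hh > min(fs["high"], self.manure_high_share) + 1e-12:
            raise ConfigError(
                "high_high_fert_share exceeds the high-fertilizer or high-manure marginal"
            )
        rest = self.manure_high_share - p_hh
        w = fs["none"] + fs["medium"]
        joint = {("high", "high"): p_hh, ("high", "low"): fs["high"] - p_hh}
        for f in ("none", "medium"):
            mh = rest * (fs[f] / w if w > 0 else 0.0)
            if mh > fs[f] + 1e-12:
                raise ConfigError("manure_high_share infeasible given fertilizer shares")
            joint[(f, "high")] = mh
            joint[(f, "low")] = fs[f] - mh
        return joint


def generate_cells(config: GeneratorConfig) -> pd.DataFrame:
    """Synthetic cropland cell table with the configured marginal composition.

    Areas are symmetric-Dirichlet across cells, rescaled so that the total
    equals ``total_area_kha`` (in hectares) exactly; every categorical
    attribute is drawn independently except the fertilizer and manure rates,
    which are drawn jointly to hit the high-high target.
    """
    config.validate()
    rng = _rng(config.seed, "cells")
    n = config.n_cells
    total_ha = config.total_area_kha * 1e3

    area = rng.dirichlet(np.ones(n)) * total_ha
    area *= total_ha / area.sum()  # exact conservation

    climate = rng.choice(list(config.climate_shares), p=list(config.climate_shares.values()), size=n)
    tillage = rng.choice(list(config.tillage_shares), p=list(config.tillage_shares.values()), size=n)
    residue = rng.choice(list(config.residue_shares), p=list(config.residue_shares.values()), size=n)
    rotation = np.where(
        rng.uniform(size=n) < config.no_catch_crop_share, "without_catch_crops", "with_catch_crops"
    )

    joint = config.fert_manure_joint()
    cells = list(joint)
    fm = [cells[i] for i in rng.choice(len(cells), p=list(joint.values()), size=n)]
    fert_rate = np.empty(n)
    manure_rate = np.empty(n)
    for fert_class in config.fert_class_bounds:
        idx = np.array([i for i, (f, _) in enumerate(fm) if f == fert_class])
        if idx.size:
            lo, hi = config.fert_class_bounds[fert_class]
            fert_rate[idx] = _truncated_lognormal(
                rng, idx.size, config.rate_median, config.rate_sigma, lo, hi
            )
    for manure_class in config.manure_class_bounds:
        idx = np.array([i for i, (_, m) in enumerate(fm) if m == manure_class])
        if idx.size:
            lo, hi = config.manure_class_bounds[manure_class]
            manure_rate[idx] = _truncated_lognormal(
                rng, idx.size, config.rate_median / 2, config.rate_sigma, lo, hi
            )

    region = rng.integers(0, config.n_regions, size=n)
    return pd.DataFrame(
        {
            "region_id": [f"R{i + 1:03d}" for i in region],
            "climate": climate,
            "area_ha": area,
            "n_fert_rate": fert_rate,
            "n_manure_rate": manure_rate,
            "tillage": tillage,
            "rotation": rotation,
            "residue_fate": residue,
        }
    )


@dataclass(frozen=True)
class EffectGeneratorConfig:
    """Generator for effect-size records with a known pooled truth.

    Per intervention x climate cell, ``k_studies`` study means are drawn
    around the stored truth with between-study scatter sd/sqrt(n_pairs)
    (each study's own SE), and each record reports SD = ``sd`` with
    ``n_pairs`` pairs, so the pooled SE is sd / sqrt(k n).
    """

    k_studies: int = 3
    sd: float = 0.1
    n_pairs: int = 10
    metrics: Sequence[str] = ("stock_annual",)
    depth_m: float = 0.3
    duration_yr: float = REFERENCE_DURATION_YR
    bulk_density: float = DEFAULT_BULK_DENSITY
    truth: pd.DataFrame | None = None  # columns intervention, climate, mean
    seed: int = 0

    def validate(self) -> None:
        if self.k_studies < 1 or self.n_pairs < 1:
            raise ConfigError("k_studies and n_pairs must be >= 1")
        if self.sd < 0:
            raise ConfigError("sd must be non-negative")
        bad = set(self.metrics) - {"stock_total", "stock_annual", "conc_total", "conc_annual"}
        if bad:
            raise ConfigError(f"unknown metrics {sorted(bad)}")


def _metric_factor(metric: str, cfg: EffectGeneratorConfig) -> float:
    f = 1.0
    if metric.startswith("conc"):
        f *= concentration_to_stock(1.0, cfg.bulk_density, cfg.depth_m)
    if metric.endswith("_total"):
        f /= REFERENCE_DURATION_YR
    return f


def generate_effect_records(
    config: EffectGeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic effect-size records plus the truth table they were drawn from.

    Records cycle through the configured metrics, back-transforming the
    annual-scale truth into each metric's units, so mixed-metric inputs
    harmonize to the same truth by construction.  Returns
    ``(records, truth)`` where truth has columns
    (intervention, climate, true_mean, true_pooled_se).
    """
    config.validate()
    rng = _rng(config.seed, "effects")
    truth = config.truth
    if truth is None:
        t2 = load_table2_effects()
        truth = t2[t2["climate"] != "other"][["intervention", "climate", "mean_tC_ha_yr"]]
        truth = truth.rename(columns={"mean_tC_ha_yr": "mean"})

    from .meta_harmonize import INTERVENTION_MEASURE  # avoid cycle at import time

    records = []
    truth_rows = []
    metric_cycle = list(config.metrics)
    i = 0
    for _, cell in truth.iterrows():
        iv, cl, mu = cell["intervention"], cell["climate"], float(cell["mean"])
        se_study = config.sd / np.sqrt(config.n_pairs)
        for j in range(config.k_studies):
            metric = metric_cycle[i % len(metric_cycle)]
            i += 1
            f = _metric_factor(metric, config)
            study_mean = mu + rng.normal(0.0, se_study)
            records.append(
                {
                    "source_id": f"synth-{iv}-{cl}-{j}",
                    "measure": INTERVENTION_MEASURE[iv],
                    "intervention": iv,
                    "climate": cl,
                    "metric": metric,
                    "value": study_mean / f,
                    "variation_kind": "SD",
                    "variation_value": config.sd / f,
                    "variation_value2": np.nan,
                    "n_pairs": config.n_pairs,
                    "depth_m": config.depth_m,
                    "duration_yr": config.duration_yr,
                }
            )
        truth_rows.append(
            {
                "intervention": iv,
                "climate": cl,
                "true_mean": mu,
                "true_pooled_se": se_study / np.sqrt(config.k_studies),
            }
        )
    return pd.DataFrame(records), pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class ManureGeneratorConfig:
    """Generator for regional manure-N excretion and application tables.

    Defaults normalize total excretion to the global figure of
    129 Tg N yr^-1 with 92% of excreted N recycled (applied on cropland or
    grassland), leaving a surplus below the 10% bound the budget assumes.
    """

    n_regions: int = 20
    total_excretion_kg_n: float = 1.29e11  # 129 Tg N yr^-1
    recycling_fraction: float = 0.92
    cropland_share_of_recycled: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_regions < 1:
            raise ConfigError("n_regions must be >= 1")
        if not 0 <= self.recycling_fraction <= 1:
            raise ConfigError("recycling_fraction must be in [0, 1]")
        if not 0 <= self.cropland_share_of_recycled <= 1:
            raise ConfigError("cropland_share_of_recycled must be in [0, 1]")
        if self.total_excretion_kg_n < 0:
            raise ConfigError("total_excretion_kg_n must be non-negative")


def generate_manure_records(config: ManureGeneratorConfig) -> pd.DataFrame:
    """Per-region excretion and application totals with a uniform recycling
    fraction, so the aggregate surplus is exactly
    ``(1 - recycling_fraction) x total_excretion``."""
    config.validate()
    rng = _rng(config.seed, "manure")
    excretion = rng.dirichlet(np.ones(config.n_regions)) * config.total_excretion_kg_n
    excretion *= config.total_excretion_kg_n / excretion.sum() if excretion.sum() > 0 else 1.0
    recycled = excretion * config.recycling_fraction
    return pd.DataFrame(
        {
            "region_id": [f"R{i + 1:03d}" for i in range(config.n_regions)],
            "n_excreted": excretion,
            "n_applied_cropland": recycled * config.cropland_share_of_recycled,
            "n_applied_grassland": recycled * (1 - config.cropland_share_of_recycled),
        }
    )
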