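"""Area x effect upscaling, Monte-Carlo bounds and scenario combination."""

import numpy as np
import pandas as pd
import pytest

from socpotential.errors import NoEffectError
from socpotential.upscale import (
    combine_max_complementarity,
    combine_rank_weighted,
    global_potentials,
    load_table3_potentials,
    measure_potential,
    monte_carlo_potential,
)


def effects_table(rows):
    return pd.DataFrame(rows, columns=["intervention", "climate", "mean_tC_ha_yr", "se_tC_ha_yr"])


def area_table(rows):
    return pd.DataFrame(rows, columns=["climate", "intervention", "area_ha"])


SIMPLE_EFFECTS = effects_table([("NT-HT", "temperate", 0.23, 0.02), ("NT-HT", "other", 0.2, 0.01)])


class TestMeasurePotential:
    def test_zero_area(self):
        out = measure_potential(area_table([("temperate", "NT-HT", 0.0)]), SIMPLE_EFFECTS)
        assert out["potential_mton"].iloc[0] == 0.0

    def test_hand_arithmetic(self):
        # 100 Mha at 0.23 t C/ha/yr -> 23 Mton C/yr
        out = measure_potential(area_table([("temperate", "NT-HT", 100e6)]), SIMPLE_EFFECTS)
        assert out["potential_mton"].iloc[0] == pytest.approx(23.0)

    def test_additivity_over_strata(self):
        both = measure_potential(
            area_table([("temperate", "NT-HT", 60e6), ("temperate", "NT-HT", 40e6)]),
            SIMPLE_EFFECTS,
        )
        assert both["potential_mton"].iloc[0] == pytest.approx(23.0)

    def test_linear_in_area_and_effect(self):
        base = measure_potential(area_table([("temperate", "NT-HT", 50e6)]), SIMPLE_EFFECTS)
        doubled_area = measure_potential(area_table([("temperate", "NT-HT", 100e6)]), SIMPLE_EFFECTS)
        assert doubled_area["potential_mton"].iloc[0] == pytest.approx(
            2 * base["potential_mton"].iloc[0]
        )
        doubled_eff = measure_potential(
            area_table([("temperate", "NT-HT", 50e6)]),
            effects_table([("NT-HT", "temperate", 0.46, 0.02)]),
        )
        assert doubled_eff["potential_mton"].iloc[0] == pytest.approx(
            2 * base["potential_mton"].iloc[0]
        )

    def test_fallback_to_other_zone(self):
        # tropical has no NT-HT cell; the across-zone "other" effect applies
        out = measure_potential(area_table([("tropical", "NT-HT", 100e6)]), SIMPLE_EFFECTS)
        assert out["potential_mton"].iloc[0] == pytest.approx(20.0)

    def test_missing_effect_and_no_fallback(self):
        with pytest.raises(NoEffectError):
            measure_potential(
                area_table([("tropical", "NT-HT", 1.0)]),
                effects_table([("NT-HT", "temperate", 0.23, 0.02)]),
            )


class TestMonteCarlo:
    def test_degenerate_zero_se(self):
        eff = effects_table([("NT-HT", "temperate", 0.2, 0.0)])
        out = monte_carlo_potential(
            area_table([("temperate", "NT-HT", 100e6)]), eff, n_mc=100, seed=1
        )
        row = out[out["climate"] == "temperate"].iloc[0]
        assert row["q01_mton"] == row["q99_mton"] == row["mean_mton"] == pytest.approx(20.0)

    def test_fixed_seed_reproducible(self):
        args = (area_table([("temperate", "NT-HT", 100e6)]), SIMPLE_EFFECTS)
        a = monte_carlo_potential(*args, n_mc=500, seed=42)
        b = monte_carlo_potential(*args, n_mc=500, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_quantiles_match_normal_theory_small(self):
        # one cell: potential ~ Normal(100, 10) Mton; z_0.01 = 2.326
        eff = effects_table([("IF-NF", "temperate", 0.1, 0.01)])
        out = monte_carlo_potential(
            area_table([("temperate", "IF-NF", 1e9)]), eff, n_mc=20_000, seed=3
        )
        row = out[out["climate"] == "temperate"].iloc[0]
        assert row["mean_mton"] == pytest.approx(100.0)
        assert row["q01_mton"] == pytest.approx(100 - 23.26, rel=0.03)
        assert row["q99_mton"] == pytest.approx(100 + 23.26, rel=0.03)

    def test_all_row_bound_rules(self):
        eff = effects_table(
            [("IF-NF", "temperate", 0.1, 0.01), ("IF-NF", "tropical", 0.2, 0.02)]
        )
        areas = area_table([("temperate", "IF-NF", 1e8), ("tropical", "IF-NF", 1e8)])
        draws = monte_carlo_potential(areas, eff, n_mc=2000, seed=5, all_bounds="draws")
        sums = monte_carlo_potential(
            areas, eff, n_mc=2000, seed=5, all_bounds="sum_zone_quantiles"
        )
        zones = sums[sums["climate"] != "all"]
        all_sums = sums[sums["climate"] == "all"].iloc[0]
        assert all_sums["q01_mton"] == pytest.approx(zones["q01_mton"].sum())
        # independent zones: quantile of the sum is inside the summed quantiles
        all_draws = draws[draws["climate"] == "all"].iloc[0]
        assert all_draws["q01_mton"] >= all_sums["q01_mton"] - 1e-9
        assert all_draws["q99_mton"] <= all_sums["q99_mton"] + 1e-9

    def test_regional_cap_applied_within_draws(self):
        eff = effects_table([("OF-NF", "temperate", 0.5, 0.0)])
        areas = pd.DataFrame(
            {
                "region_id": ["A", "B"],
                "climate": ["temperate", "temperate"],
                "intervention": ["OF-NF", "OF-NF"],
                "area_ha": [100e6, 100e6],
            }
        )
        budget = pd.DataFrame(
            {"region_id": ["A", "B"], "stable_c_supply_mton": [10.0, 1000.0]}
        )
        out = monte_carlo_potential(areas, eff, n_mc=100, seed=1, cap_budget=budget)
        row = out[out["climate"] == "temperate"].iloc[0]
        assert row["mean_mton"] == pytest.approx(10.0 + 50.0)

    def test_invalid_n_mc(self):
        with pytest.raises(ValueError):
            monte_carlo_potential(area_table([("temperate", "NT-HT", 1.0)]), SIMPLE_EFFECTS, n_mc=1)


def fixture_globals():
    return global_potentials(load_table3_potentials())


class TestScenarios:
    def test_all_zeros(self):
        gp = fixture_globals() * 0.0
        assert combine_max_complementarity(gp).total == 0.0
        assert combine_rank_weighted(gp).total == 0.0

    def test_single_nonzero_measure_keeps_full_weight(self):
        gp = fixture_globals() * 0.0
        gp.loc["M3"] = [100.0, 80.0, 120.0]
        res = combine_rank_weighted(gp)
        assert res.total == pytest.approx(100.0)
        assert res.ranks[0] == "M3"

    def test_rank_weighted_below_max_and_above_best_measure(self):
        gp = fixture_globals()
        rw = combine_rank_weighted(gp)
        mc = combine_max_complementarity(gp)
        assert gp["mean_mton"].max() <= rw.total <= mc.total

    def test_duplicate_or_missing_measures_rejected(self):
        gp = fixture_globals()
        with pytest.raises(ValueError):
            combine_max_complementarity(gp.drop(index="M5"))
        both_m2 = pd.concat([gp, gp.loc[["M2cor"]].rename(index={"M2cor": "M2"})])
        with pytest.raises(ValueError):
            combine_max_complementarity(both_m2.drop(index="M1"))

    def test_tie_break_uses_fixed_measure_order(self):
        gp = fixture_globals()
        gp["mean_mton"] = 50.0  # all tied
        res = combine_rank_weighted(gp)
        assert list(res.ranks) == ["M1", "M2cor", "M3", "M4", "M5"]


def test_table3_fixture_zone_additivity():
    """Every measure's "all" mean equals the sum of its four zone means."""
    t3 = load_table3_potentials()
    for measure, grp in t3.groupby("measure"):
        zones = grp[grp["climate"] != "all"]["mean_mton"].sum()
        all_row = grp[grp["climate"] == "all"]["mean_mton"].iloc[0]
        assert zones == pytest.approx(all_row), measure
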