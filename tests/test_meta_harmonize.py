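"""Unit conversion, SE harmonization, CV imputation and inverse-variance pooling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from socpotential.errors import ImputationUnavailableError, NoDataError
from socpotential.meta_harmonize import (
    annualize,
    build_effect_table,
    concentration_to_stock,
    constant_bulk_density,
    harmonize_records,
    impute_sd,
    load_table2_effects,
    pool_effects,
    se_from_ci,
    se_from_sd,
)


class TestUnitConversions:
    @pytest.mark.parametrize(
        "conc,bd,depth,expected",
        [
            (0.0, 1400, 0.3, 0.0),
            (1.0, 1400, 0.3, 4.2),  # default bulk density, 30 cm topsoil
            (2.5, 1200, 0.2, 6.0),
            (-1.0, 1400, 0.3, -4.2),  # sign preserved for SOC losses
        ],
    )
    def test_concentration_to_stock(self, conc, bd, depth, expected):
        assert concentration_to_stock(conc, bd, depth) == pytest.approx(expected)

    @pytest.mark.parametrize("bd,depth", [(0, 0.3), (-5, 0.3), (1400, 0), (1400, -0.1)])
    def test_concentration_to_stock_rejects_nonpositive(self, bd, depth):
        with pytest.raises(ValueError):
            concentration_to_stock(1.0, bd, depth)

    @pytest.mark.parametrize("total,dur,expected", [(0, 20, 0), (20, 20, 1.0), (4.2, 20, 0.21)])
    def test_annualize(self, total, dur, expected):
        assert annualize(total, dur) == pytest.approx(expected)

    def test_annualize_rejects_nonpositive_duration(self):
        with pytest.raises(ValueError):
            annualize(1.0, 0.0)

    @given(
        conc=st.floats(-50, 50),
        bd=st.floats(800, 2000),
        depth=st.floats(0.05, 1.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_unit_chain_matches_stepwise_oracle(self, conc, bd, depth):
        """g/kg -> g/m^2 -> t/ha computed step by step agrees to machine precision."""
        g_per_m2 = conc * bd * depth  # g C per kg soil x kg soil per m^3 x m
        t_per_ha = g_per_m2 * 1e-6 * 1e4  # g -> t and m^-2 -> ha^-1
        assert concentration_to_stock(conc, bd, depth) == pytest.approx(t_per_ha, rel=1e-12)

    @given(
        conc=st.floats(-50, 50), bd=st.floats(800, 2000),
        depth=st.floats(0.05, 1.0), dur=st.floats(1.0, 100.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_annualize_round_trip(self, conc, bd, depth, dur):
        total = concentration_to_stock(conc, bd, depth)
        assert annualize(total, dur) * dur == pytest.approx(total, rel=1e-12, abs=1e-15)


class TestStandardErrors:
    @pytest.mark.parametrize("sd,n,expected", [(0, 10, 0), (1, 1, 1), (0.4, 16, 0.1)])
    def test_se_from_sd(self, sd, n, expected):
        assert se_from_sd(sd, n) == pytest.approx(expected)

    def test_se_from_sd_rejects_bad_args(self):
        with pytest.raises(ValueError):
            se_from_sd(0.1, 0)
        with pytest.raises(ValueError):
            se_from_sd(-0.1, 5)

    @pytest.mark.parametrize(
        "lo,hi,expected",
        [(0.5, 0.5, 0.0), (-0.196, 0.196, 0.1), (0.2, 0.6, 0.4 / 3.92)],
    )
    def test_se_from_ci(self, lo, hi, expected):
        assert se_from_ci(lo, hi) == pytest.approx(expected)

    def test_se_from_ci_rejects_inverted_interval(self):
        with pytest.raises(ValueError):
            se_from_ci(0.5, 0.2)

    @given(m=st.floats(-5, 5), s=st.floats(0, 2))
    @settings(max_examples=100, derandomize=True)
    def test_se_from_ci_inverts_normal_interval(self, m, s):
        assert se_from_ci(m - 1.96 * s, m + 1.96 * s) == pytest.approx(s, abs=1e-12)

    @pytest.mark.parametrize(
        "mean,cv,expected", [(0, 0.2, 0), (0.5, 0.2, 0.125), (-0.4, 0.5, 0.25)]
    )
    def test_impute_sd(self, mean, cv, expected):
        assert impute_sd(mean, cv) == pytest.approx(expected)


class TestPooling:
    def test_single_record_identity(self):
        pe = pool_effects([0.21], [0.02])
        assert (pe.mean, pe.se, pe.k_studies) == (0.21, 0.02, 1)

    def test_equal_weight_symmetry(self):
        assert pool_effects([0.1, 0.3], [0.05, 0.05]).mean == pytest.approx(0.2)

    def test_hand_computed_weights(self):
        # weights 1/0.01^2 = 10000 and 1/0.02^2 = 2500
        pe = pool_effects([0.12, 0.17], [0.01, 0.02])
        assert pe.mean == pytest.approx((0.12 * 10000 + 0.17 * 2500) / 12500)
        assert pe.mean == pytest.approx(0.13)
        assert pe.se == pytest.approx(math.sqrt(1 / 12500), rel=1e-9)
        assert pe.se == pytest.approx(0.008944, abs=1e-6)

    def test_rejects_empty_and_zero_se(self):
        with pytest.raises(NoDataError):
            pool_effects([], [])
        with pytest.raises(ValueError):
            pool_effects([0.1, 0.2], [0.05, 0.0])

    def test_convex_hull_and_se_shrinkage(self, rng):
        for _ in range(200):
            k = rng.integers(1, 8)
            means = rng.normal(0, 1, k)
            ses = rng.uniform(0.01, 1.0, k)
            pe = pool_effects(means, ses)
            assert means.min() - 1e-12 <= pe.mean <= means.max() + 1e-12
            assert pe.se <= ses.min() + 1e-12

    def test_permutation_invariance_and_scale_equivariance(self, rng):
        means = rng.normal(0, 1, 6)
        ses = rng.uniform(0.05, 0.5, 6)
        pe = pool_effects(means, ses)
        perm = rng.permutation(6)
        pe_perm = pool_effects(means[perm], ses[perm])
        assert pe_perm.mean == pytest.approx(pe.mean, rel=1e-12)
        assert pe_perm.se == pytest.approx(pe.se, rel=1e-12)
        c = 3.7
        pe_scaled = pool_effects(c * means, c * ses)
        assert pe_scaled.mean == pytest.approx(c * pe.mean, rel=1e-12)
        assert pe_scaled.se == pytest.approx(c * pe.se, rel=1e-12)


class TestHarmonize:
    def test_metric_conversion_routes(self, records_df):
        # same annual truth 0.21 expressed in all four metrics
        df = records_df(
            {"metric": "stock_annual", "value": 0.21},
            {"metric": "stock_total", "value": 4.2},
            {"metric": "conc_annual", "value": 0.05, "depth_m": 0.3},
            {"metric": "conc_total", "value": 1.0, "depth_m": 0.3},
        )
        out = harmonize_records(df, constant_bulk_density(1400.0))
        assert out["mean"].values == pytest.approx([0.21, 0.21, 0.21, 0.21])

    def test_se_routes(self, records_df):
        df = records_df(
            {"variation_kind": "SD", "variation_value": 0.4, "n_pairs": 16},
            {"variation_kind": "SE", "variation_value": 0.07},
            {"variation_kind": "CI95", "variation_value": 0.1, "variation_value2": 0.3},
        )
        out = harmonize_records(df)
        assert out["se"].values == pytest.approx([0.1, 0.07, 0.2 / 3.92])

    def test_se_scales_with_conversion(self, records_df):
        # SD reported in concentration units scales by the same factor as the mean
        df = records_df(
            {
                "metric": "conc_total",
                "value": 1.0,
                "variation_kind": "SD",
                "variation_value": 0.5,
                "n_pairs": 4,
                "depth_m": 0.3,
            }
        )
        out = harmonize_records(df, constant_bulk_density(1400.0))
        f = 4.2 / 20  # t/ha per g/kg, then per year
        assert out["mean"].iloc[0] == pytest.approx(1.0 * f)
        assert out["se"].iloc[0] == pytest.approx(0.5 / 2 * f)

    def test_cv_imputation_uses_group_average(self, records_df):
        df = records_df(
            {"value": 0.2, "variation_kind": "SE", "variation_value": 0.05, "n_pairs": 4},
            {"value": 0.4, "variation_kind": np.nan, "variation_value": np.nan, "n_pairs": 4},
        )
        out = harmonize_records(df)
        # group CV = |0.05 * 2 / 0.2| = 0.5; SD = 1.25 * 0.5 * 0.4; SE = SD / 2
        assert out["se"].iloc[1] == pytest.approx(1.25 * 0.5 * 0.4 / 2)

    def test_imputation_unavailable_without_reported_variation(self, records_df):
        df = records_df({"variation_kind": np.nan, "variation_value": np.nan})
        with pytest.raises(ImputationUnavailableError):
            harmonize_records(df)

    def test_global_cv_fallback_when_configured(self, records_df):
        df = records_df(
            {"variation_kind": "SE", "variation_value": 0.05},
            {"climate": "tropical", "variation_kind": np.nan, "variation_value": np.nan},
        )
        out = harmonize_records(df, allow_global_cv=True)
        assert out["se"].notna().all()

    def test_measure_intervention_consistency_enforced(self, records_df):
        df = records_df({"measure": "M3"})  # IF-NF belongs to M1
        with pytest.raises(ValueError, match="inconsistent"):
            harmonize_records(df)


class TestBuildEffectTable:
    def test_single_record_passthrough(self, records_df):
        out = build_effect_table(records_df({}))
        row = out[out["climate"] == "temperate"].iloc[0]
        assert row["mean_tC_ha_yr"] == pytest.approx(0.2)
        assert row["se_tC_ha_yr"] == pytest.approx(0.05)
        # the "other" entry equals the single zone cell
        other = out[out["climate"] == "other"].iloc[0]
        assert other["mean_tC_ha_yr"] == pytest.approx(0.2)

    def test_other_is_arithmetic_mean_for_equal_se(self, records_df):
        out = build_effect_table(
            records_df(
                {"climate": "temperate", "value": 0.1},
                {"climate": "tropical", "value": 0.3},
            )
        )
        other = out[out["climate"] == "other"].iloc[0]
        assert other["mean_tC_ha_yr"] == pytest.approx(0.2)

    def test_table2_single_records_round_trip(self, records_df):
        """Zone cells fed as single stock_annual records reproduce themselves."""
        fixture = load_table2_effects()
        zones = fixture[fixture["climate"] != "other"]
        rows = [
            {
                "measure": r["measure"],
                "intervention": r["intervention"],
                "climate": r["climate"],
                "value": r["mean_tC_ha_yr"],
                "variation_kind": "SE",
                "variation_value": r["se_tC_ha_yr"],
            }
            for _, r in zones.iterrows()
        ]
        out = build_effect_table(records_df(*rows))
        merged = zones.merge(out, on=["intervention", "climate"], suffixes=("_fix", "_out"))
        assert len(merged) == len(zones)
        assert merged["mean_tC_ha_yr_out"].values == pytest.approx(
            merged["mean_tC_ha_yr_fix"].values
        )
        assert merged["se_tC_ha_yr_out"].values == pytest.approx(
            merged["se_tC_ha_yr_fix"].values
        )


def test_table2_fixture_schema():
    t2 = load_table2_effects()
    assert set(t2.columns) >= {"measure", "intervention", "climate", "mean_tC_ha_yr", "se_tC_ha_yr"}
    assert (t2["se_tC_ha_yr"] > 0).all()
    # every intervention carries an across-zone "other" entry for fallback
    assert set(t2[t2["climate"] == "other"]["intervention"]) == set(t2["intervention"])
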