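"""Aggregation, biomass/carbon conversion, change rates, and exceedance arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import gsvfuse as g
from gsvfuse.carbon_accounting import ConversionFactors, annual_rate_change, tonnes_to_tg

F = ConversionFactors()


def test_printed_factor_table_is_internally_consistent():
    F.validate()
    assert F.gsv_to_agb_c / F.gsv_to_agb == pytest.approx(0.4975, abs=1e-4)


def test_mistyped_factor_tables_are_flagged():
    with pytest.raises(ValueError, match="inconsistent"):
        ConversionFactors(gsv_to_agb_c=0.35).validate()
    with pytest.raises(ValueError, match="positive"):
        ConversionFactors(root_to_shoot=-0.1).validate()


def test_annual_accumulation_converts_to_live_carbon():
    """1,163 million m3/yr of stemwood is 407 Tg C/yr of live biomass carbon."""
    c_tg = tonnes_to_tg(1163e6 * F.gsv_to_live_c)
    assert round(c_tg) == 407


def test_zero_gsv_converts_to_zero_every_pool():
    for pool in ("live_c", "agb_c", "agb", "bgb"):
        assert g.convert(0.0, F, pool) == 0.0


def test_national_agb_density_with_comparison_factor():
    """111e9 m3 over 713.1e6 ha at 0.6859 t/m3 gives 107 Mg/ha of AGB."""
    density = 111e9 / 713.1e6 * F.houghton_gsv_to_agb
    assert round(density) == 107


def test_unknown_pool_rejected():
    with pytest.raises(ValueError, match="unknown pool"):
        g.convert(10.0, F, "soil")


def test_bgb_is_agb_times_root_to_shoot():
    assert g.convert(100.0, F, "bgb") == pytest.approx(
        g.convert(100.0, F, "agb") * F.root_to_shoot
    )


@given(
    st.floats(min_value=0, max_value=1e12, allow_nan=False),
    st.floats(min_value=0, max_value=1e12, allow_nan=False),
)
def test_conversion_is_linear(a, b):
    for pool in ("live_c", "agb_c", "agb", "bgb"):
        total = g.convert(a + b, F, pool)
        parts = g.convert(a, F, pool) + g.convert(b, F, pool)
        assert total == pytest.approx(parts, rel=1e-9, abs=1e-12)


# -- aggregation ---------------------------------------------------------------


def test_uniform_density_aggregates_exactly():
    pred = np.full((2, 5), 100.0)
    region = np.zeros((2, 5), dtype=int)
    mask = np.ones((2, 5), dtype=bool)
    agg = g.aggregate(pred, region, mask, pixel_area=0.5)
    assert agg.national_total == pytest.approx(500.0)
    assert agg.national_density == pytest.approx(100.0)


def test_regional_totals_sum_to_national():
    rng = np.random.default_rng(3)
    pred = rng.uniform(0, 300, (30, 30))
    region = rng.integers(0, 5, (30, 30))
    mask = rng.random((30, 30)) < 0.8
    agg = g.aggregate(pred, region, mask, pixel_area=0.5)
    assert agg.per_region["total_gsv"].sum() == agg.national_total


def test_masked_pixels_contribute_nothing():
    pred = np.full((3, 3), 50.0)
    region = np.zeros((3, 3), dtype=int)
    mask = np.zeros((3, 3), dtype=bool)
    mask[0, 0] = True
    agg = g.aggregate(pred, region, mask, pixel_area=1.0)
    assert agg.national_total == pytest.approx(50.0)


def test_region_without_forest_is_flagged():
    pred = np.full((2, 2), 10.0)
    region = np.array([[0, 0], [1, 1]])
    mask = np.array([[True, True], [False, False]])
    agg = g.aggregate(pred, region, mask, pixel_area=1.0)
    row = agg.per_region.set_index("region").loc[1]
    assert row["no_forest"] and np.isnan(row["density"])


def test_misaligned_rasters_rejected():
    with pytest.raises(ValueError, match="dimension"):
        g.aggregate(np.zeros((2, 2)), np.zeros((3, 2), dtype=int), np.ones((2, 2), bool), 0.5)


# -- change rates and exceedance ----------------------------------------------


def test_national_change_rate_arithmetic():
    """1,163e6 m3/yr over 721.7e6 ha: +1.61 m3/ha/yr and +0.56 t C/ha/yr."""
    est = annual_rate_change(1163e6, area_basis=721.7e6)
    rep = est.report()
    assert rep["per_ha_rate_m3_ha_yr"] == 1.61
    assert rep["per_ha_carbon_rate_t_c_ha_yr"] == 0.56
    assert rep["carbon_rate_tg_c_yr"] == 407


def test_change_rate_invariants():
    est = g.change_rate(111e9, 81.7e9, years=26.0, area_basis=721.7e6)
    assert est.annual_gsv_rate == pytest.approx(est.delta_gsv / 26.0)
    assert est.carbon_rate_tg == pytest.approx(
        tonnes_to_tg(est.annual_gsv_rate * F.gsv_to_live_c)
    )


def test_no_change_means_zero_rates():
    est = g.change_rate(81.7e9, 81.7e9, years=26.0, area_basis=721.7e6)
    assert est.delta_gsv == est.annual_gsv_rate == est.per_ha_rate == 0.0


def test_change_rate_rejects_bad_inputs():
    with pytest.raises(ValueError):
        g.change_rate(1.0, 1.0, years=0.0, area_basis=1.0)
    with pytest.raises(ValueError):
        g.change_rate(1.0, 1.0, years=1.0, area_basis=-5.0)


def test_exceedance_vs_register():
    assert round(g.percent_exceedance(111e9, 79.9e9)) == 39
    assert round(100 * 7.1e9 / 79.9e9) == 9
    assert g.percent_exceedance(5.0, 5.0) == 0.0
    with pytest.raises(ValueError):
        g.percent_exceedance(1.0, 0.0)


# -- managed subset --------------------------------------------------------------


def _densities():
    return pd.DataFrame(
        {"region": [0, 1], "density": [100.0, 200.0], "forest_area": [2e6, 3e6]}
    )


def test_managed_total_hand_arithmetic():
    managed = pd.DataFrame({"region": [0, 1], "managed_area": [1e6, 2e6]})
    res = g.managed_subset(_densities(), managed)
    assert res.total_gsv == pytest.approx(500e6)


def test_managed_equal_to_forest_recovers_national_total():
    managed = pd.DataFrame({"region": [0, 1], "managed_area": [2e6, 3e6]})
    res = g.managed_subset(_densities(), managed)
    assert res.total_gsv == pytest.approx(100.0 * 2e6 + 200.0 * 3e6)


def test_zero_managed_area_gives_zero():
    managed = pd.DataFrame({"region": [0, 1], "managed_area": [0.0, 0.0]})
    assert g.managed_subset(_densities(), managed).total_gsv == 0.0


def test_missing_managed_area_is_an_error():
    managed = pd.DataFrame({"region": [0], "managed_area": [1e6]})
    with pytest.raises(ValueError, match="missing managed area"):
        g.managed_subset(_densities(), managed)


def test_managed_area_above_forest_area_rejected():
    managed = pd.DataFrame({"region": [0, 1], "managed_area": [5e6, 1e6]})
    with pytest.raises(ValueError, match="exceeds"):
        g.managed_subset(_densities(), managed)


def test_managed_sequestration_uses_change_machinery():
    managed = pd.DataFrame({"region": [0, 1], "managed_area": [2e6, 3e6]})
    res = g.managed_subset(_densities(), managed, baseline_managed_gsv=500e6, years=26.0)
    assert res.change is not None
    assert res.change.delta_gsv == pytest.approx(res.total_gsv - 500e6)
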