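"""Design encoding, (weighted) least squares, frequency weights, truncated prediction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import gsvfuse as g
from gsvfuse import fusion_model as fm


def _normal_equations_oracle(X, y, w=None):
    """Independent closed-form solution of the (weighted) normal equations."""
    if w is None:
        w = np.ones(len(y))
    XtWX = X.T @ (X * w[:, None])
    XtWy = X.T @ (w * y)
    return np.linalg.solve(XtWX, XtWy)


def _make_records(n, seed, zones=fm.ZONES, pfts=fm.PFTS, coeffs=None, noise=0.0):
    rng = np.random.default_rng(seed)
    gb = rng.uniform(0, 300, n)
    cci = np.clip(0.8 * gb + rng.uniform(0, 80, n), 0, None)
    z = rng.integers(0, len(zones), n)
    p = rng.integers(0, len(pfts), n)
    coeffs = coeffs or g.default_true_coeffs(len(zones), len(pfts))
    y = coeffs.mean_response(gb, cci, z, p) + rng.normal(0, noise, n)
    return pd.DataFrame(
        {
            "gsv_gt": y,
            "gsv_gb": gb,
            "gsv_cci": cci,
            "zone": np.asarray(zones)[z],
            "pft": np.asarray(pfts)[p],
        }
    )


# -- design matrix -----------------------------------------------------------


def test_design_row_zero_maps_touch_only_intercept_block():
    rec = {"gsv_gb": 0.0, "gsv_cci": 0.0, "zone": "north taiga", "pft": "mixed forest"}
    row = g.build_design_row(rec)
    names = fm.ModelSpec().column_names(fm.ZONES, fm.PFTS)
    nonzero = {names[i] for i in np.flatnonzero(row)}
    assert nonzero == {"a0[north taiga]", "b0[mixed forest]"}


def test_design_row_interaction_arithmetic():
    rec = {"gsv_gb": 100.0, "gsv_cci": 200.0, "zone": "middle taiga", "pft": "evergreen needleleaf"}
    row = g.build_design_row(rec)
    names = fm.ModelSpec().column_names(fm.ZONES, fm.PFTS)
    assert row[names.index("a3[middle taiga]")] == 20_000.0


def test_pft_change_leaves_zone_columns_untouched():
    base = {"gsv_gb": 50.0, "gsv_cci": 60.0, "zone": "south taiga", "pft": "evergreen needleleaf"}
    other = dict(base, pft="deciduous broadleaf")
    names = fm.ModelSpec().column_names(fm.ZONES, fm.PFTS)
    zone_cols = [i for i, n in enumerate(names) if n.startswith("a")]
    r1, r2 = g.build_design_row(base), g.build_design_row(other)
    np.testing.assert_array_equal(r1[zone_cols], r2[zone_cols])


def test_unknown_category_lists_known_levels():
    rec = {"gsv_gb": 1.0, "gsv_cci": 1.0, "zone": "savanna", "pft": "mixed forest"}
    with pytest.raises(ValueError, match="forest-tundra"):
        g.build_design_row(rec)


# -- fitting ----------------------------------------------------------------


def test_fit_matches_normal_equations_oracle():
    recs = _make_records(180, seed=1, noise=12.0)
    res = g.fit(recs)
    z = fm._category_index(recs["zone"], fm.ZONES, "zone")
    p = fm._category_index(recs["pft"], fm.PFTS, "pft")
    X = g.build_design(
        recs["gsv_gb"].to_numpy(), recs["gsv_cci"].to_numpy(), z, p,
        len(fm.ZONES), len(fm.PFTS),
    )
    expected = _normal_equations_oracle(X, recs["gsv_gt"].to_numpy())
    np.testing.assert_allclose(res.params, expected, rtol=1e-8)


def test_weighted_fit_matches_weighted_normal_equations():
    recs = _make_records(150, seed=2, noise=10.0)
    rng = np.random.default_rng(3)
    w = rng.uniform(0.1, 3.0, len(recs))
    res = g.fit(recs, weights=w)
    z = fm._category_index(recs["zone"], fm.ZONES, "zone")
    p = fm._category_index(recs["pft"], fm.PFTS, "pft")
    X = g.build_design(
        recs["gsv_gb"].to_numpy(), recs["gsv_cci"].to_numpy(), z, p,
        len(fm.ZONES), len(fm.PFTS),
    )
    expected = _normal_equations_oracle(X, recs["gsv_gt"].to_numpy(), w)
    np.testing.assert_allclose(res.params, expected, rtol=1e-8)


def test_noiseless_records_recover_generating_coefficients_exactly():
    truth = g.default_true_coeffs()
    recs = _make_records(400, seed=4, coeffs=truth, noise=0.0)
    res = g.fit(recs)
    got = res.coefficient_set()
    for fam in ("a0", "a1", "a2", "a3", "b0", "b1", "b2"):
        np.testing.assert_allclose(getattr(got, fam), getattr(truth, fam), atol=1e-8)


def test_unit_weights_equal_unweighted_fit():
    recs = _make_records(120, seed=5, noise=8.0)
    a = g.fit(recs)
    b = g.fit(recs, weights=np.ones(len(recs)))
    np.testing.assert_allclose(a.params, b.params, rtol=1e-12)


def test_intercept_only_fit_is_the_mean():
    recs = pd.DataFrame(
        {
            "gsv_gt": [1.0, 2.0, 3.0],
            "gsv_gb": [0.0, 0.0, 0.0],
            "gsv_cci": [0.0, 0.0, 0.0],
            "zone": ["north taiga"] * 3,
            "pft": ["mixed forest"] * 3,
        }
    )
    spec = fm.ModelSpec(
        use_gb=False, use_cci=False, use_interaction=False,
        zone_blocks=False, pft_offsets=False,
    )
    res = g.fit(recs, spec=spec)
    assert res.params.shape == (1,)
    assert res.params[0] == pytest.approx(2.0)


def test_residual_sums_vanish_for_ols_and_wls():
    recs = _make_records(200, seed=6, noise=15.0)
    scale = recs["gsv_gt"].abs().mean()
    ols = g.fit(recs)
    assert abs(ols.residuals.sum()) < 1e-6 * len(recs) * scale
    w = np.random.default_rng(7).uniform(0.2, 2.0, len(recs))
    wls = g.fit(recs, weights=w)
    assert abs(wls.weighted_residual_sum) < 1e-6 * len(recs) * scale


def test_rank_deficiency_names_collinear_columns():
    recs = _make_records(100, seed=8, noise=5.0)
    recs["gsv_cci"] = recs["gsv_gb"]  # perfectly collinear maps
    with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
        g.fit(recs, spec=fm.ModelSpec(use_interaction=False, pft_offsets=False))


def test_zero_weights_rejected():
    recs = _make_records(60, seed=9)
    with pytest.raises(ValueError, match="zero"):
        g.fit(recs, weights=np.zeros(len(recs)))


def test_too_few_records_rejected():
    recs = _make_records(10, seed=10)
    with pytest.raises(ValueError, match="at least"):
        g.fit(recs)


# -- weights -----------------------------------------------------------------


def test_identical_distributions_give_unit_weights():
    recs = pd.DataFrame({"gsv_gb": [5.0, 15.0, 25.0, 35.0]})
    scheme = g.compute_weights(recs, [5.0, 15.0, 25.0, 35.0])
    np.testing.assert_allclose(scheme.weights, 1.0)


def test_frequency_ratio_hand_computation():
    """Calibration uniform on bins [0,10) and [10,20); target all in [0,10)."""
    recs = pd.DataFrame({"gsv_gb": [5.0, 15.0]})
    scheme = g.compute_weights(recs, [1.0, 2.0, 3.0])
    np.testing.assert_allclose(scheme.weights, [2.0, 0.0])


def test_values_at_or_above_1000_clamp_to_last_bin():
    recs = pd.DataFrame({"gsv_gb": [1500.0, 995.0]})
    scheme = g.compute_weights(recs, [999.0])
    # both records land in bin [990, 1000) together with the whole target
    assert fm._bin_index(np.array([1500.0]))[0] == 99
    np.testing.assert_allclose(scheme.weights, [1.0, 1.0])


def test_orphan_target_bin_merges_with_warning():
    recs = pd.DataFrame({"gsv_gb": [5.0, 5.0]})
    with pytest.warns(UserWarning, match="merged"):
        scheme = g.compute_weights(recs, [5.0, 55.0])
    # orphan mass lands in the nearest occupied calibration bin -> weights stay 1
    np.testing.assert_allclose(scheme.weights, [1.0, 1.0])
    assert scheme.merged_bins == [5]


@given(st.floats(min_value=0, max_value=5000, allow_nan=False))
def test_bin_index_always_valid(x):
    b = fm._bin_index(np.array([x]))[0]
    assert 0 <= b < fm.N_BINS


def test_weights_renormalised_to_mean_one(records):
    target = np.asarray(records["gsv_gb"]) * 1.4  # shifted target distribution
    scheme = g.compute_weights(records, target)
    assert scheme.weights.mean() == pytest.approx(1.0)
    assert (scheme.weights >= 0).all()


# -- prediction ---------------------------------------------------------------


def test_zero_coefficients_predict_zero(landscape):
    zero = g.CoefficientSet(
        landscape.zones, landscape.pfts,
        *(np.zeros(len(landscape.zones)) for _ in range(4)),
        *(np.zeros(len(landscape.pfts)) for _ in range(3)),
    )
    pred = g.predict(zero, landscape)
    assert np.nansum(pred.raster) == 0.0
    assert pred.negative_fraction == 0.0


def test_negative_intercept_truncated_and_counted(landscape):
    nz, npf = len(landscape.zones), len(landscape.pfts)
    coeffs = g.CoefficientSet(
        landscape.zones, landscape.pfts,
        np.full(nz, -50.0), np.zeros(nz), np.zeros(nz), np.zeros(nz),
        np.zeros(npf), np.zeros(npf), np.zeros(npf),
    )
    pred = g.predict(coeffs, landscape)
    mask = landscape.forest_mask.astype(bool)
    assert (pred.raster[mask] == 0.0).all()
    assert pred.negative_fraction == 1.0


def test_identity_coefficients_reproduce_first_map(landscape):
    pred = g.predict(g.CoefficientSet.identity(landscape.zones, landscape.pfts), landscape)
    mask = landscape.forest_mask.astype(bool)
    np.testing.assert_allclose(pred.raster[mask], landscape.map_gb[mask])
    assert np.isnan(pred.raster[~mask]).all()


def test_dimension_mismatch_rejected(landscape):
    from types import SimpleNamespace

    bad = SimpleNamespace(
        map_gb=landscape.map_gb, map_cci=landscape.map_cci[:-1, :],
        zone=landscape.zone, pft=landscape.pft, forest_mask=landscape.forest_mask,
    )
    with pytest.raises(ValueError, match="dimension"):
        g.predict(g.CoefficientSet.identity(landscape.zones, landscape.pfts), bad)


def test_unseen_zone_pft_combo_falls_back_and_flags(landscape, records):
    # Drop one combo from calibration, then predict over the full landscape.
    drop_zone, drop_pft = records.iloc[0][["zone", "pft"]]
    reduced = records.loc[~((records["zone"] == drop_zone) & (records["pft"] == drop_pft))]
    res = g.fit(reduced, zones=landscape.zones, pfts=landscape.pfts)
    pred = g.predict(res, landscape)
    zi = list(landscape.zones).index(drop_zone)
    pi = list(landscape.pfts).index(drop_pft)
    combo_pixels = (landscape.zone == zi) & (landscape.pft == pi) & landscape.forest_mask
    if combo_pixels.any():
        assert pred.fallback[combo_pixels].all()
        assert pred.n_fallback >= int(combo_pixels.sum())


def test_predictions_nonnegative_and_monotone_in_maps(records, landscape):
    res = g.fit(records, zones=landscape.zones, pfts=landscape.pfts)
    pred = g.predict(res, landscape)
    mask = landscape.forest_mask.astype(bool)
    assert (pred.raster[mask] >= 0).all()
    # Numerical monotonicity: where the fitted partial slope w.r.t. map_gb is
    # positive at a pixel, nudging map_gb up must not decrease the prediction.
    import dataclasses

    eps = 1.0
    bumped = dataclasses.replace(landscape, map_gb=landscape.map_gb + eps)
    pred2 = g.predict(res, bumped)
    coeffs = res.coefficient_set()
    z, p = landscape.zone[mask], landscape.pft[mask]
    slope = coeffs.a1[z] + coeffs.b1[p] + coeffs.a3[z] * landscape.map_cci[mask]
    pos = slope > 0
    assert (pred2.raster[mask][pos] >= pred.raster[mask][pos] - 1e-9).all()


def test_coefficient_set_roundtrips_through_json(tmp_path):
    truth = g.default_true_coeffs()
    truth.to_json(tmp_path / "c.json")
    back = g.CoefficientSet.from_json(tmp_path / "c.json")
    for fam in ("a0", "a1", "a2", "a3", "b0", "b1", "b2"):
        np.testing.assert_array_equal(getattr(back, fam), getattr(truth, fam))
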