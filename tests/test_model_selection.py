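"""Fold assignment and cross-validated model comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import gsvfuse as g
from gsvfuse import fusion_model as fm
from gsvfuse import model_selection as ms


def test_balanced_folds_forty_records():
    labels = g.assign_folds(40, k=20, seed=0)
    sizes = np.bincount(labels, minlength=20)
    assert (sizes == 2).all()


def test_balanced_folds_forty_one_records():
    labels = g.assign_folds(41, k=20, seed=0)
    sizes = np.sort(np.bincount(labels, minlength=20))
    assert sizes[:-1].tolist() == [2] * 19 and sizes[-1] == 3


def test_fold_assignment_deterministic():
    a = g.assign_folds(137, k=20, seed=42)
    b = g.assign_folds(137, k=20, seed=42)
    np.testing.assert_array_equal(a, b)


def test_k_larger_than_n_rejected():
    with pytest.raises(ValueError):
        g.assign_folds(10, k=20, seed=0)


@given(st.integers(min_value=20, max_value=300), st.integers(min_value=2, max_value=20))
def test_folds_partition_with_near_equal_sizes(n, k):
    labels = g.assign_folds(n, k=k, seed=1)
    sizes = np.bincount(labels, minlength=k)
    assert sizes.sum() == n
    assert sizes.max() - sizes.min() <= 1


def test_stratified_folds_mirror_category_mix():
    strata = np.repeat(["a", "b"], [400, 100])
    labels = g.assign_folds(500, k=10, seed=3, stratify_by=strata)
    for f in range(10):
        frac_b = (strata[labels == f] == "b").mean()
        assert abs(frac_b - 0.2) < 0.06
    sizes = np.bincount(labels, minlength=10)
    assert sizes.max() - sizes.min() <= 1


def _records_from_model(n, seed, noise):
    rng = np.random.default_rng(seed)
    gb = rng.uniform(0, 300, n)
    cci = np.clip(0.8 * gb + rng.uniform(0, 80, n), 0, None)
    z = rng.integers(0, 6, n)
    p = rng.integers(0, 4, n)
    truth = g.default_true_coeffs()
    y = truth.mean_response(gb, cci, z, p) + rng.normal(0, noise, n)
    return pd.DataFrame(
        {
            "gsv_gt": y,
            "gsv_gb": gb,
            "gsv_cci": cci,
            "zone": np.asarray(fm.ZONES)[z],
            "pft": np.asarray(fm.PFTS)[p],
        }
    )


def test_true_model_on_noiseless_data_scores_zero():
    recs = _records_from_model(600, seed=1, noise=0.0)
    res = g.cross_validate(
        recs, candidates=[ms.CandidateSpec("truth", fm.ModelSpec())], k=20, seed=2
    )
    row = res.summary.iloc[0]
    assert row["me"] == pytest.approx(0.0, abs=1e-7)
    assert row["mae"] == pytest.approx(0.0, abs=1e-7)
    assert row["mse"] == pytest.approx(0.0, abs=1e-10)


def test_intercept_only_two_level_hand_computation():
    """Records split evenly between 0 and 10: MAE 5, MSE 25, small |ME|."""
    n = 400
    recs = pd.DataFrame(
        {
            "gsv_gt": np.tile([0.0, 10.0], n // 2),
            "gsv_gb": np.zeros(n),
            "gsv_cci": np.zeros(n),
            "zone": ["middle taiga"] * n,
            "pft": ["mixed forest"] * n,
        }
    )
    spec = fm.ModelSpec(
        use_gb=False, use_cci=False, use_interaction=False,
        zone_blocks=False, pft_offsets=False,
    )
    res = g.cross_validate(recs, candidates=[ms.CandidateSpec("mean", spec)], k=2, seed=5)
    row = res.summary.iloc[0]
    assert row["mae"] == pytest.approx(5.0, abs=0.2)
    assert row["mse"] == pytest.approx(25.0, abs=1.0)
    assert abs(row["me"]) < 0.5


def test_identical_candidates_get_identical_metrics():
    recs = _records_from_model(200, seed=7, noise=10.0)
    cands = [
        ms.CandidateSpec("one", fm.ModelSpec(use_interaction=False)),
        ms.CandidateSpec("two", fm.ModelSpec(use_interaction=False)),
    ]
    res = g.cross_validate(recs, candidates=cands, k=10, seed=8)
    a, b = res.summary.iloc[0], res.summary.iloc[1]
    assert a["mse"] == b["mse"] and a["mae"] == b["mae"] and a["me"] == b["me"]


def test_out_of_fold_discipline_no_leakage():
    """On pure-noise data a rich model cannot look good: CV-MSE must exceed
    its in-sample training MSE (a leaking CV would report training-like error)."""
    rng = np.random.default_rng(9)
    recs = _records_from_model(300, seed=9, noise=0.0)
    recs["gsv_gt"] = rng.normal(100, 30, len(recs))  # sever the signal
    cand = ms.CandidateSpec("rich", fm.ModelSpec())
    res = g.cross_validate(recs, candidates=[cand], k=20, seed=10)
    train_fit = g.fit(recs)
    train_mse = float((train_fit.residuals**2).mean())
    assert res.summary.iloc[0]["mse"] > train_mse * 1.05


def test_nested_candidate_training_mse_never_worse():
    """The richer nested model has training MSE <= the reduced model's."""
    recs = _records_from_model(500, seed=11, noise=20.0)
    rich = g.fit(recs, spec=fm.ModelSpec())
    poor = g.fit(recs, spec=fm.ModelSpec(use_interaction=False))
    assert float((rich.residuals**2).mean()) <= float((poor.residuals**2).mean()) + 1e-9


def test_failed_candidate_reported_not_dropped():
    recs = _records_from_model(200, seed=12, noise=10.0)
    recs["gsv_cci"] = recs["gsv_gb"]  # collinear: some candidates cannot fit
    cands = [
        ms.CandidateSpec("collinear", fm.ModelSpec(use_interaction=False, pft_offsets=False)),
        ms.CandidateSpec("gb_only", fm.ModelSpec(use_cci=False, use_interaction=False)),
    ]
    res = g.cross_validate(recs, candidates=cands, k=10, seed=13)
    assert res.summary.set_index("candidate").loc["collinear", "failed"]
    assert res.selected == "gb_only"


def test_selection_prefers_lowest_mse(records):
    res = g.cross_validate(records, k=10, seed=14)
    ok = res.summary.loc[~res.summary["failed"]]
    assert res.selected == ok.sort_values(["mse", "mae", "n_params"]).iloc[0]["candidate"]
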