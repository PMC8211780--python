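"""Candidate comparison by k-fold cross-validation.

Candidate calibration-model forms (full zone/PFT structure, main effects
only, single-map, pooled) are compared on out-of-fold predictions by mean
error (ME), mean absolute error (MAE) and mean squared error (MSE).  The
selection rule is lowest CV-MSE, ties broken by MAE and then by parsimony
(fewest design columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fusion_model as fm


@dataclass(frozen=True)
class CandidateSpec:
    """A named model form entering the cross-validation comparison."""

    name: str
    spec: fm.ModelSpec = field(default_factory=fm.ModelSpec)

    def __post_init__(self) -> None:
        # Every candidate has at least the intercept block by construction of
        # ModelSpec; nothing further to validate here.
        if not self.name:
            raise ValueError("candidate needs a name")


def default_candidates() -> list[CandidateSpec]:
    """Plausible candidate set: the selected full model plus reduced forms."""
    return [
        CandidateSpec("full_zone_pft_interaction", fm.ModelSpec()),
        CandidateSpec(
            "main_effects_only",
            fm.ModelSpec(use_interaction=False),
        ),
        CandidateSpec(
            "gb_only",
            fm.ModelSpec(use_cci=False, use_interaction=False),
        ),
        CandidateSpec(
            "cci_only",
            fm.ModelSpec(use_gb=False, use_interaction=False),
        ),
        CandidateSpec(
            "pooled_no_strata",
            fm.ModelSpec(zone_blocks=False, pft_offsets=False),
        ),
    ]


@dataclass
class CVResult:
    """Cross-validation outcome: per-fold and summary error statistics."""

    summary: pd.DataFrame  # candidate, me, mae, mse, n_params, failed
    per_fold: pd.DataFrame  # candidate, fold, me, mae, mse
    selected: str
    seed: int
    k: int


def assign_folds(
    n: int,
    k: int = 20,
    seed: int = 0,
    stratify_by: np.ndarray | None = None,
) -> np.ndarray:
    """Balanced fold labels in 0..k-1; sizes differ by at most one.

    With ``stratify_by``, records are shuffled within each category and dealt
    round-robin so each fold's category mix approximates the whole.
    """
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} records")
    rng = np.random.default_rng(seed)
    labels = np.empty(n, dtype=np.int64)
    if stratify_by is None:
        perm = rng.permutation(n)
        # Deal shuffled records round-robin: fold sizes differ by <= 1.
        labels[perm] = np.arange(n) % k
    else:
        strata = np.asarray(stratify_by)
        start = rng.integers(0, k)  # rotate so small strata don't pile on fold 0
        counter = 0
        for s in pd.unique(strata):
            idx = np.flatnonzero(strata == s)
            rng.shuffle(idx)
            for i in idx:
                labels[i] = (start + counter) % k
                counter += 1
    return labels


def _metrics(obs: np.ndarray, pred: np.ndarray) -> tuple[float, float, float]:
    err = obs - pred
    return float(err.mean()), float(np.abs(err).mean()), float((err**2).mean())


def cross_validate(
    records: pd.DataFrame,
    candidates: list[CandidateSpec] | None = None,
    k: int = 20,
    seed: int = 0,
    zones=fm.ZONES,
    pfts=fm.PFTS,
    stratify_by: str | None = None,
    truncate_predictions: bool = True,
) -> CVResult:
    """Compare candidates on out-of-fold predictions; select by MSE.

    Every record's prediction comes from a model trained without it.  A
    rank-deficient training split marks the candidate as failed (excluded
    from selection) rather than silently dropping it.
    """
    if candidates is None:
        candidates = default_candidates()
    n = len(records)
    strat = records[stratify_by].to_numpy() if stratify_by else None
    folds = assign_folds(n, k=k, seed=seed, stratify_by=strat)
    y = records["gsv_gt"].to_numpy(dtype=float)

    rows_fold, rows_sum = [], []
    for cand in candidates:
        pred = np.full(n, np.nan)
        failed = False
        for f in range(k):
            test = folds == f
            train = ~test
            try:
                res = fm.fit(records.loc[train], zones=zones, pfts=pfts, spec=cand.spec)
            except (np.linalg.LinAlgError, ValueError):
                failed = True
                break
            gb = records.loc[test, "gsv_gb"].to_numpy(dtype=float)
            cci = records.loc[test, "gsv_cci"].to_numpy(dtype=float)
            zi = fm._category_index(records.loc[test, "zone"], zones, "zone")
            pi = fm._category_index(records.loc[test, "pft"], pfts, "pft")
            X = fm.build_design(gb, cci, zi, pi, len(zones), len(pfts), cand.spec)
            p = X @ res.params
            if truncate_predictions:
                p = np.maximum(p, 0.0)
            pred[test] = p
            me, mae, mse = _metrics(y[test], p)
            rows_fold.append({"candidate": cand.name, "fold": f, "me": me, "mae": mae, "mse": mse})
        if failed:
            rows_sum.append(
                {
                    "candidate": cand.name,
                    "me": np.nan,
                    "mae": np.nan,
                    "mse": np.nan,
                    "n_params": len(cand.spec.column_names(zones, pfts)),
                    "failed": True,
                }
            )
            continue
        me, mae, mse = _metrics(y, pred)
        rows_sum.append(
            {
                "candidate": cand.name,
                "me": me,
                "mae": mae,
                "mse": mse,
                "n_params": len(cand.spec.column_names(zones, pfts)),
                "failed": False,
            }
        )

    summary = pd.DataFrame(rows_sum)
    ok = summary.loc[~summary["failed"]]
    if ok.empty:
        raise ValueError("every candidate failed to fit; no model can be selected")
    best = ok.sort_values(["mse", "mae", "n_params"], kind="stable").iloc[0]["candidate"]
    return CVResult(
        summary=summary,
        per_fold=pd.DataFrame(rows_fold),
        selected=str(best),
        seed=seed,
        k=k,
    )
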