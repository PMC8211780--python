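"""Bootstrap uncertainty for region-level GSV density.

The fusion model's residuals are strongly heteroscedastic, so analytic
regression standard errors are unusable; instead the calibration plots are
resampled with replacement B times, the model is refitted on each replicate
(re-deriving covariate-shift weights when the weighted variant is
configured), and the per-region mean predicted density is recorded.  The
replicate distribution gives the point estimate (mean), standard error (sd)
and a percentile 95% confidence interval per region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fusion_model as fm
from .synthetic_landscape import Landscape


@dataclass
class BootstrapConfig:
    """Bootstrap settings; resampling unit is the plot record."""

    B: int = 1000
    stratify_by_region: bool = False
    seed: int = 0
    max_redraw_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.B < 2:
            raise ValueError("B must be >= 2")


@dataclass
class RegionEstimate:
    """Per-region GSV density with bootstrap uncertainty and derived total."""

    region: int
    mean_density: float  # m3/ha, mean over bootstrap replicates
    se_density: float  # m3/ha
    ci95: tuple[float, float]  # percentile interval, m3/ha
    relative_se: float  # percent, 100 * se / mean
    forest_area: float  # ha
    total_gsv: float  # m3
    full_data_density: float  # m3/ha, estimate from the unresampled fit


def _region_pixel_data(landscape: Landscape) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forest-pixel map values, categories, and region ids, flattened."""
    mask = landscape.forest_mask.astype(bool)
    return (
        np.column_stack(
            [landscape.map_gb[mask], landscape.map_cci[mask]]
        ),
        np.column_stack(
            [landscape.zone[mask].astype(np.int64), landscape.pft[mask].astype(np.int64)]
        ),
        landscape.region[mask].astype(np.int64),
    )


def _resample_indices(
    rng: np.random.Generator, regions: np.ndarray, stratified: bool
) -> np.ndarray:
    n = regions.shape[0]
    if not stratified:
        return rng.integers(0, n, n)
    parts = []
    for r in np.unique(regions):
        idx = np.flatnonzero(regions == r)
        parts.append(rng.choice(idx, size=idx.size, replace=True))
    return np.concatenate(parts)


def bootstrap_regions(
    records: pd.DataFrame,
    landscape: Landscape,
    spec: fm.ModelSpec = fm.ModelSpec(),
    boot: BootstrapConfig = BootstrapConfig(),
) -> list[RegionEstimate]:
    """Bootstrap region-mean GSV densities; deterministic for a fixed seed.

    Each replicate resamples the plot records with replacement, refits the
    model (recomputing frequency-bin weights against each region's map-GSV
    distribution when ``spec.weighted``), predicts over every region's forest
    pixels with zero-truncation, and records the mean density.  Replicates
    with a rank-deficient design are redrawn; more than
    ``max_redraw_fraction x B`` redraws is an error.
    """
    if len(records) == 0:
        raise ValueError("no calibration records")
    zones, pfts = landscape.zones, landscape.pfts
    rng = np.random.default_rng(boot.seed)

    maps_px, cats_px, region_px = _region_pixel_data(landscape)
    region_ids = np.unique(region_px)
    X_px = fm.build_design(
        maps_px[:, 0], maps_px[:, 1], cats_px[:, 0], cats_px[:, 1],
        len(zones), len(pfts), spec,
    )
    counts = np.array([(region_px == r).sum() for r in region_ids])
    areas = counts * landscape.pixel_area
    rec_regions = records["region"].to_numpy()

    def region_means(res: fm.FitResult, df: pd.DataFrame) -> np.ndarray:
        """Per-region mean of the zero-truncated prediction."""
        if spec.weighted:
            out = np.empty(region_ids.size)
            for j, r in enumerate(region_ids):
                sel = region_px == r
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    ws = fm.compute_weights(df, maps_px[sel, 0])
                res_r = fm.fit(df, weights=ws.weights, zones=zones, pfts=pfts, spec=spec)
                out[j] = np.maximum(X_px[sel] @ res_r.params, 0.0).mean()
            return out
        pred = np.maximum(X_px @ res.params, 0.0)
        sums = np.array([pred[region_px == r].sum() for r in region_ids])
        return sums / counts

    # Full-data point estimate (reference for CI bracketing).
    full_fit = fm.fit(records, zones=zones, pfts=pfts, spec=spec)
    full_means = region_means(full_fit, records)

    reps = np.empty((boot.B, region_ids.size))
    redraws = 0
    max_redraws = max(1, int(np.ceil(boot.max_redraw_fraction * boot.B)))
    b = 0
    while b < boot.B:
        idx = _resample_indices(rng, rec_regions, boot.stratify_by_region)
        df = records.iloc[idx]
        try:
            res = fm.fit(df, zones=zones, pfts=pfts, spec=spec)
            reps[b] = region_means(res, df)
        except (np.linalg.LinAlgError, ValueError):
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError(
                    f"more than {boot.max_redraw_fraction:.0%} of bootstrap replicates "
                    "were rank deficient; calibration data too sparse"
                )
            continue
        b += 1

    lo, hi = np.percentile(reps, [2.5, 97.5], axis=0)
    mean = reps.mean(axis=0)
    se = reps.std(axis=0, ddof=1)
    out = []
    for j, r in enumerate(region_ids):
        rel = 100.0 * se[j] / mean[j] if mean[j] > 0 else float("nan")
        out.append(
            RegionEstimate(
                region=int(r),
                mean_density=float(mean[j]),
                se_density=float(se[j]),
                ci95=(float(lo[j]), float(hi[j])),
                relative_se=float(rel),
                forest_area=float(areas[j]),
                total_gsv=float(mean[j] * areas[j]),
                full_data_density=float(full_means[j]),
            )
        )
    return out


def bootstrap_coefficients(
    records: pd.DataFrame,
    B: int = 200,
    seed: int = 0,
    spec: fm.ModelSpec = fm.ModelSpec(),
    zones=fm.ZONES,
    pfts=fm.PFTS,
    max_redraw_fraction: float = 0.10,
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap the model coefficients themselves.

    Returns ``(replicates, ci)`` where ``replicates`` is (B, p) and ``ci`` is
    (2, p) holding the 2.5/97.5 percentile bounds per coefficient.  Used for
    parameter-recovery checks; regional estimates use
    :func:`bootstrap_regions`.
    """
    rng = np.random.default_rng(seed)
    n = len(records)
    reps = []
    redraws = 0
    max_redraws = max(1, int(np.ceil(max_redraw_fraction * B)))
    while len(reps) < B:
        idx = rng.integers(0, n, n)
        try:
            res = fm.fit(records.iloc[idx], zones=zones, pfts=pfts, spec=spec)
        except (np.linalg.LinAlgError, ValueError):
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("too many rank-deficient bootstrap replicates")
            continue
        reps.append(res.params)
    reps = np.asarray(reps)
    ci = np.percentile(reps, [2.5, 97.5], axis=0)
    return reps, ci


def summarize_errors(estimates: list[RegionEstimate]) -> dict[str, float]:
    """Regional relative-SE summary: min, max, median, and area-weighted mean (%)."""
    if not estimates:
        raise ValueError("no region estimates")
    rel = np.array([e.relative_se for e in estimates])
    area = np.array([e.forest_area for e in estimates])
    if area.sum() <= 0:
        raise ValueError("total forest area is zero")
    return {
        "min_rel_se": float(rel.min()),
        "max_rel_se": float(rel.max()),
        "median_rel_se": float(np.median(rel)),
        "area_weighted_rel_se": float(np.sum(rel * area) / area.sum()),
    }


def estimates_to_frame(estimates: list[RegionEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region": [e.region for e in estimates],
            "mean_density": [e.mean_density for e in estimates],
            "se": [e.se_density for e in estimates],
            "ci_lo": [e.ci95[0] for e in estimates],
            "ci_hi": [e.ci95[1] for e in estimates],
            "rel_se": [e.relative_se for e in estimates],
            "forest_area": [e.forest_area for e in estimates],
            "total_gsv": [e.total_gsv for e in estimates],
        }
    )
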